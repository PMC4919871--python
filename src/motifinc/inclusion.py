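"""Motif inclusion index (MII) from transcript abundance estimates.

For gene g and motif m the MII is the TPM-weighted fraction of the
gene's coding output that contains the motif::

    MII(g, m) = sum_{k in K} A_k / sum_{n in N} A_n

where N is the set of coding transcripts of g, K ⊆ N those containing
m, and A a transcript's abundance in TPM.  Non-coding isoforms enter
neither sum.  A gene whose total coding abundance is at or below the
detection cutoff (1 TPM by default) is UNDETECTED in that sample; for
multi-sample analyses a gene is kept when detected in at least
ceil(9/16 x n_samples) samples, generalizing a 9-of-16 tissue rule.

Abundance input follows the kallisto ``abundance.tsv`` dialect
(columns target_id, length, eff_length, est_counts, tpm); transcript
version suffixes (".N") are stripped for matching.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from motifinc.annotation import Gene, GenomeAnnotation
from motifinc.catalog import Motif, MotifCatalog
from motifinc.regulation import RegulationRecord, motif_presence

logger = logging.getLogger("motifinc.inclusion")


class _Undetected:
    """Sentinel for genes below the detection cutoff in a sample."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDETECTED"


UNDETECTED = _Undetected()

_VERSION_RE = re.compile(r"\.\d+$")


@dataclass
class AbundanceTable:
    """Per-sample transcript abundances (TPM)."""

    sample_id: str
    tpm: pd.Series  # index: transcript_id (version-stripped)

    def gene_total(self, gene: Gene) -> float:
        """Total TPM over the gene's coding transcripts."""
        return float(
            sum(
                self.tpm.get(t.transcript_id, 0.0)
                for t in gene.coding_transcripts()
            )
        )

    def n_unknown(self, annotation: GenomeAnnotation) -> int:
        known = {t.transcript_id for t in annotation.transcripts()}
        return int(sum(tid not in known for tid in self.tpm.index))


def load_abundance(path, sample_id: str | None = None) -> AbundanceTable:
    """Read one kallisto-style ``abundance.tsv``.

    Negative TPM values are rejected; transcript version suffixes are
    stripped (logged when any were present).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("target_id", "tpm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["tpm"] < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    ids = df["target_id"].astype(str)
    stripped = ids.str.replace(_VERSION_RE, "", regex=True)
    n_versioned = int((ids != stripped).sum())
    if n_versioned:
        logger.info("%s: stripped version suffix from %d transcript ids", path, n_versioned)
    if sample_id is None:
        sample_id = path.parent.name or path.stem
    tpm = pd.Series(df["tpm"].to_numpy(dtype=float), index=stripped.to_numpy())
    tpm = tpm.groupby(level=0).sum()  # collapse duplicates after version strip
    return AbundanceTable(sample_id=sample_id, tpm=tpm)


def load_manifest(manifest_path) -> list[AbundanceTable]:
    """Load a sample manifest TSV (columns: sample_id, path).

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", comment="#", dtype=str)
    tables = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        tables.append(load_abundance(p, sample_id=row["sample_id"]))
    return tables


# ---------------------------------------------------------------------------
# MII
# ---------------------------------------------------------------------------

def compute_mii(
    gene: Gene,
    motif: Motif,
    abundance: AbundanceTable,
    presence_calls: Mapping[str, bool] | None = None,
    min_tpm: float = 1.0,
):
    """MII of one motif in one sample, or :data:`UNDETECTED`.

    ``presence_calls`` maps each coding transcript id to motif
    presence; when omitted, presence is evaluated as a protein
    substring test.  The gene is UNDETECTED when its total coding
    abundance is at or below ``min_tpm`` (strictly-above rule).
    """
    coding = gene.coding_transcripts()
    if not coding:
        raise ValueError(f"gene {gene.gene_id} has no coding transcripts")
    if presence_calls is None:
        presence_calls = {
            t.transcript_id: motif_presence(motif, t) for t in coding
        }
    missing = [t.transcript_id for t in coding if t.transcript_id not in presence_calls]
    if missing:
        raise ValueError(
            f"presence calls missing for coding transcripts: {missing}"
        )
    denom = 0.0
    numer = 0.0
    for t in coding:
        a = float(abundance.tpm.get(t.transcript_id, 0.0))
        denom += a
        if presence_calls[t.transcript_id]:
            numer += a
    if denom <= min_tpm:
        return UNDETECTED
    return numer / denom


def gene_detected(
    gene: Gene,
    tables: Sequence[AbundanceTable],
    min_tpm: float = 1.0,
    min_samples: int | None = None,
) -> bool:
    """True iff the gene's coding abundance exceeds ``min_tpm`` in enough samples.

    ``min_samples`` defaults to ceil(9/16 x number of samples).
    """
    if not tables:
        raise ValueError("no abundance tables")
    if min_samples is None:
        min_samples = math.ceil(9 / 16 * len(tables))
    n_det = sum(t.gene_total(gene) > min_tpm for t in tables)
    return n_det >= min_samples


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

@dataclass
class MIIMatrix:
    """Motif x sample MII values (NaN marks UNDETECTED cells)."""

    values: pd.DataFrame  # index: row label, columns: sample ids
    detection_params: tuple[float, int]  # (min_tpm, min_detected_samples)
    const_like: set[str] = field(default_factory=set)
    row_motifs: dict[str, list[str]] = field(default_factory=dict)
    motif_gene: dict[str, str] = field(default_factory=dict)

    def alternative_rows(self, exclude_const_like: bool = True) -> pd.DataFrame:
        if not exclude_const_like:
            return self.values
        keep = [
            lbl
            for lbl in self.values.index
            if not all(m in self.const_like for m in self.row_motifs[lbl])
        ]
        return self.values.loc[keep]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="motif")


def build_mii_matrix(
    catalog: MotifCatalog,
    records: Sequence[RegulationRecord],
    tables: Sequence[AbundanceTable],
    annotation: GenomeAnnotation,
    collapse: bool = False,
    const_like_threshold: float = 0.95,
    min_tpm: float = 1.0,
    min_samples: int | None = None,
) -> MIIMatrix:
    """Assemble the motif x sample MII matrix behind the inclusion heatmaps.

    Rows are restricted to motifs of genes detected in at least
    ``min_samples`` samples.  Motifs whose MII exceeds
    ``const_like_threshold`` in every detected sample are flagged
    constitutive-like.  With ``collapse=True``, same-gene same-type
    motifs with identical profiles (after rounding to 6 decimals) are
    merged into one row labeled ``GENE(id1;id2)``.
    """
    sample_ids = [t.sample_id for t in tables]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in tables: {sample_ids}")
    if min_samples is None:
        min_samples = math.ceil(9 / 16 * len(tables))
    rec_by_motif = {r.motif_id: r for r in records}

    rows: dict[str, list[float]] = {}
    motif_gene: dict[str, str] = {}
    for motif in catalog:
        rec = rec_by_motif.get(motif.motif_id)
        if rec is None:
            continue
        gene = annotation.genes[motif.gene_id]
        if not gene_detected(gene, tables, min_tpm, min_samples):
            logger.info(
                "gene %s below detection cutoff; motif %s excluded",
                gene.gene_id, motif.motif_id,
            )
            continue
        presence = {c.transcript_id: c.present for c in rec.calls}
        vals = []
        for t in tables:
            v = compute_mii(gene, motif, t, presence_calls=presence, min_tpm=min_tpm)
            vals.append(np.nan if v is UNDETECTED else float(v))
        rows[motif.motif_id] = vals
        motif_gene[motif.motif_id] = motif.gene_id

    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    const_like = {
        mid
        for mid, row in df.iterrows()
        if row.notna().any() and (row.dropna() > const_like_threshold).all()
    }

    row_motifs = {mid: [mid] for mid in df.index}
    if collapse and len(df):
        df, row_motifs = _collapse_profiles(df, catalog, motif_gene)
    return MIIMatrix(
        values=df,
        detection_params=(min_tpm, min_samples),
        const_like=const_like,
        row_motifs=row_motifs,
        motif_gene=motif_gene,
    )


def _collapse_profiles(df, catalog, motif_gene):
    """Merge same-gene same-type motifs with byte-identical profiles."""
    key_of = {}
    for mid in df.index:
        motif = catalog.get(mid)
        profile = tuple(
            "NA" if np.isnan(v) else f"{v:.6f}" for v in df.loc[mid].to_numpy()
        )
        key_of[mid] = (motif.gene_id, motif.motif_type, profile)
    groups: dict[tuple, list[str]] = {}
    for mid in df.index:
        groups.setdefault(key_of[mid], []).append(mid)
    new_rows, row_motifs = {}, {}
    for (gene_id, _mtype, _profile), mids in groups.items():
        label = mids[0] if len(mids) == 1 else f"{gene_id}({';'.join(mids)})"
        new_rows[label] = df.loc[mids[0]].to_numpy()
        row_motifs[label] = mids
    out = pd.DataFrame.from_dict(new_rows, orient="index", columns=df.columns)
    return out, row_motifs
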