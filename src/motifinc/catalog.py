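"""Motif catalog: loading, validation, protein placement, NLS subtypes.

A catalog is a TSV of curated targeting signals (one row per motif:
id, host gene, type NLS/NES, amino-acid sequence, optional annotated
start position, optional subtype hint and source).  Loading enforces
the curation rules: motifs longer than 50 residues are signal patches
rather than signals and are dropped, and motifs whose sequence cannot
be found in any coding isoform of their gene are dropped as
unmappable.

NLS subtype calls follow the classical motif definitions: a bipartite
NLS has two adjacent basic residues (K/R), a 10-residue spacer and at
least three basic residues within the next five positions; a
monopartite NLS contains the consensus K-(K/R)-X-(K/R); PY-NLSs come
from a curated list (here, a catalog ``subtype_hint``) rather than a
sequence pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("motifinc.catalog")

MAX_MOTIF_LENGTH = 50
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
BASIC = set("KR")

MOTIF_TYPES = ("NLS", "NES")
NLS_SUBTYPES = ("PY", "bipartite", "monopartite", "non-classified")
DEFAULT_PRECEDENCE = ("PY", "bipartite", "monopartite")


class CatalogError(ValueError):
    pass


@dataclass
class Motif:
    """A curated targeting signal."""

    motif_id: str
    motif_type: str  # NLS | NES
    gene_id: str
    aa_seq: str
    annotated_start: int | None = None  # 1-based
    subtype: str | None = None  # NLS only; "not-applicable" for NES
    subtype_hint: str | None = None  # e.g. "PY" for curated PY-NLSs
    source: str = ""
    ambiguous_position: bool = False

    @property
    def length(self) -> int:
        return len(self.aa_seq)


@dataclass
class MotifCatalog:
    motifs: list[Motif] = field(default_factory=list)
    n_dropped_length: int = 0
    n_dropped_unmappable: int = 0

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def by_gene(self) -> dict[str, list[Motif]]:
        idx: dict[str, list[Motif]] = {}
        for m in self.motifs:
            idx.setdefault(m.gene_id, []).append(m)
        return idx

    def of_type(self, motif_type: str) -> list[Motif]:
        return [m for m in self.motifs if m.motif_type == motif_type]

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


# ---------------------------------------------------------------------------
# Loading / validation
# ---------------------------------------------------------------------------

def load_motifs(tsv_path, annotation=None, classify: bool = True) -> MotifCatalog:
    """Load and validate a motif TSV.

    Columns: ``motif_id  gene_id  type  sequence`` plus optional
    ``start`` (1-based annotated position), ``subtype_hint`` and
    ``source``.  Lines starting with ``#`` are comments.

    Motifs longer than 50 residues are dropped (logged).  When an
    annotation is supplied, motifs whose sequence occurs in no coding
    isoform of their gene are dropped as unmappable (logged), and each
    kept motif is positioned in its reference protein.  NLS subtypes
    are assigned unless ``classify`` is False.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str)
    required = {"motif_id", "gene_id", "type", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"motif TSV missing columns: {sorted(missing)}")
    if df["motif_id"].duplicated().any():
        dups = df.loc[df["motif_id"].duplicated(), "motif_id"].tolist()
        raise CatalogError(f"duplicate motif_id(s): {dups}")

    cat = MotifCatalog()
    for _, row in df.iterrows():
        mtype = str(row["type"]).strip()
        if mtype not in MOTIF_TYPES:
            raise CatalogError(
                f"motif {row['motif_id']}: unknown type {mtype!r} "
                f"(expected one of {MOTIF_TYPES})"
            )
        seq = str(row["sequence"]).strip().upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise CatalogError(
                f"motif {row['motif_id']}: non-amino-acid letters {sorted(bad)}"
            )
        start = row.get("start")
        start = int(start) if pd.notna(start) and str(start).strip() else None
        hint = row.get("subtype_hint")
        hint = str(hint).strip() if pd.notna(hint) and str(hint).strip() else None
        motif = Motif(
            motif_id=str(row["motif_id"]),
            motif_type=mtype,
            gene_id=str(row["gene_id"]),
            aa_seq=seq,
            annotated_start=start,
            subtype_hint=hint,
            source=str(row["source"]) if pd.notna(row.get("source")) else "",
        )
        if motif.length > MAX_MOTIF_LENGTH:
            cat.n_dropped_length += 1
            logger.info(
                "dropping motif %s: length %d exceeds %d residues",
                motif.motif_id, motif.length, MAX_MOTIF_LENGTH,
            )
            continue
        if annotation is not None and not _mappable(motif, annotation):
            cat.n_dropped_unmappable += 1
            logger.info(
                "dropping motif %s: sequence not found in any coding "
                "isoform of gene %s", motif.motif_id, motif.gene_id,
            )
            continue
        if classify and motif.motif_type == "NLS":
            motif.subtype = classify_nls_subtype(motif)
        elif motif.motif_type == "NES":
            motif.subtype = "not-applicable"
        cat.motifs.append(motif)
    logger.info(
        "loaded %d motifs (%d dropped for length, %d unmappable)",
        len(cat), cat.n_dropped_length, cat.n_dropped_unmappable,
    )
    return cat


def _mappable(motif: Motif, annotation) -> bool:
    gene = annotation.genes.get(motif.gene_id)
    if gene is None:
        return False
    return any(
        motif.aa_seq in t.protein_seq for t in gene.coding_transcripts()
    )


def write_catalog(catalog: MotifCatalog, out_path) -> None:
    """Re-export a validated catalog, with subtype and ambiguity columns.

    The output parses back through :func:`load_motifs` to an identical
    catalog (idempotent round-trip).
    """
    rows = []
    for m in catalog:
        rows.append(
            {
                "motif_id": m.motif_id,
                "gene_id": m.gene_id,
                "type": m.motif_type,
                "sequence": m.aa_seq,
                "start": m.annotated_start if m.annotated_start is not None else "",
                "subtype_hint": m.subtype_hint or "",
                "source": m.source,
                "subtype": m.subtype or "",
                "ambiguous_position": int(m.ambiguous_position),
            }
        )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Placement in the reference protein
# ---------------------------------------------------------------------------

def locate_motif(motif: Motif, protein_seq: str, use_annotation: bool = True) -> int | None:
    """1-based start of the motif in a protein, or None when absent.

    An annotated start is honored when the sequence actually matches
    there; otherwise the first occurrence is returned and, if the
    sequence occurs more than once, the motif's ``ambiguous_position``
    flag is set.  Pass ``use_annotation=False`` when locating in an
    isoform other than the one the annotation refers to.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    if use_annotation and motif.annotated_start is not None:
        i = motif.annotated_start - 1
        if protein_seq[i : i + motif.length] == motif.aa_seq:
            return motif.annotated_start
        logger.warning(
            "motif %s: annotated start %d inconsistent with protein; "
            "falling back to search", motif.motif_id, motif.annotated_start,
        )
    first = protein_seq.find(motif.aa_seq)
    if first == -1:
        return None
    if protein_seq.find(motif.aa_seq, first + 1) != -1:
        motif.ambiguous_position = True
    return first + 1


# ---------------------------------------------------------------------------
# NLS subtype classification
# ---------------------------------------------------------------------------

def matches_monopartite(seq: str) -> bool:
    """Contains the classical monopartite consensus K-(K/R)-X-(K/R)."""
    return any(
        seq[i] == "K" and seq[i + 1] in BASIC and seq[i + 3] in BASIC
        for i in range(len(seq) - 3)
    )


def matches_bipartite(seq: str, spacer_lengths: Sequence[int] = (10,)) -> bool:
    """Contains the bipartite pattern: 2 basics, spacer, >=3 basics in 5.

    The spacer is 10 residues by default; pass ``spacer_lengths=(10, 11,
    12)`` for the looser 10-12 residue linker definition.  The trailing
    window covers up to five positions after the spacer and must hold at
    least three basic residues.
    """
    n = len(seq)
    for i in range(n - 1):
        if seq[i] in BASIC and seq[i + 1] in BASIC:
            for s in spacer_lengths:
                w0 = i + 2 + s
                window = seq[w0 : w0 + 5]
                if sum(c in BASIC for c in window) >= 3:
                    return True
    return False


def classify_nls_subtype(
    motif: Motif,
    py_ids: Iterable[str] | None = None,
    spacer_lengths: Sequence[int] = (10,),
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str:
    """Assign an NLS subtype: PY, bipartite, monopartite or non-classified.

    PY membership comes from a curated id list (``py_ids``) or the
    catalog's ``subtype_hint``; the sequence patterns are tested
    anywhere within the motif.  When several classes match, the first
    in ``precedence`` wins (default PY > bipartite > monopartite).
    """
    if motif.motif_type != "NLS":
        raise ValueError(f"motif {motif.motif_id} is not an NLS")
    matched = set()
    if (py_ids is not None and motif.motif_id in set(py_ids)) or (
        motif.subtype_hint == "PY"
    ):
        matched.add("PY")
    if matches_bipartite(motif.aa_seq, spacer_lengths):
        matched.add("bipartite")
    if matches_monopartite(motif.aa_seq):
        matched.add("monopartite")
    for sub in precedence:
        if sub in matched:
            return sub
    return "non-classified"
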