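"""Co-regulation of NLS and NES within dual-motif genes.

Genes carrying both an import and an export signal can coordinate the
two: a joint 2x2 status table (NLS x NES, constitutive/alternative)
with Fisher's exact test measures concordance, and per-gene comparison
of NLS vs NES inclusion profiles across samples identifies complete
co-regulation (identical MII in every common detected sample, e.g.
both motifs on one cassette exon).

Gene-level status for multi-motif genes is the conservative reading:
constitutive only when every motif of that type is constitutive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from motifinc.inclusion import MIIMatrix
from motifinc.regulation import RegulationRecord

logger = logging.getLogger("motifinc.coregulation")

STATUSES = ("constitutive", "alternative")


@dataclass
class CoRegulationRecord:
    gene_id: str
    nls_status: str
    nes_status: str
    joint_class: str  # both_const | both_alt | mixed
    complete_coreg: bool | None = None  # None = not assessable
    same_exons: bool | None = None


def _gene_status(records: list[RegulationRecord]) -> str:
    return (
        "constitutive"
        if all(r.status == "constitutive" for r in records)
        else "alternative"
    )


def joint_status_records(records) -> list[CoRegulationRecord]:
    """One record per gene carrying at least one NLS and one NES."""
    by_gene: dict[str, dict[str, list[RegulationRecord]]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {}).setdefault(r.motif_type, []).append(r)
    out = []
    for gene_id in sorted(by_gene):
        groups = by_gene[gene_id]
        if "NLS" not in groups or "NES" not in groups:
            continue
        nls, nes = _gene_status(groups["NLS"]), _gene_status(groups["NES"])
        if nls == nes == "constitutive":
            joint = "both_const"
        elif nls == nes == "alternative":
            joint = "both_alt"
        else:
            joint = "mixed"
        out.append(CoRegulationRecord(gene_id, nls, nes, joint))
    return out


def joint_status_table(records) -> pd.DataFrame:
    """2x2 contingency table: rows NLS status, columns NES status."""
    co = records if records and isinstance(records[0], CoRegulationRecord) else None
    if co is None:
        co = joint_status_records(records)
    table = pd.DataFrame(
        np.zeros((2, 2), dtype=int), index=list(STATUSES), columns=list(STATUSES)
    )
    table.index.name = "NLS"
    table.columns.name = "NES"
    for r in co:
        table.loc[r.nls_status, r.nes_status] += 1
    return table


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value)``.  The p-value is the exact
    two-sided hypergeometric probability; the odds ratio is the sample
    (cross-product) estimate, with the Haldane 0.5 correction applied
    when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts in contingency table")
    res = stats.fisher_exact(t.astype(int), alternative="two-sided")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)


def complete_coregulation(
    gene_id: str,
    mii_matrix: MIIMatrix,
    catalog=None,
    annotation=None,
    eps: float = 1e-6,
):
    """Do a gene's NLS and NES share one inclusion profile?

    True iff |MII_NLS - MII_NES| <= eps in every sample where both are
    defined; None when the two motifs share no detected sample.  When a
    catalog and annotation are given, additionally reports whether both
    motifs map to the same exon set of their reference transcript
    (``same_exons``).  With several motifs of a type, all NLS x NES
    pairs must agree.
    """
    nls_rows, nes_rows = [], []
    for mid, gid in mii_matrix.motif_gene.items():
        if gid != gene_id:
            continue
        label = next(
            lbl for lbl, mids in mii_matrix.row_motifs.items() if mid in mids
        )
        motif_type = None
        if catalog is not None:
            motif_type = catalog.get(mid).motif_type
        else:  # fall back on id convention used in reports
            motif_type = "NLS" if "NLS" in mid.upper() else "NES"
        (nls_rows if motif_type == "NLS" else nes_rows).append(
            mii_matrix.values.loc[label]
        )
    if not nls_rows or not nes_rows:
        raise ValueError(f"gene {gene_id}: need both an NLS and an NES with MII rows")

    verdicts = []
    for rn in nls_rows:
        for re_ in nes_rows:
            both = rn.notna() & re_.notna()
            if not both.any():
                verdicts.append(None)
                continue
            verdicts.append(bool((rn[both] - re_[both]).abs().le(eps).all()))
    if all(v is None for v in verdicts):
        coreg = None
    else:
        coreg = all(v for v in verdicts if v is not None) and None not in verdicts

    same_exons = None
    if catalog is not None and annotation is not None:
        from motifinc.regulation import reference_mapping

        gene = annotation.genes[gene_id]
        exon_sets = {"NLS": [], "NES": []}
        for m in catalog.by_gene.get(gene_id, []):
            mapping = reference_mapping(m, gene)
            exon_sets[m.motif_type].append(frozenset(mapping.exon_indices))
        if exon_sets["NLS"] and exon_sets["NES"]:
            same_exons = set(exon_sets["NLS"]) == set(exon_sets["NES"])
    return coreg, same_exons


def coregulation_report(
    records, mii_matrix: MIIMatrix | None = None, catalog=None, annotation=None,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-gene co-regulation table for all dual-motif genes."""
    co = joint_status_records(records)
    rows = []
    for r in co:
        if mii_matrix is not None:
            try:
                r.complete_coreg, r.same_exons = complete_coregulation(
                    r.gene_id, mii_matrix, catalog=catalog,
                    annotation=annotation, eps=eps,
                )
            except ValueError:
                logger.info("gene %s: no MII rows for both motif types", r.gene_id)
        rows.append(
            {
                "gene_id": r.gene_id,
                "nls_status": r.nls_status,
                "nes_status": r.nes_status,
                "joint_class": r.joint_class,
                "complete_coreg": r.complete_coreg,
                "same_exons": r.same_exons,
            }
        )
    return pd.DataFrame(rows)
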