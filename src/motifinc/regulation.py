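"""Constitutive/alternative status and regulation modes per motif.

A motif is *constitutive* when every coding transcript of its gene
contains it, and *alternative* otherwise.  Each motif-lacking coding
transcript is explained by one or more pre-translational mechanisms,
evaluated against the motif's genomic coding footprint taken from a
reference isoform:

* ``alt_init``   - the transcript's coding region starts downstream
  (3', in transcription direction) of the motif's first coding base:
  alternative transcription/translation initiation.
* ``alt_term``   - the coding region ends upstream (5') of the motif's
  last coding base: alternative translation termination.
* ``alt_splice`` - some motif-coding base is spliced out of the
  transcript while its CDS span covers the motif locus (cassette exon,
  alternative 5'/3' splice site, intronic exon).
* ``frameshift`` - all motif-coding bases are retained inside the CDS
  but translated in a different reading frame.

Absences explained by none of the four are flagged ``unexplained``.
A transcript can satisfy several conditions; all are recorded, so a
motif can be regulated by more than one mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from motifinc.annotation import (
    Gene,
    GenomeAnnotation,
    MotifMapping,
    Transcript,
    protein_interval_to_genomic,
)
from motifinc.catalog import Motif, MotifCatalog, locate_motif

logger = logging.getLogger("motifinc.regulation")

MODES = ("alt_init", "alt_term", "alt_splice", "frameshift")


class RegulationError(ValueError):
    pass


@dataclass
class PresenceCall:
    motif_id: str
    transcript_id: str
    present: bool
    absence_modes: frozenset[str] = frozenset()
    unexplained: bool = False


@dataclass
class RegulationRecord:
    motif_id: str
    gene_id: str
    motif_type: str
    status: str  # constitutive | alternative
    modes: frozenset[str]
    n_coding_transcripts: int
    n_with_motif: int
    calls: list[PresenceCall] = field(default_factory=list)
    reference_mapping: MotifMapping | None = None

    @property
    def is_constitutive(self) -> bool:
        return self.status == "constitutive"


def motif_presence(motif: Motif, transcript: Transcript) -> bool:
    """True iff the motif sequence is a contiguous substring of the protein."""
    if not transcript.is_coding:
        raise RegulationError(
            f"presence is undefined on non-coding transcript "
            f"{transcript.transcript_id}"
        )
    return motif.aa_seq in transcript.protein_seq


def reference_mapping(motif: Motif, gene: Gene) -> MotifMapping:
    """Genomic footprint of the motif on its reference isoform.

    The reference is the longest coding protein containing the motif
    (ties broken by transcript id, so the choice is deterministic).
    """
    bearing = [t for t in gene.coding_transcripts() if motif.aa_seq in t.protein_seq]
    if not bearing:
        raise RegulationError(
            f"motif {motif.motif_id} not present in any coding transcript "
            f"of {gene.gene_id}"
        )
    ref = min(bearing, key=lambda t: (-len(t.protein_seq), t.transcript_id))
    start = locate_motif(motif, ref.protein_seq)
    return protein_interval_to_genomic(
        ref, start, start + motif.length - 1,
        motif_id=motif.motif_id, motif_type=motif.motif_type,
    )


def _downstream(strand: str, a: int, b: int) -> bool:
    """True iff genomic position a lies strictly 3' of b in transcription direction."""
    return a > b if strand == "+" else a < b


def classify_motif(
    motif: Motif, gene: Gene, annotation: GenomeAnnotation | None = None
) -> RegulationRecord:
    """Classify one motif across all coding transcripts of its gene."""
    coding = gene.coding_transcripts()
    if not coding:
        raise RegulationError(f"gene {gene.gene_id} has no coding transcripts")
    ref_map = reference_mapping(motif, gene)
    strand = gene.strand

    # motif coding bases and transcription-direction endpoints
    motif_bases: list[int] = []
    for s, e in ref_map.genomic_intervals:
        motif_bases.extend(range(s, e))
    first_base = motif_bases[0] if strand == "+" else motif_bases[-1]
    last_base = motif_bases[-1] if strand == "+" else motif_bases[0]

    calls: list[PresenceCall] = []
    for tx in sorted(coding, key=lambda t: t.transcript_id):
        if motif_presence(motif, tx):
            calls.append(PresenceCall(motif.motif_id, tx.transcript_id, True))
            continue
        modes = set()
        cpos = tx.coding_positions()
        t_first, t_last = int(cpos[0]), int(cpos[-1])
        if _downstream(strand, t_first, first_base):
            modes.add("alt_init")
        if _downstream(strand, last_base, t_last):
            modes.add("alt_term")
        in_exons = _positions_in_intervals(motif_bases, tx.exons)
        covers = not _downstream(strand, t_first, first_base) and not _downstream(
            strand, last_base, t_last
        )
        if covers and not all(in_exons):
            modes.add("alt_splice")
        index_of = {int(p): i for i, p in enumerate(cpos)}
        if all(p in index_of for p in motif_bases):
            if index_of[first_base] % 3 != 0:
                modes.add("frameshift")
        calls.append(
            PresenceCall(
                motif.motif_id,
                tx.transcript_id,
                present=False,
                absence_modes=frozenset(modes),
                unexplained=not modes,
            )
        )
        if not modes:
            logger.warning(
                "motif %s absent from %s but no regulation mode applies",
                motif.motif_id, tx.transcript_id,
            )

    n_with = sum(c.present for c in calls)
    all_modes = frozenset().union(*(c.absence_modes for c in calls))
    status = "constitutive" if n_with == len(coding) else "alternative"
    return RegulationRecord(
        motif_id=motif.motif_id,
        gene_id=gene.gene_id,
        motif_type=motif.motif_type,
        status=status,
        modes=all_modes,
        n_coding_transcripts=len(coding),
        n_with_motif=n_with,
        calls=calls,
        reference_mapping=ref_map,
    )


def _positions_in_intervals(positions, intervals) -> list[bool]:
    return [any(s <= p < e for s, e in intervals) for p in positions]


def classify_catalog(
    catalog: MotifCatalog, annotation: GenomeAnnotation
) -> list[RegulationRecord]:
    """Classify every motif of a catalog; order follows the catalog."""
    records = []
    for motif in catalog:
        gene = annotation.genes.get(motif.gene_id)
        if gene is None:
            raise RegulationError(
                f"motif {motif.motif_id}: gene {motif.gene_id} not in annotation"
            )
        records.append(classify_motif(motif, gene, annotation))
    return records


def summarize_modes(records) -> dict[str, int]:
    """Tabulate mode usage over one motif type's records.

    A motif regulated by k modes contributes to k mode counts;
    ``multi_mode`` counts motifs with two or more modes.
    """
    counts = {m: 0 for m in MODES}
    counts["constitutive"] = 0
    counts["alternative"] = 0
    counts["multi_mode"] = 0
    counts["unexplained"] = 0
    for r in records:
        counts[r.status] += 1
        for m in r.modes:
            counts[m] += 1
        if len(r.modes) >= 2:
            counts["multi_mode"] += 1
        if any(c.unexplained for c in r.calls):
            counts["unexplained"] += 1
    return counts


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def regulation_report(records) -> pd.DataFrame:
    rows = [
        {
            "motif_id": r.motif_id,
            "gene_id": r.gene_id,
            "type": r.motif_type,
            "status": r.status,
            "modes": ";".join(sorted(r.modes)),
            "n_coding_transcripts": r.n_coding_transcripts,
            "n_with_motif": r.n_with_motif,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def presence_matrix(records) -> pd.DataFrame:
    """Motif x transcript presence matrix (1 present / 0 absent)."""
    data: dict[str, dict[str, int]] = {}
    for r in records:
        for c in r.calls:
            data.setdefault(r.motif_id, {})[c.transcript_id] = int(c.present)
    return pd.DataFrame.from_dict(data, orient="index").fillna(-1).astype(int)
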