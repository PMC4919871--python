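"""Synthetic fixtures: gene models with planted motifs and abundances.

Generates complete, self-consistent test data — genome FASTA, Ensembl-
dialect GTF, protein FASTA, motif catalog TSV, kallisto-style abundance
tables and a ground-truth ledger — in which every pre-translational
regulation scenario is planted by construction:

* ``constitutive``   motif in an exon shared by all coding isoforms
* ``cassette_exon``  motif exon skipped in-frame by some isoforms
* ``alt5ss``         proximal 5' splice site removes the motif-coding
                     exon end
* ``alt3ss``         distal 3' splice site removes the motif-coding
                     exon start
* ``intronic_exon``  motif-coding interior of an exon spliced out
* ``alt_init``       downstream alternative promoter/start codon past
                     the motif
* ``alt_term``       alternative terminal exon ending before the motif
* ``frameshift``     off-frame exon skip translating the motif region
                     in a shifted frame
* ``multi_mode``     one early-terminating isoform plus one
                     frameshifted isoform (two modes on one gene)

Motif peptides are embedded with codons drawn uniformly among
synonymous options; flanking peptides are rejection-sampled so the
motif occurs exactly once per bearing protein (and, for NLS genes,
basic residues are kept out of flanks so the planted subtype is
unambiguous).  Abundance tables assign each gene a total TPM drawn
log-uniformly from [0.1, 500] (so a fraction of genes falls below the
1 TPM detection cutoff) and split it so motif-bearing isoforms carry
exactly the planted inclusion fraction f; a high-abundance non-coding
filler transcript absorbs the remainder so each sample sums to 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from motifinc.annotation import Gene, GenomeAnnotation, Transcript
from motifinc.catalog import Motif, classify_nls_subtype
from motifinc.inclusion import AbundanceTable

logger = logging.getLogger("motifinc.simulate")

SCENARIOS = (
    "constitutive",
    "cassette_exon",
    "alt5ss",
    "alt3ss",
    "intronic_exon",
    "alt_init",
    "alt_term",
    "frameshift",
    "multi_mode",
)

#: Planted per-sample inclusion fractions exercised by default.
DEFAULT_F_GRID = (0.0, 0.016, 0.39, 0.5, 0.75, 0.88, 0.95, 1.0)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SYN: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _SYN.setdefault(_aa, []).append(_codon)
_STOP = "TAA"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_NONBASIC = "".join(c for c in _AA20 if c not in "KR")
_NT = "ACGT"

_UTR = 24
_INTRON = 48


class SimulationError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic gene."""

    scenario: str
    motif_type: str = "NLS"  # NLS | NES
    n_isoforms: int | None = None
    strand: str = "+"
    motif_subtype_target: str | None = None  # monopartite|bipartite|PY|none
    motif_exon_span: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if self.n_isoforms is not None and self.scenario != "constitutive":
            if self.n_isoforms < 2:
                raise SimulationError(
                    f"{self.scenario} requires at least 2 isoforms"
                )
        if self.motif_exon_span != 1 and self.scenario != "constitutive":
            raise SimulationError(
                "multi-exon motifs are only generated for the constitutive scenario"
            )


@dataclass
class SimulatedGene:
    """A realized gene plus its planted truth."""

    gene: Gene
    chrom_seq: str  # sequence of the gene's chromosome segment
    motif: Motif
    scenario: str
    subtype_target: str | None
    status: str
    modes: frozenset[str]
    aa_start: int  # 1-based, in the reference protein
    exon_span: int
    bearing_transcripts: frozenset[str]
    reference_transcript: str


# ---------------------------------------------------------------------------
# Random sequence ingredients
# ---------------------------------------------------------------------------

def _rand_nt(rng, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


def _rand_pep(rng, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _codons(rng, peptide: str) -> str:
    return "".join(
        _SYN[aa][rng.integers(0, len(_SYN[aa]))] for aa in peptide
    )


def _make_motif_peptide(rng, motif_type: str, subtype_target: str | None) -> str:
    basic = "KR"
    if motif_type == "NES":
        # leucine-rich export signal: L-x3-L-x2-L-x-L
        x = lambda n: _rand_pep(rng, n, "ADEGNQSTV")  # noqa: E731
        return x(1) + "L" + x(3) + "L" + x(2) + "L" + x(1) + "L" + x(1)
    target = subtype_target or "monopartite"
    if target == "monopartite":
        core = "K" + rng.choice(list(basic)) + _rand_pep(rng, 1, _AA_NONBASIC) + rng.choice(list(basic))
        return _rand_pep(rng, 2, _AA_NONBASIC) + core + _rand_pep(rng, 2, _AA_NONBASIC)
    if target == "bipartite":
        tail = "".join(rng.permutation(list("KKK" + _rand_pep(rng, 2, _AA_NONBASIC))))
        return rng.choice(list(basic)) + rng.choice(list(basic)) + _rand_pep(rng, 10, _AA_NONBASIC) + tail
    if target == "PY":
        n_region = _rand_pep(rng, 7, "AGSTNQVIP")
        return n_region + "R" + _rand_pep(rng, int(rng.integers(2, 6)), _AA_NONBASIC.replace("P", "")) + "PY"
    if target == "none":
        return _rand_pep(rng, int(rng.integers(8, 13)), _AA_NONBASIC)
    raise SimulationError(f"unknown motif subtype target {target!r}")


# ---------------------------------------------------------------------------
# Layout machinery (local sense-strand coordinates)
# ---------------------------------------------------------------------------

class _Layout:
    def __init__(self):
        self.seq = ""

    def add(self, s: str) -> tuple[int, int]:
        a = len(self.seq)
        self.seq += s
        return (a, len(self.seq))


@dataclass
class _IsoDraft:
    exons: list[tuple[int, int]]  # ascending in sense orientation
    cds: tuple[int, int]  # span incl stop codon
    bearing: bool


@dataclass
class _GeneDraft:
    seq: str
    isoforms: list[_IsoDraft]
    motif_peptide: str
    aa_start: int  # in isoform 0 (reference) protein, 1-based
    exon_span: int
    status: str
    modes: frozenset[str]


def _peps(rng, *sizes) -> list[str]:
    return [_rand_pep(rng, int(rng.integers(lo, hi + 1)), _AA_NONBASIC) for lo, hi in sizes]


def _build_draft(spec: ScenarioSpec, motif_pep: str, rng) -> _GeneDraft:
    builder = {
        "constitutive": _build_constitutive,
        "cassette_exon": _build_cassette,
        "alt5ss": _build_alt5ss,
        "alt3ss": _build_alt3ss,
        "intronic_exon": _build_intronic,
        "alt_init": _build_alt_init,
        "alt_term": _build_alt_term,
        "frameshift": _build_frameshift,
        "multi_mode": _build_multi_mode,
    }[spec.scenario]
    return builder(spec, motif_pep, rng)


def _std_scaffold(rng, motif_pep):
    """Shared 4-exon scaffold pieces: peptides pA|pB|pC1+M+pC2|pD."""
    pA, pB, pC1, pC2, pD = _peps(rng, (6, 10), (6, 10), (4, 8), (4, 8), (6, 10))
    return pA, pB, pC1, pC2, pD


def _build_constitutive(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    L.add(_rand_nt(rng, _INTRON))
    x3_nt = _codons(rng, pC1 + M + pC2)
    if spec.motif_exon_span == 2:
        # junction inside the motif, at a codon boundary
        k = int(rng.integers(1, len(M)))
        cut = 3 * (len(pC1) + k)
        x3a = L.add(x3_nt[:cut])
        L.add(_rand_nt(rng, _INTRON))
        x3b = L.add(x3_nt[cut:])
        motif_exons = [x3a, x3b]
    else:
        motif_exons = [L.add(x3_nt)]
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e2, e4 = (u5[0], x1[1]), x2, (x4[0], u3[1])
    cds = (x1[0], stop_end)
    iso1 = _IsoDraft([e1, e2, *motif_exons, e4], cds, True)
    iso2 = _IsoDraft([e1, *motif_exons, e4], cds, True)  # skips neutral exon 2
    return _GeneDraft(
        L.seq, [iso1, iso2], M, len(pA) + len(pB) + len(pC1) + 2,
        spec.motif_exon_span, "constitutive", frozenset(),
    )


def _build_cassette(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    L.add(_rand_nt(rng, _INTRON))
    x3 = L.add(_codons(rng, pC1 + M + pC2))
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
    cds = (x1[0], stop_end)
    isoforms = [
        _IsoDraft([e1, x2, x3, e4], cds, True),
        _IsoDraft([e1, x2, e4], cds, False),  # skips the motif exon
    ]
    if (spec.n_isoforms or 2) >= 3:
        isoforms.append(_IsoDraft([e1, x3, e4], cds, True))  # skips neutral exon
    return _GeneDraft(
        L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
        "alternative", frozenset({"alt_splice"}),
    )


def _build_alt5ss(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    L.add(_rand_nt(rng, _INTRON))
    x3a = L.add(_codons(rng, pC1))  # kept by both splice-site choices
    x3b = L.add(_codons(rng, M + pC2))  # removed by the proximal donor
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
    cds = (x1[0], stop_end)
    isoforms = [
        _IsoDraft([e1, x2, (x3a[0], x3b[1]), e4], cds, True),
        _IsoDraft([e1, x2, x3a, e4], cds, False),
    ]
    return _GeneDraft(
        L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
        "alternative", frozenset({"alt_splice"}),
    )


def _build_alt3ss(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    L.add(_rand_nt(rng, _INTRON))
    x3a = L.add(_codons(rng, pC1 + M))  # removed by the distal acceptor
    x3b = L.add(_codons(rng, pC2))
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
    cds = (x1[0], stop_end)
    isoforms = [
        _IsoDraft([e1, x2, (x3a[0], x3b[1]), e4], cds, True),
        _IsoDraft([e1, x2, x3b, e4], cds, False),
    ]
    return _GeneDraft(
        L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
        "alternative", frozenset({"alt_splice"}),
    )


def _build_intronic(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    L.add(_rand_nt(rng, _INTRON))
    x3a = L.add(_codons(rng, pC1))
    x3m = L.add(_codons(rng, M))  # interior piece, spliced out as an intron
    x3b = L.add(_codons(rng, pC2))
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
    cds = (x1[0], stop_end)
    isoforms = [
        _IsoDraft([e1, x2, (x3a[0], x3b[1]), e4], cds, True),
        _IsoDraft([e1, x2, x3a, x3b, e4], cds, False),
    ]
    return _GeneDraft(
        L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
        "alternative", frozenset({"alt_splice"}),
    )


def _build_alt_init(spec, M, rng):
    pA1, pA2, pB, pC = _peps(rng, (3, 6), (4, 8), (6, 10), (6, 10))
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA1 + M + pA2))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, "M" + pB))  # internal Met: downstream start codon
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * (1 + len(pC)) + 3
    x3 = L.add(_codons(rng, "M" + pC) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e3 = (u5[0], x1[1]), (x3[0], u3[1])
    cds1 = (x1[0], stop_end)
    isoforms = [
        _IsoDraft([e1, x2, e3], cds1, True),
        # alternative promoter in the first intron, CDS from the exon-2 Met
        _IsoDraft([(x2[0] - 15, x2[1]), e3], (x2[0], stop_end), False),
    ]
    if (spec.n_isoforms or 2) >= 3:
        # a further-staggered start at the exon-3 Met
        isoforms.append(
            _IsoDraft([(x3[0] - 15, u3[1])], (x3[0], stop_end), False)
        )
    return _GeneDraft(
        L.seq, isoforms, M, len(pA1) + 2, 1,
        "alternative", frozenset({"alt_init"}),
    )


def _build_alt_term(spec, M, rng):
    pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
    L = _Layout()
    u5 = L.add(_rand_nt(rng, _UTR))
    x1 = L.add("ATG" + _codons(rng, pA))
    L.add(_rand_nt(rng, _INTRON))
    x2 = L.add(_codons(rng, pB))
    stop2 = L.add(_STOP)  # read-through stop, intronic for the long isoform
    utr2 = L.add(_rand_nt(rng, 15))
    L.add(_rand_nt(rng, _INTRON))
    x3 = L.add(_codons(rng, pC1 + M + pC2))
    L.add(_rand_nt(rng, _INTRON))
    stop_end = len(L.seq) + 3 * len(pD) + 3
    x4 = L.add(_codons(rng, pD) + _STOP)
    u3 = L.add(_rand_nt(rng, _UTR))
    e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
    isoforms = [
        _IsoDraft([e1, x2, x3, e4], (x1[0], stop_end), True),
        # alternative terminal exon: exon 2 extended to a read-through stop
        _IsoDraft([e1, (x2[0], utr2[1])], (x1[0], stop2[1]), False),
    ]
    return _GeneDraft(
        L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
        "alternative", frozenset({"alt_term"}),
    )


def _frameshift_pieces(spec, M, rng, with_term_isoform: bool):
    """Off-frame exon-skip scaffold; optionally adds an early-stop isoform."""
    for _ in range(300):
        pA, pB, pC1, pC2, pD = _std_scaffold(rng, M)
        delta = int(rng.integers(1, 3))  # exon-2 3' boundary off codon by 1-2 nt
        cds_nt = (
            "ATG" + _codons(rng, pA) + _codons(rng, pB)
            + _codons(rng, pC1 + M + pC2) + _codons(rng, pD) + _STOP
        )
        b0 = 3 + 3 * len(pA)
        b1 = b0 + 3 * len(pB) + delta
        b2 = 3 + 3 * (len(pA) + len(pB) + len(pC1) + len(M) + len(pC2))
        L = _Layout()
        u5 = L.add(_rand_nt(rng, _UTR))
        x1 = L.add(cds_nt[:b0])
        L.add(_rand_nt(rng, _INTRON))
        x2 = L.add(cds_nt[b0:b1])
        stop2_iv = comp_iv = utr2_iv = None
        if with_term_isoform:
            comp_len = (3 - ((b1 - 0) % 3)) % 3
            comp = _rand_nt(rng, comp_len)
            if comp_len and _TABLE.forward_table.get(cds_nt[b1 - (3 - comp_len):b1] + comp) is None:
                continue  # completed codon would be a stop; redraw
            comp_iv = L.add(comp)
            stop2_iv = L.add(_STOP)
            utr2_iv = L.add(_rand_nt(rng, 15))
        L.add(_rand_nt(rng, _INTRON))
        x3 = L.add(cds_nt[b1:b2])
        L.add(_rand_nt(rng, _INTRON))
        x4 = L.add(cds_nt[b2:])
        u3 = L.add(_rand_nt(rng, _UTR))
        e1, e4 = (u5[0], x1[1]), (x4[0], u3[1])
        ref_stop_end = x4[0] + (len(cds_nt) - b2)
        ref = _IsoDraft([e1, x2, x3, e4], (x1[0], ref_stop_end), True)

        # frameshifted isoform: skips exon 2, shifting downstream frame
        fs_tx = L.seq[e1[0]:e1[1]] + L.seq[x3[0]:x3[1]] + L.seq[e4[0]:e4[1]]
        atg = _UTR  # ATG offset within the first exon
        frame_nt = fs_tx[atg:]
        frame_nt = frame_nt[: 3 * (len(frame_nt) // 3)]
        prot = str(Seq(frame_nt).translate(to_stop=False))
        stop_at = prot.find("*")
        if stop_at == -1:
            continue
        stop_nt_tx = atg + 3 * stop_at  # transcript coord of stop start
        # motif end in the skipped-exon transcript: within exon 3
        motif_end_tx = (e1[1] - e1[0]) + (
            b2 - b1 - 3 * len(pC2)
        )  # end of motif codons inside exon 3
        if stop_nt_tx < motif_end_tx:
            continue  # premature stop inside/before motif: redraw codons
        if M in prot[: stop_at]:
            continue
        # map the stop back to local genomic coordinates
        e1_len = e1[1] - e1[0]
        x3_len = x3[1] - x3[0]
        if stop_nt_tx < e1_len + x3_len < stop_nt_tx + 3:
            continue  # stop codon would straddle the exon junction
        if stop_nt_tx < e1_len + x3_len:
            stop_g = x3[0] + (stop_nt_tx - e1_len)
        else:
            stop_g = e4[0] + (stop_nt_tx - e1_len - x3_len)
        if stop_g + 3 > u3[1]:
            continue
        fs_iso = _IsoDraft([e1, x3, e4], (x1[0], stop_g + 3), False)
        isoforms = [ref, fs_iso]
        modes = {"frameshift"}
        if with_term_isoform:
            isoforms.append(
                _IsoDraft([e1, (x2[0], utr2_iv[1])], (x1[0], stop2_iv[1]), False)
            )
            modes.add("alt_term")
        return _GeneDraft(
            L.seq, isoforms, M, len(pA) + len(pB) + len(pC1) + 2, 1,
            "alternative", frozenset(modes),
        )
    raise SimulationError("could not realize frameshift scenario (codon search failed)")


def _build_frameshift(spec, M, rng):
    return _frameshift_pieces(spec, M, rng, with_term_isoform=False)


def _build_multi_mode(spec, M, rng):
    return _frameshift_pieces(spec, M, rng, with_term_isoform=True)


# ---------------------------------------------------------------------------
# Realization: strand flip, placement, Transcript/Gene objects
# ---------------------------------------------------------------------------

def _flip(iv: tuple[int, int], n: int) -> tuple[int, int]:
    return (n - iv[1], n - iv[0])


def _realize(
    draft: _GeneDraft,
    spec: ScenarioSpec,
    gene_id: str,
    chrom: str,
    offset: int,
) -> tuple[Gene, str]:
    """Turn a sense-strand draft into Gene/Transcript objects.

    Returns the gene and the chromosome segment carrying it (already
    reverse-complemented for minus-strand genes).  Intervals are
    shifted by ``offset``.
    """
    n = len(draft.seq)
    if spec.strand == "-":
        seq = str(Seq(draft.seq).reverse_complement())
    else:
        seq = draft.seq
    gene = Gene(gene_id=gene_id, name=gene_id, chrom=chrom, strand=spec.strand)
    for i, iso in enumerate(draft.isoforms, start=1):
        exons = iso.exons
        cds = iso.cds
        if spec.strand == "-":
            exons = sorted(_flip(e, n) for e in exons)
            cds = _flip(cds, n)
        exons = [(s + offset, e + offset) for s, e in sorted(exons)]
        cds = (cds[0] + offset, cds[1] + offset)
        cds_ivs = [
            (max(s, cds[0]), min(e, cds[1]))
            for s, e in exons
            if s < cds[1] and e > cds[0]
        ]
        gene.transcripts.append(
            Transcript(
                transcript_id=f"{gene_id}.t{i}",
                gene_id=gene_id,
                chrom=chrom,
                strand=spec.strand,
                exons=exons,
                cds_intervals=cds_ivs,
            )
        )
    return gene, seq


def simulate_gene(spec: ScenarioSpec, seed: int) -> SimulatedGene:
    """Generate one synthetic gene realizing a regulation scenario.

    The gene sits alone on chromosome ``chrS1`` with a small flanking
    pad; proteins are attached by translating each isoform's CDS, and
    the construction is verified (motif present exactly once in
    bearing isoforms, absent from the others) with resampling on the
    rare failure.
    """
    rng = np.random.default_rng(seed)
    return _simulate_gene(spec, "GSYN1", "chrS1", rng)


def _simulate_gene(
    spec: ScenarioSpec, gene_id: str, chrom: str, rng
) -> SimulatedGene:
    for _ in range(100):
        motif_pep = _make_motif_peptide(rng, spec.motif_type, spec.motif_subtype_target)
        if spec.motif_type == "NLS" and not _subtype_ok(motif_pep, spec.motif_subtype_target):
            continue
        draft = _build_draft(spec, motif_pep, rng)
        pad = 10
        gene, seg = _realize(draft, spec, gene_id, chrom, offset=pad)
        chrom_seq = _rand_nt(rng, pad) + seg + _rand_nt(rng, pad)
        genome = {chrom: chrom_seq}
        ok = True
        for iso, tx in zip(draft.isoforms, gene.transcripts):
            nt = tx.cds_sequence(genome)
            if len(nt) % 3 != 0:
                ok = False
                break
            aa = str(Seq(nt).translate())
            if not aa.endswith("*") or "*" in aa[:-1]:
                ok = False
                break
            tx.protein_seq = aa[:-1]
            if iso.bearing != (tx.protein_seq.count(motif_pep) == 1) or (
                not iso.bearing and motif_pep in tx.protein_seq
            ):
                ok = False
                break
        if not ok:
            continue
        ref = gene.transcripts[0]
        assert ref.protein_seq[draft.aa_start - 1 : draft.aa_start - 1 + len(motif_pep)] == motif_pep
        motif = Motif(
            motif_id=f"{gene_id}:{spec.motif_type}1",
            motif_type=spec.motif_type,
            gene_id=gene_id,
            aa_seq=motif_pep,
            annotated_start=draft.aa_start,
            subtype_hint="PY" if spec.motif_subtype_target == "PY" else None,
            source="synthetic",
        )
        return SimulatedGene(
            gene=gene,
            chrom_seq=chrom_seq,
            motif=motif,
            scenario=spec.scenario,
            subtype_target=spec.motif_subtype_target,
            status=draft.status,
            modes=draft.modes,
            aa_start=draft.aa_start,
            exon_span=draft.exon_span,
            bearing_transcripts=frozenset(
                tx.transcript_id
                for iso, tx in zip(draft.isoforms, gene.transcripts)
                if iso.bearing
            ),
            reference_transcript=gene.transcripts[0].transcript_id,
        )
    raise SimulationError(f"could not realize scenario {spec.scenario} for {gene_id}")


def _subtype_ok(peptide: str, target: str | None) -> bool:
    probe = Motif("probe", "NLS", "g", peptide,
                  subtype_hint="PY" if target == "PY" else None)
    expected = {None: "monopartite", "none": "non-classified"}.get(target, target)
    return classify_nls_subtype(probe) == expected


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A complete in-memory fixture with its truth ledger."""

    annotation: GenomeAnnotation
    genome: dict[str, str]
    sim_genes: list[SimulatedGene]
    tables: list[AbundanceTable] = field(default_factory=list)
    truth_motifs: pd.DataFrame | None = None
    truth_abundance: pd.DataFrame | None = None

    def motif_rows(self):
        return [g.motif for g in self.sim_genes]


def default_scenario_grid() -> list[ScenarioSpec]:
    """64 gene recipes: 8 base scenarios x 2 motif types x 2 strands x 2.

    NLS subtype targets cycle through monopartite / bipartite / PY /
    non-classified; the second constitutive NLS replicate carries a
    two-exon motif so multi-exon spans are represented.
    """
    base = [s for s in SCENARIOS if s != "multi_mode"]
    nls_targets = ("monopartite", "bipartite", "PY", "none")
    specs = []
    i = 0
    for scen in base:
        for mtype in ("NLS", "NES"):
            for strand in ("+", "-"):
                for rep in range(2):
                    target = nls_targets[(i + rep) % 4] if mtype == "NLS" else None
                    span = 2 if (scen == "constitutive" and mtype == "NLS" and rep == 1) else 1
                    specs.append(
                        ScenarioSpec(
                            scenario=scen,
                            motif_type=mtype,
                            strand=strand,
                            motif_subtype_target=target,
                            motif_exon_span=span,
                            n_isoforms=3 if scen in ("alt_init", "cassette_exon") else None,
                        )
                    )
                i += 1
    return specs


def simulate_fixture(
    seed: int,
    specs: list[ScenarioSpec] | None = None,
    n_samples: int = 16,
    genes_per_chrom: int = 8,
    f_grid=DEFAULT_F_GRID,
) -> Fixture:
    """Build the default multi-gene fixture with abundances and truth."""
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_scenario_grid()
    sim_genes: list[SimulatedGene] = []
    for i, spec in enumerate(specs):
        chrom = f"chrS{i // genes_per_chrom + 1}"
        sim_genes.append(_simulate_gene(spec, f"GSYN{i + 1:03d}", chrom, rng))

    # pack genes onto chromosomes with random spacers
    genome: dict[str, str] = {}
    for sg in sim_genes:
        chrom = sg.gene.chrom
        existing = genome.get(chrom, "")
        spacer = _rand_nt(rng, 120)
        _shift_gene(sg.gene, len(existing) + len(spacer))
        genome[chrom] = existing + spacer + sg.chrom_seq

    annotation = GenomeAnnotation()
    for sg in sim_genes:
        annotation.genes[sg.gene.gene_id] = sg.gene
    # non-coding filler gene absorbing the TPM balance of each sample
    filler_chrom = f"chrS{len(genome) + 1}"
    filler_seq = _rand_nt(rng, 400)
    genome[filler_chrom] = filler_seq
    filler = Gene("GSYNFILL", "GSYNFILL", filler_chrom, "+")
    filler.transcripts.append(
        Transcript("GSYNFILL.t1", "GSYNFILL", filler_chrom, "+", exons=[(50, 350)])
    )
    annotation.genes["GSYNFILL"] = filler

    fixture = Fixture(annotation=annotation, genome=genome, sim_genes=sim_genes)
    fixture.truth_motifs = _truth_motifs_frame(sim_genes)
    tables, truth_ab = simulate_abundance(
        sim_genes, f_grid=f_grid, n_samples=n_samples,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fixture.tables = tables
    fixture.truth_abundance = truth_ab
    return fixture


def _shift_gene(gene: Gene, shift: int) -> None:
    for tx in gene.transcripts:
        tx.exons = [(s + shift, e + shift) for s, e in tx.exons]
        tx.cds_intervals = [(s + shift, e + shift) for s, e in tx.cds_intervals]


def _truth_motifs_frame(sim_genes) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": sg.motif.motif_id,
                "gene_id": sg.gene.gene_id,
                "type": sg.motif.motif_type,
                "scenario": sg.scenario,
                "subtype_target": sg.subtype_target or "",
                "strand": sg.gene.strand,
                "status": sg.status,
                "modes": ";".join(sorted(sg.modes)),
                "aa_start": sg.aa_start,
                "exon_span": sg.exon_span,
                "n_coding_transcripts": len(sg.gene.coding_transcripts()),
                "n_with_motif": len(sg.bearing_transcripts),
                "reference_transcript": sg.reference_transcript,
            }
            for sg in sim_genes
        ]
    )


def simulate_abundance(
    sim_genes: list[SimulatedGene],
    f_grid=DEFAULT_F_GRID,
    n_samples: int = 16,
    seed: int = 0,
    total_range: tuple[float, float] = (0.1, 500.0),
) -> tuple[list[AbundanceTable], pd.DataFrame]:
    """Assign per-sample TPMs realizing planted inclusion fractions.

    For gene g in sample s the motif-bearing isoforms share f_s x T_g
    TPM and the remaining coding isoforms (1 - f_s) x T_g, with T_g
    log-uniform in ``total_range``.  Inclusion fractions cycle
    deterministically through ``f_grid`` (constitutive genes are pinned
    to f = 1); a filler transcript brings each sample to 1e6 TPM.

    Returns the tables and a truth frame (gene_id, sample_id, f,
    total_tpm).
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log(total_range[0]), np.log(total_range[1])
    tables = []
    truth_rows = []
    for s in range(n_samples):
        sample_id = f"sample_{s + 1:02d}"
        tpm: dict[str, float] = {}
        for gi, sg in enumerate(sim_genes):
            coding = sg.gene.coding_transcripts()
            bearing = [t for t in coding if t.transcript_id in sg.bearing_transcripts]
            others = [t for t in coding if t.transcript_id not in sg.bearing_transcripts]
            if not others:  # constitutive gene: only f = 1 is realizable
                f = 1.0
            else:
                f = float(f_grid[(gi + s) % len(f_grid)])
            if f > 0 and not bearing:
                raise SimulationError(
                    f"gene {sg.gene.gene_id}: f={f} with no motif-bearing isoform"
                )
            total = float(np.exp(rng.uniform(lo, hi)))
            for t in bearing:
                tpm[t.transcript_id] = f * total / len(bearing)
            for t in others:
                tpm[t.transcript_id] = (1 - f) * total / len(others)
            truth_rows.append(
                {"gene_id": sg.gene.gene_id, "sample_id": sample_id,
                 "f": f, "total_tpm": total}
            )
        assigned = sum(tpm.values())
        if assigned > 1e6:
            raise SimulationError("assigned TPM exceeds 1e6; reduce gene count")
        tpm["GSYNFILL.t1"] = 1e6 - assigned
        tables.append(
            AbundanceTable(sample_id=sample_id, tpm=pd.Series(tpm).sort_index())
        )
    return tables, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fixture(fixture: Fixture, out_dir) -> dict[str, Path]:
    """Write the fixture as GTF + FASTAs + TSVs; returns the paths.

    Output is byte-deterministic for a given fixture (fixed float
    formats, sorted iteration orders).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "genes.gtf",
        "genome": out / "genome.fa",
        "proteins": out / "proteins.fa",
        "motifs": out / "motifs.tsv",
        "manifest": out / "manifest.tsv",
        "truth_motifs": out / "truth_motifs.tsv",
        "truth_abundance": out / "truth_abundance.tsv",
    }
    _write_gtf(fixture, paths["gtf"])
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(fixture.genome):
            fh.write(f">{chrom}\n")
            seq = fixture.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["proteins"], "w") as fh:
        for tx in fixture.annotation.coding_transcripts():
            fh.write(f">{tx.transcript_id}\n{tx.protein_seq}\n")
    with open(paths["motifs"], "w") as fh:
        fh.write("motif_id\tgene_id\ttype\tsequence\tstart\tsubtype_hint\tsource\n")
        for m in fixture.motif_rows():
            fh.write(
                f"{m.motif_id}\t{m.gene_id}\t{m.motif_type}\t{m.aa_seq}\t"
                f"{m.annotated_start}\t{m.subtype_hint or ''}\t{m.source}\n"
            )
    if fixture.truth_motifs is not None:
        fixture.truth_motifs.to_csv(paths["truth_motifs"], sep="\t", index=False)
    if fixture.truth_abundance is not None:
        fixture.truth_abundance.to_csv(
            paths["truth_abundance"], sep="\t", index=False, float_format="%.6f"
        )
    tx_len = {
        t.transcript_id: sum(e - s for s, e in t.exons)
        for t in fixture.annotation.transcripts()
    }
    with open(paths["manifest"], "w") as fh:
        fh.write("sample_id\tpath\n")
        for table in fixture.tables:
            sdir = out / "samples" / table.sample_id
            sdir.mkdir(parents=True, exist_ok=True)
            ab = sdir / "abundance.tsv"
            with open(ab, "w") as afh:
                afh.write("target_id\tlength\teff_length\test_counts\ttpm\n")
                for tid in table.tpm.index:
                    ln = tx_len.get(tid, 300)
                    eff = max(ln - 150, 10)
                    tpmv = table.tpm[tid]
                    afh.write(
                        f"{tid}\t{ln}\t{eff}\t{tpmv * eff / 1000:.3f}\t{tpmv:.6f}\n"
                    )
            fh.write(f"{table.sample_id}\tsamples/{table.sample_id}/abundance.tsv\n")
    return paths


def _write_gtf(fixture: Fixture, path) -> None:
    def attrs(gene, tx=None, extra=""):
        a = f'gene_id "{gene.gene_id}"; gene_name "{gene.name}";'
        if tx is not None:
            a += f' transcript_id "{tx.transcript_id}";'
        return a + extra

    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for gid in sorted(fixture.annotation.genes):
            gene = fixture.annotation.genes[gid]
            g_start = min(t.exons[0][0] for t in gene.transcripts)
            g_end = max(t.exons[-1][1] for t in gene.transcripts)
            fh.write(
                f"{gene.chrom}\tsynthetic\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{gene.strand}\t.\t{attrs(gene)}\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    f"{gene.chrom}\tsynthetic\ttranscript\t{tx.exons[0][0] + 1}\t"
                    f"{tx.exons[-1][1]}\t.\t{gene.strand}\t.\t{attrs(gene, tx)}\n"
                )
                exons_tx = tx.exons_tx_order()
                for num, (s, e) in enumerate(exons_tx, start=1):
                    exon_attr = ' exon_number "%d";' % num
                    fh.write(
                        f"{gene.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs(gene, tx, exon_attr)}\n"
                    )
                if tx.is_coding:
                    _write_cds_features(fh, gene, tx, attrs)


def _write_cds_features(fh, gene, tx, attrs) -> None:
    """Emit CDS rows (stop codon excluded) plus a stop_codon row."""
    ivs = tx.cds_intervals if gene.strand == "+" else list(reversed(tx.cds_intervals))
    # peel the stop codon (last 3 nt in transcription order; within one exon)
    if gene.strand == "+":
        last_s, last_e = ivs[-1]
        stop = (last_e - 3, last_e)
        ivs = ivs[:-1] + ([(last_s, last_e - 3)] if last_e - 3 > last_s else [])
    else:
        last_s, last_e = ivs[-1]
        stop = (last_s, last_s + 3)
        ivs = ivs[:-1] + ([(last_s + 3, last_e)] if last_e > last_s + 3 else [])
    phase = 0
    for s, e in ivs:
        fh.write(
            f"{gene.chrom}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t"
            f"{phase}\t{attrs(gene, tx)}\n"
        )
        phase = (3 - ((e - s) - phase) % 3) % 3
    fh.write(
        f"{gene.chrom}\tsynthetic\tstop_codon\t{stop[0] + 1}\t{stop[1]}\t.\t"
        f"{gene.strand}\t0\t{attrs(gene, tx)}\n"
    )
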