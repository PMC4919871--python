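"""Gene annotation model and protein-to-genome coordinate mapping.

Loads an Ensembl-dialect GTF together with genome and/or protein FASTA
files into a light in-memory object model (genes holding coding
transcripts with ordered exons and CDS bounds), and converts 1-based
protein residue intervals into 0-based half-open genomic intervals,
split across exons.  A BED12 writer emits browser tracks of mapped
motifs (NLS red, NES blue).

Conventions
-----------
* Genomic intervals are 0-based half-open; GTF input/output is 1-based
  inclusive; BED output is 0-based half-open.
* Protein residue positions are 1-based.
* A transcript's stored CDS includes the stop codon; the stop codon is
  excluded from the protein-coding mapping space, so a protein of L
  residues maps to exactly 3L coding nucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger("motifinc.annotation")

Interval = tuple[int, int]

#: GTF tags marking transcripts truncated at either end.
INCOMPLETE_TAGS = frozenset({"cds_start_NF", "cds_end_NF", "mRNA_start_NF", "mRNA_end_NF"})


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class AnnotationConsistencyError(ValueError):
    """Structurally inconsistent annotation (e.g. CDS outside exons)."""


class ProteinMismatchError(ValueError):
    """Supplied protein sequence disagrees with the CDS translation."""


@dataclass
class Transcript:
    """One transcript: ordered exons, CDS bounds and protein sequence.

    ``exons`` and ``cds_intervals`` are stored in ascending genomic
    order; transcription order is derived from ``strand``.
    ``cds_intervals`` include the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_intervals: list[Interval] = field(default_factory=list)
    protein_seq: str = ""
    incomplete: bool = False

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_intervals)

    @property
    def cds_start(self) -> int | None:
        """Leftmost genomic CDS coordinate (strand-agnostic)."""
        return self.cds_intervals[0][0] if self.cds_intervals else None

    @property
    def cds_end(self) -> int | None:
        """Rightmost genomic CDS coordinate, exclusive (strand-agnostic)."""
        return self.cds_intervals[-1][1] if self.cds_intervals else None

    def exons_tx_order(self) -> list[Interval]:
        """Exons ordered 5'→3' in transcription direction."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_nt_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of protein-coding nucleotides, transcription order.

        Excludes the stop codon, so the array has length 3 x (number of
        full codons before the stop) for complete transcripts.
        """
        if not self.cds_intervals:
            return np.empty(0, dtype=np.int64)
        parts = [np.arange(s, e, dtype=np.int64) for s, e in self.cds_intervals]
        pos = np.concatenate(parts)
        if self.strand == "-":
            pos = pos[::-1]
        if not self.incomplete:
            pos = pos[:-3]  # drop stop codon
        else:
            pos = pos[: 3 * (len(pos) // 3)]
        return pos

    def exon_rank_at(self, genomic_pos: int) -> int | None:
        """1-based exon rank (transcription order) containing a position."""
        for rank, (s, e) in enumerate(self.exons_tx_order(), start=1):
            if s <= genomic_pos < e:
                return rank
        return None

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence (exons joined, strand-corrected)."""
        chrom_seq = genome[self.chrom]
        s = "".join(chrom_seq[a:b] for a, b in self.exons)
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        s = "".join(chrom_seq[a:b] for a, b in self.cds_intervals)
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s


@dataclass
class Gene:
    gene_id: str
    name: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def coding_transcripts(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.is_coding]


@dataclass
class GenomeAnnotation:
    """All genes of an annotation, with transcript-level back-index."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts(self) -> Iterable[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts

    def coding_transcripts(self) -> Iterable[Transcript]:
        for t in self.transcripts():
            if t.is_coding:
                yield t

    def get_transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts():
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class MotifMapping:
    """A motif's footprint on one transcript and the genome.

    ``aa_start``/``aa_end`` are 1-based inclusive residue positions;
    ``genomic_intervals`` are 0-based half-open, ascending genomic
    order; ``exon_indices`` are 1-based exon ranks in transcription
    order.
    """

    motif_id: str
    transcript_id: str
    aa_start: int
    aa_end: int
    nt_interval_in_transcript: Interval
    genomic_intervals: list[Interval]
    exon_indices: set[int]
    chrom: str = ""
    strand: str = "+"
    motif_type: str | None = None

    @property
    def n_exons(self) -> int:
        return len(self.exon_indices)


# ---------------------------------------------------------------------------
# GTF / FASTA loading
# ---------------------------------------------------------------------------

def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def _merge_adjacent(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def load_annotation(
    gtf_path,
    genome_fasta=None,
    protein_fasta=None,
    exclude_incomplete: bool = False,
) -> GenomeAnnotation:
    """Load a GTF plus sequence files into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    gtf_path : path-like
        Ensembl-dialect GTF with gene/transcript/exon/CDS features (and
        optional stop_codon features, folded into the stored CDS).
    genome_fasta : path-like, optional
        Genome FASTA; when given, proteins are translated from the CDS.
    protein_fasta : path-like, optional
        Protein FASTA keyed by transcript id; preferred over in-house
        translation when both sources are available, but the two must
        agree (:class:`ProteinMismatchError` otherwise).
    exclude_incomplete : bool
        Drop transcripts flagged truncated at the 5' or 3' end instead
        of retaining them with ``incomplete=True``.

    Raises
    ------
    GTFParseError
        Malformed GTF line (message names the 1-based line number).
    AnnotationConsistencyError
        CDS not contained in the transcript's exons.
    """
    gene_feats: dict[str, object] = {}
    tx_feats: dict[str, object] = {}
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    stops: dict[str, list[Interval]] = {}
    tx_gene: dict[str, str] = {}
    tx_incomplete: dict[str, bool] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - surface with line number
                raise GTFParseError(f"{gtf_path}: line {lineno}: {exc}") from exc
            ftype = feat.featuretype
            if ftype not in ("gene", "transcript", "exon", "CDS", "stop_codon"):
                continue
            gid = _attr(feat, "gene_id")
            if gid is None:
                raise GTFParseError(f"{gtf_path}: line {lineno}: missing gene_id")
            iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
            if ftype == "gene":
                gene_feats[gid] = feat
                continue
            tid = _attr(feat, "transcript_id")
            if tid is None:
                raise GTFParseError(f"{gtf_path}: line {lineno}: missing transcript_id")
            tx_gene[tid] = gid
            if ftype == "transcript":
                tx_feats[tid] = feat
                tags = feat.attributes.get("tag", [])
                tx_incomplete[tid] = bool(INCOMPLETE_TAGS & set(tags))
            elif ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif ftype == "CDS":
                cds.setdefault(tid, []).append(iv)
            elif ftype == "stop_codon":
                stops.setdefault(tid, []).append(iv)

    genome = _read_fasta(genome_fasta) if genome_fasta else None
    proteins = _read_fasta(protein_fasta) if protein_fasta else None

    ann = GenomeAnnotation()
    for gid, gfeat in gene_feats.items():
        ann.genes[gid] = Gene(
            gene_id=gid,
            name=_attr(gfeat, "gene_name") or gid,
            chrom=gfeat.seqid,
            strand=gfeat.strand,
        )

    n_dropped = 0
    for tid, tfeat in tx_feats.items():
        gid = tx_gene[tid]
        if gid not in ann.genes:  # transcript without gene feature
            ann.genes[gid] = Gene(gid, gid, tfeat.seqid, tfeat.strand)
        gene = ann.genes[gid]
        tx = Transcript(
            transcript_id=tid,
            gene_id=gid,
            chrom=tfeat.seqid,
            strand=tfeat.strand,
            exons=sorted(exons.get(tid, [])),
            cds_intervals=_merge_adjacent(cds.get(tid, []) + stops.get(tid, [])),
            incomplete=tx_incomplete.get(tid, False),
        )
        if tx.is_coding:
            _check_cds_in_exons(tx)
            if tx.cds_nt_length() % 3 != 0 and not tx.incomplete:
                logger.warning(
                    "transcript %s: CDS length %d not a multiple of 3; "
                    "flagging incomplete", tid, tx.cds_nt_length(),
                )
                tx.incomplete = True
            _attach_protein(tx, genome, proteins)
        if exclude_incomplete and tx.incomplete:
            n_dropped += 1
            logger.info("dropping incomplete transcript %s", tid)
            continue
        gene.transcripts.append(tx)
    if n_dropped:
        logger.info("dropped %d incomplete transcripts", n_dropped)
    return ann


def _check_cds_in_exons(tx: Transcript) -> None:
    for cs, ce in tx.cds_intervals:
        if not any(es <= cs and ce <= ee for es, ee in tx.exons):
            raise AnnotationConsistencyError(
                f"transcript {tx.transcript_id}: CDS interval "
                f"[{cs},{ce}) not contained in any exon"
            )


def _translate_cds(tx: Transcript, genome: Mapping[str, str]) -> str:
    nt = tx.cds_sequence(genome)
    nt = nt[: 3 * (len(nt) // 3)]
    aa = str(Seq(nt).translate())
    return aa[:-1] if aa.endswith("*") else aa


def _attach_protein(tx, genome, proteins) -> None:
    translated = _translate_cds(tx, genome) if genome else None
    supplied = proteins.get(tx.transcript_id) if proteins else None
    if supplied is not None and translated is not None and supplied != translated:
        raise ProteinMismatchError(
            f"transcript {tx.transcript_id}: supplied protein differs "
            f"from CDS translation"
        )
    tx.protein_seq = supplied if supplied is not None else (translated or "")


# ---------------------------------------------------------------------------
# Protein -> genome mapping
# ---------------------------------------------------------------------------

def protein_interval_to_genomic(
    transcript: Transcript,
    aa_start: int,
    aa_end: int,
    motif_id: str = "",
    motif_type: str | None = None,
) -> MotifMapping:
    """Map residues ``aa_start..aa_end`` (1-based, inclusive) to the genome.

    Returns the motif's genomic codon footprint split across exons, the
    1-based exon ranks (transcription order) it touches, and its
    nucleotide interval within the mature transcript's coding region.
    """
    if not transcript.is_coding:
        raise ValueError(f"transcript {transcript.transcript_id} is non-coding")
    pos = transcript.coding_positions()
    n_res = len(pos) // 3
    if not (1 <= aa_start <= aa_end):
        raise ValueError(f"invalid residue interval {aa_start}..{aa_end}")
    if aa_end > n_res:
        raise ValueError(
            f"residue interval {aa_start}..{aa_end} beyond protein length "
            f"{n_res} of {transcript.transcript_id}"
        )
    lo, hi = 3 * (aa_start - 1), 3 * aa_end
    sub = pos[lo:hi]
    sub_sorted = np.sort(sub)
    intervals: list[Interval] = []
    run_start = prev = int(sub_sorted[0])
    for p in sub_sorted[1:]:
        p = int(p)
        if p != prev + 1:
            intervals.append((run_start, prev + 1))
            run_start = p
        prev = p
    intervals.append((run_start, prev + 1))
    ranks = {transcript.exon_rank_at(int(sub[0]))}
    for p in (int(x) for x in sub):
        ranks.add(transcript.exon_rank_at(p))
    ranks.discard(None)
    return MotifMapping(
        motif_id=motif_id,
        transcript_id=transcript.transcript_id,
        aa_start=aa_start,
        aa_end=aa_end,
        nt_interval_in_transcript=(lo, hi),
        genomic_intervals=intervals,
        exon_indices=ranks,  # type: ignore[arg-type]
        chrom=transcript.chrom,
        strand=transcript.strand,
        motif_type=motif_type,
    )


# ---------------------------------------------------------------------------
# BED12 track output
# ---------------------------------------------------------------------------

_TRACK_COLORS = {"NLS": "255,0,0", "NES": "0,0,255"}  # red / blue


def write_motif_track(mappings: Sequence[MotifMapping | None], out_path) -> int:
    """Write one BED12 record per mapped motif; returns records written.

    NLS records are colored red and NES records blue.  ``None`` entries
    (motifs with no mapping) are skipped with a warning.
    """
    n = 0
    with open(out_path, "w") as fh:
        fh.write('track name="motifs" itemRgb="On"\n')
        for m in mappings:
            if m is None or not m.genomic_intervals:
                logger.warning("skipping motif with no mapping in BED output")
                continue
            chrom_start = m.genomic_intervals[0][0]
            chrom_end = m.genomic_intervals[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.genomic_intervals)
            starts = ",".join(str(s - chrom_start) for s, _ in m.genomic_intervals)
            color = _TRACK_COLORS.get(m.motif_type or "", "128,128,128")
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        m.motif_id or m.transcript_id,
                        "0",
                        m.strand,
                        str(chrom_start),
                        str(chrom_end),
                        color,
                        str(len(m.genomic_intervals)),
                        sizes + ",",
                        starts + ",",
                    ]
                )
                + "\n"
            )
            n += 1
    return n
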