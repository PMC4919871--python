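# Methods

## Problem and model

Protein targeting motifs (NLS, NES) are short linear peptides whose
presence in a protein is fixed at the transcript level: an isoform
either encodes the motif or it does not. The package models a gene as
a set of coding transcripts (ordered exons, CDS bounds, protein
sequence) and a motif as a curated amino-acid string attached to a
gene. Three questions are answered in sequence:

1. **Where is the motif?** The motif is located in a reference
   protein, its residue interval converted to transcript and genomic
   coordinates, and the number of exons it spans counted.
2. **How is its inclusion regulated?** Presence in an isoform is a
   contiguous-substring test on the isoform's protein. A motif present
   in all coding isoforms is constitutive; otherwise each absence is
   attributed to alternative initiation, alternative termination,
   alternative splicing of the motif-coding region, and/or a reading
   frame shift.
3. **How much of the gene's output carries it?** The motif inclusion
   index (MII) is the TPM fraction of the gene's coding transcripts
   containing the motif, per sample.

## Coordinate conventions

Genomic intervals are 0-based half-open internally; GTF input/output
is 1-based inclusive and BED output 0-based half-open. Protein
positions are 1-based. The stored CDS includes the stop codon, but the
stop codon is excluded from the protein-coding mapping space, so a
protein of L residues corresponds to exactly 3L coding nucleotides.
On the minus strand, genomic intervals are reported in ascending
genomic order while exon ranks and 5′/3′ comparisons follow
transcription direction.

The relative position of a motif in its protein is P/(Lp − Lm) with P
the 0-based position of the first motif residue: the zero-based
convention makes the statistic span exactly [0, 1], with 0 for a motif
starting at residue 1 and 1 for a motif ending at the final residue.
A motif covering the whole protein returns 0 by convention (logged).

## Regulation-mode conditions

All four conditions are evaluated against the motif's genomic coding
footprint, taken from the longest coding isoform containing the motif
(ties broken by transcript id; deterministic). For a motif-lacking
coding transcript with first/last coding bases t_first/t_last
(transcription direction) and motif first/last coding bases
m_first/m_last:

* `alt_init`: t_first strictly 3′ of m_first.
* `alt_term`: t_last strictly 5′ of m_last.
* `alt_splice`: at least one motif base missing from the transcript's
  exon union while the CDS span covers the motif locus (so absences
  already explained by a shifted start or end are not double-counted
  as splicing).
* `frameshift`: every motif base present within the transcript's
  coding exons, but the distance in coding nucleotides from the
  transcript's own start codon to m_first is not ≡ 0 (mod 3).

Conditions are recorded non-exclusively, since one gene can combine
mechanisms (e.g. one isoform truncated before the motif and another
including it out of frame). An absence matched by no condition —
possible only when isoform and reference disagree in sequence at the
motif locus — is flagged `unexplained` rather than forced into a
class. Transcription and translation initiation are a single merged
`alt_init` mode: without ribosome profiling the two cannot be
distinguished from annotation alone. Non-coding isoforms are ignored
throughout; all definitions quantify over coding transcripts.

Transcripts flagged 5′/3′-incomplete (`cds_start_NF`-style tags, or a
CDS length not divisible by 3) are retained but flagged; an
`exclude_incomplete` switch drops them. When both a protein FASTA and
a genome FASTA are given, the supplied protein is preferred but must
equal the CDS translation (hard error otherwise).

## NLS subtypes

* **Bipartite**: two adjacent basic residues (K/R), a spacer of
  exactly 10 residues, and at least three basic residues in the five
  positions after the spacer, anywhere in the motif. A configuration
  option widens the spacer to 10–12 residues for the looser classical
  linker definition; the strict 10 is the default.
* **Monopartite**: the contiguous 4-residue consensus K-(K/R)-X-(K/R)
  anywhere in the motif.
* **PY-NLS**: taken from curated annotation (a `subtype_hint` column
  or an explicit id list), not from a sequence pattern — the class has
  no usable consensus.
* Everything else is non-classified.

A motif matching several patterns is assigned by the precedence
PY > bipartite > monopartite (configurable); the individual pattern
matchers are exposed separately so non-exclusive counts remain
available.

## Single-exon resampling null

Observed statistic: the fraction of motifs entirely encoded in one
exon (on the reference isoform). Null: each of R replicates draws
|catalog| protein subsequences with the catalog's own length multiset,
choosing a protein uniformly from the whole annotated proteome
(proteins shorter than the drawn length are rejected and redrawn) and
a start position uniformly among valid positions. The empirical
p-value uses the add-one correction p = (1 + #{null ≥ obs})/(R + 1),
which avoids zero p-values and is exactly uniform (conservatively
super-uniform at ties) when the observed data arise from the null.
R defaults to 999; the seed is a required argument.

Calibration is verified by a matched-null experiment: pseudo-motifs
are planted by the resampler's own procedure and the p-value
distribution compared to uniform. The calibration default plants 500
pseudo-motifs of lengths 4–12 per simulation: the planted count only
controls the granularity of the test statistic (larger counts reduce
tie mass in the discrete null), and lengths 4–12 keep single-exon
probabilities in a mid range on the compact synthetic gene models.

## MII and detection

MII is the ratio of summed TPM of motif-bearing coding transcripts to
summed TPM of all coding transcripts; non-coding isoform abundance
enters neither sum. A gene is `UNDETECTED` in a sample when its total
coding abundance is ≤ 1 TPM (strictly-above rule, so exactly 1 TPM is
undetected); for multi-sample matrices a gene is kept when detected in
at least ⌈9/16 × n_samples⌉ samples, generalizing a 9-of-16 tissue
rule as a fraction. Motifs with MII above 0.95 in every detected
sample are flagged constitutive-like (the flag uses detected samples
only). Profile collapsing of same-gene same-type motifs uses exact
equality after rounding to 6 decimals, matching the abundance files'
write precision. Kallisto-style transcript version suffixes (".N") are
stripped on load; abundance entries for unknown transcripts are
ignored with a logged count.

## Co-regulation

Gene-level status for multi-motif genes is conservative: a gene's NLS
side is constitutive only if *all* its NLSs are constitutive. The
joint 2×2 table (NLS status × NES status over dual-motif genes) is
tested with the two-sided Fisher's exact test; the odds ratio reported
is the sample cross-product estimate with the Haldane 0.5 correction
when a cell is zero. Complete co-regulation of a gene's NLS and NES
requires |MII_NLS − MII_NES| ≤ ε in every sample where both are
defined (ε = 1e-6 by default, configurable); whether both motifs map
to the same exon set of the reference isoform is reported as a
separate signal, since identical profiles and shared exons are logically
independent observations.

## Synthetic data generator

The generator emulates the full input stack: multi-isoform gene
models, planted motif peptides, curated-catalog TSV, and per-sample
abundance tables with specified inclusion fractions. Each gene is
built in transcription-sense coordinates from explicit segments
(UTRs of 24 nt, introns of 48 nt, coding exons assembled from random
flank peptides and the motif peptide with codons drawn uniformly among
synonymous options) and then placed on the genome, reverse-
complemented for minus-strand genes. One builder exists per scenario;
the frameshift builder splits an exon boundary 1–2 nt into a codon and
rejection-samples codon choices until the shifted frame is stop-free
through the motif and terminates at a downstream stop.

Guarantees enforced by construction plus verification (with
resampling on failure): the motif peptide occurs exactly once in each
bearing protein and never in non-bearing proteins; flanking peptides
of NLS genes contain no basic residues, so the planted subtype cannot
be contaminated by flank-borne patterns; every annotated CDS
translates cleanly (single terminal stop).

The default fixture is 64 genes — 8 scenarios × 2 motif types ×
2 strands × 2 replicates — on 8 chromosomes, with 16 samples
mirroring the shape of a multi-tissue RNA-seq panel; the dual-mechanism
`multi_mode` scenario is additionally available through the API and is
exercised by the tests. Abundances realize planted inclusion
fractions exactly: motif-bearing isoforms share f × T of the gene
total T, the rest share (1 − f) × T, with T log-uniform in
[0.1, 500] TPM so that a realistic minority of gene-samples falls
below the 1 TPM detection cutoff; fractions cycle deterministically
through {0, 0.016, 0.39, 0.5, 0.75, 0.88, 0.95, 1} (values spanning
the practically observed range, including near-boundary ones), with
constitutive genes pinned to 1. A non-coding filler transcript
absorbs the remainder so each sample sums to 10⁶ TPM, as a TPM column
must. TPM values are written with 6 decimals; recovery tolerance is
set accordingly at 1e-5.

## What the synthetic data does and does not show

The generator produces compact genes (tens of residues per protein,
short introns), uniform-random codon usage and flank composition, and
exactly realized inclusion fractions. Passing tests therefore
demonstrate the *logic* of the pipeline — coordinate arithmetic on
both strands, mode attribution, detection cutoffs, formula identities
— not robustness to real-data phenomena it does not emulate:
annotation errors, sequence divergence between isoforms, transcript
quantification noise, version mismatches between annotation releases,
or motifs whose curated sequence differs from the reference proteome.
The `unexplained` flag and the mappability filter are the designed
escape hatches for those cases.

## Numerical choices and degenerate inputs

* Empirical p-values: add-one correction, ties counted in favor of
  the null (conservative).
* KS test for transcript counts: SciPy two-sided two-sample test with
  its default exact/asymptotic switching.
* Fisher's exact test: SciPy's two-sided hypergeometric enumeration,
  cross-checked in the tests against an independent exact-integer
  enumeration for every table with n ≤ 40.
* Relative position of a whole-protein motif: 0 by convention.
* Empty GTF: empty annotation, no error. Malformed GTF lines: parse
  error naming the 1-based line number. CDS outside exons: hard
  consistency error naming the transcript.
* A motif sequence occurring more than once in a protein with no
  annotated start: first occurrence used, ambiguity flagged on the
  record.

## Problem sizes

Defaults are sized for interactive use: the 64-gene fixture builds in
about a second; the resampling null with 999 replicates and the
200-simulation calibration each run in seconds thanks to a flat
per-nucleotide exon-rank index of the proteome; the full test suite
completes in a couple of minutes.
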