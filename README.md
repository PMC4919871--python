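# motifinc

Isoform-level analysis of the pre-translational regulation of protein
targeting motifs — nuclear localization signals (NLS) and nuclear
export signals (NES) — for transcriptomics researchers studying how
alternative transcript structure rewires protein subcellular
localization.

A protein targeting motif is encoded by a specific stretch of a gene's
coding sequence, but most human genes produce several coding isoforms,
and not all of them retain that stretch. `motifinc` maps curated motif
peptides from protein coordinates onto transcripts, exons and the
genome, decides for each motif whether it is **constitutive** (present
in every coding isoform of its gene) or **alternative**, attributes
each absence to one or more pre-translational mechanisms, and
quantifies how much of a gene's expressed output actually carries the
motif in each RNA-seq sample.

## The statistics at the core

**Regulation modes.** For a coding isoform that lacks the motif, the
absence is explained against the motif's genomic coding footprint:

| mode | meaning |
|---|---|
| `alt_init` | the isoform's coding region starts 3′ of the motif's first coding base (alternative transcription/translation initiation) |
| `alt_term` | the coding region ends 5′ of the motif's last coding base (alternative translation termination) |
| `alt_splice` | motif-coding bases are spliced out while the CDS spans the locus (cassette exon, alternative 5′/3′ splice site, intronic exon) |
| `frameshift` | all motif-coding bases are retained but translated in a shifted reading frame |

Conditions are non-exclusive: a motif can be regulated by several
mechanisms at once.

**Motif inclusion index (MII).** For gene *g*, motif *m* and one
sample,

```
MII(g, m) = Σ_{k∈K} A_k / Σ_{n∈N} A_n
```

where *N* is the set of coding transcripts of *g*, *K ⊆ N* those
containing *m*, and *A* a transcript's abundance in TPM (kallisto
`abundance.tsv` input). MII ranges over [0, 1]; genes at or below
1 TPM total are reported `UNDETECTED` in that sample.

Supporting analyses: NLS subtype classification (monopartite
K-(K/R)-X-(K/R); bipartite basic pair + 10-residue spacer + basic
cluster; curated PY-NLS list), an empirical resampling null for
single-exon motif enrichment, gene-weighted relative-position
histograms, Kolmogorov–Smirnov comparison of transcript counts between
constitutive- and alternative-motif genes, and NLS/NES co-regulation
analysis (Fisher's exact test on the joint status table, detection of
identical MII profiles).

Because no public data ships with the package, a first-class synthetic
generator (`motifinc.simulate`) builds complete fixtures — genome
FASTA, Ensembl-dialect GTF, proteins, motif catalog, 16 kallisto-style
abundance tables — in which every regulation scenario is planted by
construction on both strands, with a ground-truth ledger.

## Worked example

Generate a 64-gene synthetic dataset and run the pipeline:

```bash
motifinc simulate --seed 17 --out fixture
motifinc classify --gtf fixture/genes.gtf --genome fixture/genome.fa \
    --proteins fixture/proteins.fa --motifs fixture/motifs.tsv --out regulation.tsv
motifinc stats --gtf fixture/genes.gtf --genome fixture/genome.fa \
    --motifs fixture/motifs.tsv --reps 999 --seed 1
motifinc mii --gtf fixture/genes.gtf --genome fixture/genome.fa \
    --motifs fixture/motifs.tsv --manifest fixture/manifest.tsv --out mii.tsv
```

which prints

```
classified 64 motifs (56 alternative) -> regulation.tsv
single-exon fraction 0.969, empirical p = 0.0010 (999 replicates)
MII matrix 61 motifs x 16 samples -> mii.tsv (8 constitutive-like)
```

Reading the numbers: 56 of the 64 planted motifs are alternative
(8 genes are constitutive scenarios); 96.9 % of motifs are entirely
encoded in one exon, far more than random same-length protein
subsequences of this proteome (empirical p = 0.001 against 999
resampling replicates); 61 of 64 genes pass the detection cutoff
(total > 1 TPM in ≥ 9 of 16 samples) and get an MII row, 8 of which
stay above 0.95 in every detected sample and are flagged
constitutive-like. The first report lines look like

```
motif_id      gene_id  type  status        modes  n_coding_transcripts  n_with_motif
GSYN001:NLS1  GSYN001  NLS   constitutive         2                     2
```

and the MII matrix holds one value per motif and sample (`NA` when the
gene is below 1 TPM):

```
motif         sample_01  sample_02  sample_03
GSYN001:NLS1  1.0        1.0        1.0
GSYN002:NLS1  1.0        NA         NA
```

The same functionality is available as a library
(`motifinc.load_annotation`, `classify_catalog`, `build_mii_matrix`,
…); see `docs/methods.md` for the model details and design choices.

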