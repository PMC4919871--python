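import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifinc.annotation import Gene, GenomeAnnotation, Transcript
from motifinc.catalog import Motif, MotifCatalog
from motifinc.posstats import (
    exon_span_counts,
    length_summary,
    null_pvalue_calibration,
    position_histogram,
    relative_position,
    single_exon_null_test,
    transcript_count_comparison,
)


@pytest.mark.parametrize(
    "p, lp, lm, expected",
    [(0, 100, 10, 0.0), (90, 100, 10, 1.0), (45, 100, 10, 0.5)],
)
def test_relative_position_reference_points(p, lp, lm, expected):
    assert relative_position(p, lp, lm) == expected


def test_relative_position_whole_protein_convention():
    assert relative_position(0, 10, 10) == 0.0


def test_relative_position_rejects_invalid():
    with pytest.raises(ValueError):
        relative_position(95, 100, 10)


@given(st.data())
@settings(max_examples=200, derandomize=True)
def test_relative_position_bounded(data):
    lm = data.draw(st.integers(1, 50))
    lp = data.draw(st.integers(lm + 1, 2000))
    pm = data.draw(st.integers(0, lp - lm))
    assert 0.0 <= relative_position(pm, lp, lm) <= 1.0


def _toy_annotation(proteins_by_gene):
    """Annotation whose transcripts carry given proteins (one exon each)."""
    ann = GenomeAnnotation()
    pos = 0
    for gid, prots in proteins_by_gene.items():
        gene = Gene(gid, gid, "chr1", "+")
        for i, prot in enumerate(prots):
            n = 3 * len(prot) + 3
            gene.transcripts.append(
                Transcript(
                    transcript_id=f"{gid}.t{i}",
                    gene_id=gid,
                    chrom="chr1",
                    strand="+",
                    exons=[(pos, pos + n)],
                    cds_intervals=[(pos, pos + n)],
                    protein_seq=prot,
                )
            )
            pos += n + 10
        ann.genes[gid] = gene
    return ann


def test_position_histogram_splits_gene_weight_across_isoforms():
    # one gene, two isoforms holding the motif at relative 0.1 and 0.9
    motif = "WWWW"
    p1 = "A" * 4 + motif + "A" * 36  # P=4, Lp=44, Lm=4 -> 0.1
    p2 = "A" * 36 + motif + "A" * 4  # P=36 -> 0.9
    ann = _toy_annotation({"g1": [p1, p2]})
    cat = MotifCatalog(motifs=[Motif("m1", "NLS", "g1", motif)])
    h = position_histogram(cat, ann, n_bins=10)
    assert h.total_weight == 1.0
    assert h.weighted_counts[1] == 0.5 and h.weighted_counts[9] == 0.5
    assert h.weighted_counts.sum() == pytest.approx(1.0)


def test_position_histogram_single_isoform_genes_full_weight():
    motif = "WWWW"
    ann = _toy_annotation({"g1": ["A" * 4 + motif + "A" * 36],
                           "g2": ["A" * 36 + motif + "A" * 4]})
    cat = MotifCatalog(
        motifs=[Motif("m1", "NLS", "g1", motif), Motif("m2", "NLS", "g2", motif)]
    )
    h = position_histogram(cat, ann, n_bins=10)
    assert h.total_weight == 2.0
    assert h.weighted_counts[1] == 1.0 and h.weighted_counts[9] == 1.0


def test_histogram_weight_conservation_on_fixture(loaded):
    ann, cat = loaded
    h = position_histogram(cat, ann)
    contributing = {m.gene_id for m in cat}
    assert h.total_weight == len(contributing)
    assert h.weighted_counts.sum() == pytest.approx(h.total_weight)


def test_exon_span_counts_match_planted(loaded, truth):
    ann, cat = loaded
    spans = exon_span_counts(cat, ann)
    for mid, span in spans.items():
        assert span == truth.loc[mid, "exon_span"]


def test_single_exon_null_test_deterministic_under_seed(loaded):
    ann, cat = loaded
    r1 = single_exon_null_test(cat, ann, n_reps=199, seed=7)
    r2 = single_exon_null_test(cat, ann, n_reps=199, seed=7)
    assert r1.empirical_p == r2.empirical_p
    assert np.array_equal(r1.null_fractions, r2.null_fractions)
    assert len(r1.null_fractions) == 199
    assert 0 < r1.empirical_p <= 1


def test_single_exon_enrichment_detected_for_planted_motifs(loaded):
    """Nearly all planted motifs are single-exon by construction, while
    random subsequences of the synthetic proteome straddle junctions
    frequently: the resampling null must flag the enrichment."""
    ann, cat = loaded
    res = single_exon_null_test(cat, ann, n_reps=999, seed=1)
    assert res.observed_single_exon_fraction > 0.9
    assert res.empirical_p <= 0.05


def test_null_test_requires_enough_replicates(loaded):
    ann, cat = loaded
    with pytest.raises(ValueError):
        single_exon_null_test(cat, ann, n_reps=10, seed=0)


def test_null_pvalues_uniform_under_matched_null(loaded):
    """Planting pseudo-motifs by the resampler's own procedure yields
    approximately uniform empirical p-values."""
    ann, _ = loaded
    pvals = null_pvalue_calibration(ann, n_sims=200, n_reps=199, seed=0)
    u = np.sort(pvals)
    n = len(u)
    ks = max(
        float(np.max(np.arange(1, n + 1) / n - u)),
        float(np.max(u - np.arange(0, n) / n)),
    )
    assert ks < 0.1


class _R:
    def __init__(self, gene_id):
        self.gene_id = gene_id


def test_transcript_count_comparison_identical_groups():
    ann = _toy_annotation({f"g{i}": ["AAAW"] for i in range(6)})
    const = [_R(f"g{i}") for i in range(3)]
    alt = [_R(f"g{i}") for i in range(3, 6)]
    res = transcript_count_comparison(const, alt, ann)
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_transcript_count_comparison_disjoint_counts():
    genes = {f"c{i}": ["AAAW"] for i in range(3)}
    genes.update({f"a{i}": ["AAAW"] * 10 for i in range(3)})
    ann = _toy_annotation(genes)
    res = transcript_count_comparison(
        [_R(f"c{i}") for i in range(3)], [_R(f"a{i}") for i in range(3)], ann
    )
    assert res.statistic == 1.0


def test_transcript_count_comparison_planted_effect():
    # alternative-motif genes are built with systematically more isoforms
    rng = np.random.default_rng(0)
    genes = {}
    const_ids, alt_ids = [], []
    for i in range(30):
        genes[f"c{i}"] = ["AAAW"] * int(rng.integers(1, 4))
        const_ids.append(f"c{i}")
        genes[f"a{i}"] = ["AAAW"] * int(rng.integers(4, 12))
        alt_ids.append(f"a{i}")
    ann = _toy_annotation(genes)
    res = transcript_count_comparison(
        [_R(g) for g in const_ids], [_R(g) for g in alt_ids], ann
    )
    assert res.pvalue < 0.05


def test_transcript_count_comparison_empty_group_error():
    ann = _toy_annotation({"g0": ["AAAW"]})
    with pytest.raises(ValueError, match="alternative"):
        transcript_count_comparison([_R("g0")], [], ann)


def test_length_summary_bins_by_type():
    cat = MotifCatalog(
        motifs=[
            Motif("a", "NLS", "g1", "KKKK"),
            Motif("b", "NLS", "g2", "RRRR"),
            Motif("c", "NLS", "g3", "K" * 20),
            Motif("d", "NES", "g4", "LLLL"),
        ]
    )
    s = length_summary(cat)
    assert s["NLS"] == {4: 2, 20: 1}
    assert s["NES"] == {4: 1}
    assert length_summary(MotifCatalog()) == {}
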