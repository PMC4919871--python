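import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motifinc.coregulation import (
    complete_coregulation,
    coregulation_report,
    fisher_exact,
    joint_status_records,
    joint_status_table,
)
from motifinc.inclusion import MIIMatrix
from motifinc.regulation import RegulationRecord
from oracles import fisher_two_sided_oracle


def _rec(gene, mtype, status):
    return RegulationRecord(
        motif_id=f"{gene}:{mtype}", gene_id=gene, motif_type=mtype,
        status=status, modes=frozenset() if status == "constitutive" else frozenset({"alt_init"}),
        n_coding_transcripts=2, n_with_motif=2 if status == "constitutive" else 1,
    )


def test_joint_status_table_counts_dual_motif_genes():
    records = [
        _rec("g1", "NLS", "constitutive"), _rec("g1", "NES", "constitutive"),
        _rec("g2", "NLS", "constitutive"), _rec("g2", "NES", "constitutive"),
        _rec("g3", "NLS", "alternative"), _rec("g3", "NES", "alternative"),
        _rec("g4", "NLS", "constitutive"), _rec("g4", "NES", "alternative"),
        _rec("g5", "NLS", "alternative"),  # NLS only: not a dual-motif gene
    ]
    table = joint_status_table(records)
    assert table.loc["constitutive", "constitutive"] == 2
    assert table.loc["alternative", "alternative"] == 1
    assert table.loc["constitutive", "alternative"] == 1
    assert table.to_numpy().sum() == 4


def test_gene_level_status_is_all_constitutive_rule():
    records = [
        _rec("g1", "NLS", "constitutive"),
        RegulationRecord("g1:NLS2", "g1", "NLS", "alternative",
                         frozenset({"alt_term"}), 3, 1),
        _rec("g1", "NES", "constitutive"),
    ]
    (co,) = joint_status_records(records)
    assert co.nls_status == "alternative" and co.joint_class == "mixed"


def test_concentrated_table_when_all_genes_both_alt():
    records = []
    for i in range(5):
        records += [_rec(f"g{i}", "NLS", "alternative"), _rec(f"g{i}", "NES", "alternative")]
    table = joint_status_table(records)
    assert table.loc["alternative", "alternative"] == 5
    assert table.to_numpy().sum() == 5


def test_planted_concordance_detected_by_fisher():
    records = []
    for i in range(22):
        records += [_rec(f"c{i}", "NLS", "constitutive"), _rec(f"c{i}", "NES", "constitutive")]
    for i in range(22):
        records += [_rec(f"a{i}", "NLS", "alternative"), _rec(f"a{i}", "NES", "alternative")]
    for i in range(6):
        records += [_rec(f"x{i}", "NLS", "constitutive"), _rec(f"x{i}", "NES", "alternative")]
    table = joint_status_table(records)
    _, p = fisher_exact(table)
    assert p < 0.05


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[10, 0], [0, 10]], 2 / 184756),
        ([[5, 5], [5, 5]], 1.0),
        ([[1, 0], [0, 1]], 1.0),
    ],
)
def test_fisher_reference_values(table, expected):
    _, p = fisher_exact(table)
    assert p == pytest.approx(expected, rel=1e-9)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])


def test_fisher_odds_ratio_with_haldane_correction():
    odds, _ = fisher_exact([[10, 0], [0, 10]])
    assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))
    odds2, _ = fisher_exact([[6, 2], [3, 9]])
    assert odds2 == pytest.approx((6 * 9) / (2 * 3))


def test_fisher_matches_enumeration_oracle_on_all_small_tables():
    """Two-sided p agrees with exact hypergeometric enumeration for every
    2x2 table of total size at most 40."""
    n_checked = 0
    for n in range(1, 41):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                a_lo, a_hi = max(0, c1 - r2), min(r1, c1)
                for a in range(a_lo, a_hi + 1):
                    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
                    p_impl = fisher_exact([[a, b], [c, d]])[1]
                    p_oracle = fisher_two_sided_oracle(a, b, c, d)
                    assert p_impl == pytest.approx(p_oracle, rel=1e-7, abs=1e-12), (
                        a, b, c, d,
                    )
                    n_checked += 1
    assert n_checked > 10_000


def _matrix(rows: dict, samples=("s1", "s2", "s3"), gene="g1"):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
    return MIIMatrix(
        values=df,
        detection_params=(1.0, 1),
        row_motifs={k: [k] for k in rows},
        motif_gene={k: gene for k in rows},
    )


def test_identical_profiles_are_completely_coregulated():
    m = _matrix({"g1:NLS1": [0.016, 0.5, 0.88], "g1:NES1": [0.016, 0.5, 0.88]})
    coreg, _ = complete_coregulation("g1", m, eps=0.0)
    assert coreg is True


def test_divergent_profiles_are_not_coregulated():
    # NLS near 1 everywhere, NES low everywhere
    m = _matrix({"g1:NLS1": [0.97, 0.99, 1.0], "g1:NES1": [0.1, 0.2, 0.05]})
    coreg, _ = complete_coregulation("g1", m)
    assert coreg is False


def test_coregulation_symmetric_and_monotone_in_eps():
    m = _matrix({"g1:NLS1": [0.5, 0.6, 0.7], "g1:NES1": [0.5, 0.6001, 0.7]})
    swapped = _matrix({"g1:NES1": [0.5, 0.6, 0.7], "g1:NLS1": [0.5, 0.6001, 0.7]})
    for eps in (0.0, 1e-6, 1e-3, 1e-2):
        a, _ = complete_coregulation("g1", m, eps=eps)
        b, _ = complete_coregulation("g1", swapped, eps=eps)
        assert a == b
    assert complete_coregulation("g1", m, eps=1e-6)[0] is False
    assert complete_coregulation("g1", m, eps=1e-3)[0] is True


def test_no_common_detected_sample_gives_na():
    m = _matrix({"g1:NLS1": [0.5, np.nan, np.nan], "g1:NES1": [np.nan, 0.5, 0.5]})
    coreg, _ = complete_coregulation("g1", m)
    assert coreg is None


def test_coregulation_requires_both_motif_types():
    m = _matrix({"g1:NLS1": [0.5, 0.6, 0.7]})
    with pytest.raises(ValueError):
        complete_coregulation("g1", m)


def test_same_exon_flag_for_shared_cassette_exon(loaded, records, fixture):
    """A gene whose NLS and NES sit in the same cassette exon reports
    complete co-regulation with the same-exon flag set."""
    from motifinc.annotation import GenomeAnnotation
    from motifinc.catalog import MotifCatalog
    from motifinc.regulation import classify_catalog
    from motifinc.simulate import ScenarioSpec, simulate_gene
    from motifinc.inclusion import AbundanceTable, build_mii_matrix

    nls = simulate_gene(ScenarioSpec(scenario="cassette_exon", motif_type="NLS"), seed=2)
    gene = nls.gene
    # plant an NES inside the same cassette exon by appending it to the
    # motif peptide region: reuse the same gene and add a second motif
    # whose sequence is a sub-peptide of the cassette-exon product
    ref = gene.coding_transcripts()[0]
    start = nls.aa_start
    nes_seq = ref.protein_seq[start - 1 : start - 1 + nls.motif.length]
    from motifinc.catalog import Motif

    nes = Motif("g:NES1", "NES", gene.gene_id, nes_seq, annotated_start=start)
    nls.motif.motif_id = "g:NLS1"
    ann = GenomeAnnotation(genes={gene.gene_id: gene})
    cat = MotifCatalog(motifs=[nls.motif, nes])
    recs = classify_catalog(cat, ann)
    tids = [t.transcript_id for t in gene.coding_transcripts()]
    tables = [
        AbundanceTable(
            "s1", pd.Series({tids[0]: 3.0, tids[1]: 1.0})
        )
    ]
    matrix = build_mii_matrix(cat, recs, tables, ann, min_samples=1)
    coreg, same_exons = complete_coregulation(
        gene.gene_id, matrix, catalog=cat, annotation=ann
    )
    assert coreg is True and same_exons is True


def test_coregulation_report_covers_dual_motif_genes(records):
    df = coregulation_report(records)
    # the default fixture plants one motif per gene, so no dual-motif genes
    assert len(df) == 0


def test_fisher_p_matches_scipy_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(50):
        t = rng.integers(0, 30, size=(2, 2))
        assert fisher_exact(t)[1] == pytest.approx(
            stats.fisher_exact(t)[1], rel=1e-12
        )
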