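import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motifinc.annotation import Gene, Transcript
from motifinc.catalog import Motif
from motifinc.inclusion import (
    UNDETECTED,
    AbundanceTable,
    build_mii_matrix,
    compute_mii,
    gene_detected,
    load_abundance,
    load_manifest,
)


def _gene_two_isoforms():
    gene = Gene("g1", "g1", "chr1", "+")
    for i, prot in enumerate(["MAKRKRQV", "MAQV"]):
        n = 3 * len(prot) + 3
        gene.transcripts.append(
            Transcript(f"t{i + 1}", "g1", "chr1", "+", exons=[(0, n)],
                       cds_intervals=[(0, n)], protein_seq=prot)
        )
    return gene, Motif("m1", "NLS", "g1", "KRKR")


def _table(**tpm):
    return AbundanceTable("s1", pd.Series(tpm, dtype=float))


def test_mii_is_tpm_weighted_fraction():
    gene, motif = _gene_two_isoforms()
    assert compute_mii(gene, motif, _table(t1=3.0, t2=1.0)) == pytest.approx(0.75)


def test_mii_is_one_when_all_transcripts_carry_motif():
    gene, motif = _gene_two_isoforms()
    gene.transcripts[1].protein_seq = "MAKRKRV"
    assert compute_mii(gene, motif, _table(t1=0.7, t2=123.0)) == 1.0


def test_low_abundance_gene_is_undetected():
    gene, motif = _gene_two_isoforms()
    assert compute_mii(gene, motif, _table(t1=0.3, t2=0.2)) is UNDETECTED
    # strictly-above rule: exactly 1 TPM total is still undetected
    assert compute_mii(gene, motif, _table(t1=0.5, t2=0.5)) is UNDETECTED
    assert compute_mii(gene, motif, _table(t1=0.6, t2=0.5)) is not UNDETECTED


def test_noncoding_isoform_tpm_excluded():
    gene, motif = _gene_two_isoforms()
    gene.transcripts.append(
        Transcript("t3", "g1", "chr1", "+", exons=[(0, 30)])  # non-coding
    )
    v = compute_mii(gene, motif, _table(t1=3.0, t2=1.0, t3=1000.0))
    assert v == pytest.approx(0.75)


@given(st.floats(min_value=1e-3, max_value=1e4))
@settings(max_examples=50, derandomize=True)
def test_mii_invariant_under_global_rescaling(scale):
    gene, motif = _gene_two_isoforms()
    base = compute_mii(gene, motif, _table(t1=3.0, t2=1.0), min_tpm=0.0)
    scaled = compute_mii(
        gene, motif, _table(t1=3.0 * scale, t2=1.0 * scale), min_tpm=0.0
    )
    assert scaled == pytest.approx(base, abs=1e-12)


@pytest.mark.parametrize("f", [0.0, 0.016, 0.39, 0.5, 0.75, 0.88, 0.95, 1.0])
def test_mii_recovers_constructed_fractions_exactly(f):
    gene, motif = _gene_two_isoforms()
    total = 80.0
    v = compute_mii(gene, motif, _table(t1=f * total, t2=(1 - f) * total))
    assert v == pytest.approx(f, abs=1e-12)


def test_no_coding_transcripts_is_error():
    gene = Gene("g", "g", "chr1", "+")
    gene.transcripts.append(Transcript("t", "g", "chr1", "+", exons=[(0, 30)]))
    with pytest.raises(ValueError):
        compute_mii(gene, Motif("m", "NLS", "g", "KK"), _table(t=1.0))


def _tables_with_gene_totals(totals):
    gene, motif = _gene_two_isoforms()
    tables = [
        AbundanceTable(f"s{i}", pd.Series({"t1": t / 2, "t2": t / 2}))
        for i, t in enumerate(totals)
    ]
    return gene, tables


def test_gene_detected_nine_of_sixteen_rule():
    gene, tables = _tables_with_gene_totals([2.0] * 9 + [0.1] * 7)
    assert gene_detected(gene, tables)
    gene, tables = _tables_with_gene_totals([2.0] * 8 + [0.1] * 8)
    assert not gene_detected(gene, tables)


def test_gene_detected_single_sample_default():
    gene, tables = _tables_with_gene_totals([2.0])
    assert gene_detected(gene, tables)  # ceil(9/16 x 1) = 1
    gene, tables = _tables_with_gene_totals([0.5])
    assert not gene_detected(gene, tables)


def test_load_abundance_strips_version_suffixes(tmp_path):
    p = tmp_path / "abundance.tsv"
    p.write_text(
        "target_id\tlength\teff_length\test_counts\ttpm\n"
        "T1.3\t300\t150\t10\t5.0\nT2\t300\t150\t10\t2.5\n"
    )
    tab = load_abundance(p, sample_id="s")
    assert tab.tpm["T1"] == 5.0 and tab.tpm["T2"] == 2.5


def test_load_abundance_rejects_negative_tpm(tmp_path):
    p = tmp_path / "abundance.tsv"
    p.write_text(
        "target_id\tlength\teff_length\test_counts\ttpm\nT1\t300\t150\t10\t-1\n"
    )
    with pytest.raises(ValueError, match="negative"):
        load_abundance(p)


def test_manifest_round_trip(fixture_dir, fixture):
    tables = load_manifest(fixture_dir["manifest"])
    assert [t.sample_id for t in tables] == [t.sample_id for t in fixture.tables]
    for got, want in zip(tables, fixture.tables):
        common = want.tpm.index.intersection(got.tpm.index)
        assert len(common) == len(want.tpm)
        assert np.allclose(got.tpm[common], want.tpm[common], atol=1e-6)


def test_planted_inclusion_fractions_recovered_from_files(
    loaded, records, fixture, fixture_dir
):
    """MII computed from the written abundance tables equals the planted
    per-sample inclusion fraction to within the 6-decimal TPM rounding."""
    ann, cat = loaded
    tables = {t.sample_id: t for t in load_manifest(fixture_dir["manifest"])}
    truth_ab = fixture.truth_abundance.set_index(["gene_id", "sample_id"])
    rec_by_motif = {r.motif_id: r for r in records}
    n_checked = 0
    for motif in cat:
        rec = rec_by_motif[motif.motif_id]
        presence = {c.transcript_id: c.present for c in rec.calls}
        gene = ann.genes[motif.gene_id]
        for sid, tab in tables.items():
            t = truth_ab.loc[(motif.gene_id, sid)]
            v = compute_mii(gene, motif, tab, presence_calls=presence)
            if t["total_tpm"] <= 1.0:
                assert v is UNDETECTED
            else:
                assert v == pytest.approx(t["f"], abs=1e-5)
                n_checked += 1
    assert n_checked > 500


def test_constitutive_motifs_have_mii_one_everywhere(loaded, records, fixture):
    ann, cat = loaded
    matrix = build_mii_matrix(cat, records, fixture.tables, ann, min_samples=1)
    const_ids = {r.motif_id for r in records if r.status == "constitutive"}
    for mid in const_ids & set(matrix.values.index):
        row = matrix.values.loc[mid].dropna()
        assert (row == 1.0).all()
        assert mid in matrix.const_like


def test_matrix_rows_restricted_to_detected_genes(loaded, records, fixture):
    ann, cat = loaded
    matrix = build_mii_matrix(cat, records, fixture.tables, ann)
    truth_ab = fixture.truth_abundance
    for motif in cat:
        n_det = (
            truth_ab[truth_ab.gene_id == motif.gene_id]["total_tpm"] > 1.0
        ).sum()
        in_matrix = motif.motif_id in matrix.values.index
        assert in_matrix == (n_det >= matrix.detection_params[1])


def test_matrix_values_in_unit_interval(loaded, records, fixture):
    ann, cat = loaded
    matrix = build_mii_matrix(cat, records, fixture.tables, ann, min_samples=1)
    vals = matrix.values.to_numpy()
    finite = vals[~np.isnan(vals)]
    assert ((finite >= 0) & (finite <= 1)).all()


def test_identical_profiles_collapse_into_labeled_row():
    gene = Gene("g1", "g1", "chr1", "+")
    for i, prot in enumerate(["MAKRKRQVWLLW", "MAQV"]):
        n = 3 * len(prot) + 3
        gene.transcripts.append(
            Transcript(f"t{i + 1}", "g1", "chr1", "+", exons=[(0, n)],
                       cds_intervals=[(0, n)], protein_seq=prot)
        )
    from motifinc.annotation import GenomeAnnotation
    from motifinc.catalog import MotifCatalog
    from motifinc.regulation import classify_catalog

    ann = GenomeAnnotation(genes={"g1": gene})
    cat = MotifCatalog(
        motifs=[
            Motif("g1:NLS1", "NLS", "g1", "KRKR"),
            Motif("g1:NLS2", "NLS", "g1", "QVWL"),
        ]
    )
    records = classify_catalog(cat, ann)
    tables = [
        AbundanceTable(f"s{i}", pd.Series({"t1": 3.0, "t2": 1.0})) for i in range(2)
    ]
    matrix = build_mii_matrix(cat, records, tables, ann, collapse=True, min_samples=1)
    assert list(matrix.values.index) == ["g1(g1:NLS1;g1:NLS2)"]
    assert matrix.row_motifs["g1(g1:NLS1;g1:NLS2)"] == ["g1:NLS1", "g1:NLS2"]


def test_duplicate_sample_ids_rejected(loaded, records, fixture):
    ann, cat = loaded
    tables = [fixture.tables[0], fixture.tables[0]]
    with pytest.raises(ValueError, match="duplicate sample ids"):
        build_mii_matrix(cat, records, tables, ann)


def test_matrix_tsv_uses_na_sentinel(loaded, records, fixture, tmp_path):
    ann, cat = loaded
    matrix = build_mii_matrix(cat, records, fixture.tables, ann, min_samples=1)
    out = tmp_path / "mii.tsv"
    matrix.to_tsv(out)
    df = pd.read_csv(out, sep="\t", index_col=0)
    assert df.shape == matrix.values.shape
    assert "NA" in out.read_text()
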