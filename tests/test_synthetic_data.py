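"""Generator contracts: determinism, ground-truth consistency, file round-trips."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from scipy.stats import chisquare

from secmut import io
from secmut.cnv import expected_af, expected_rc
from secmut.msi import polymorphism_count
from secmut.records import AllelicState
from secmut.signatures import build_spectrum
from secmut.somatic_calling import apply_site_filters
from secmut.synthetic_data import (
    SimulationTruth,
    gen_cnv_profile,
    gen_expression_matrix,
    gen_msi_data,
    gen_mutation_catalog,
    gen_signature_catalog,
    gen_variant_records,
)


class TestSimulationTruth:
    def test_exposures_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationTruth(seed=0, signature_exposures={"1": 0.5, "2": 0.4})

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationTruth(seed=0, msi_locus_instability=1.5)


class TestSignatureCatalogGen:
    def test_rows_are_normalized_distributions(self):
        cat = gen_signature_catalog(5, concentration=0.5, seed=0)
        assert cat.matrix.shape == (5, 96)
        np.testing.assert_allclose(cat.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert (cat.matrix >= 0).all()

    def test_sparse_rows_have_low_overlap(self):
        cat = gen_signature_catalog(2, concentration=0.01, seed=1)
        a, b = cat.matrix
        cosine = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosine < 0.2

    def test_determinism(self):
        a = gen_signature_catalog(3, 0.05, seed=9).matrix
        b = gen_signature_catalog(3, 0.05, seed=9).matrix
        np.testing.assert_array_equal(a, b)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            gen_signature_catalog(0, 0.05, seed=0)


class TestMutationCatalogGen:
    def test_indel_only_catalog(self, sparse_catalog):
        records, truth = gen_mutation_catalog(
            sparse_catalog, [0.5, 0.5], n_snv=0, n_indel=5, seed=0
        )
        assert len(records) == 5
        assert all(r.is_indel for r in records)
        assert truth.indel_fraction == 1.0

    def test_unnormalized_exposures_rejected(self, sparse_catalog):
        with pytest.raises(ValueError):
            gen_mutation_catalog(sparse_catalog, [0.6, 0.5], n_snv=10, seed=0)

    def test_pure_signature_spectrum_fits_multinomial(self, sparse_catalog):
        records, _ = gen_mutation_catalog(
            sparse_catalog, [1.0, 0.0], n_snv=1000, seed=2
        )
        observed = build_spectrum(records).counts
        expected = 1000 * sparse_catalog.matrix[0]
        # pool channels with tiny expectation so the chi-square test is valid
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        assert chisquare(obs, exp).pvalue > 0.001

    def test_records_pass_all_filters_by_default(self, sparse_catalog):
        records, _ = gen_mutation_catalog(
            sparse_catalog, [0.5, 0.5], n_snv=50, n_indel=5, seed=3
        )
        assert all(apply_site_filters(r)[0] for r in records)

    def test_determinism(self, sparse_catalog):
        a, _ = gen_mutation_catalog(sparse_catalog, [0.5, 0.5], 100, 10, seed=4)
        b, _ = gen_mutation_catalog(sparse_catalog, [0.5, 0.5], 100, 10, seed=4)
        assert a == b


class TestMsiGen:
    def test_zero_instability_rate_gives_stable_panel(self):
        loci, tumor, normal, unstable = gen_msi_data(200, 0.0, seed=0)
        assert unstable == set()

    def test_truth_labels_match_the_instability_rule(self):
        loci, tumor, normal, unstable = gen_msi_data(300, 0.3, seed=1)
        for locus in loci:
            n_i = polymorphism_count(tumor[locus.locus_id])
            if n_i is None:
                continue
            deemed = n_i > locus.background_mean + 3 * locus.background_sd
            assert deemed == (locus.locus_id in unstable)

    def test_normal_sample_always_stable(self):
        loci, _, normal, _ = gen_msi_data(300, 0.5, seed=2)
        for locus in loci:
            n_i = polymorphism_count(normal[locus.locus_id])
            if n_i is not None:
                assert n_i <= locus.background_mean + 3 * locus.background_sd

    def test_shallow_panel_is_entirely_excluded(self):
        loci, tumor, _, _ = gen_msi_data(100, 0.2, mean_depth=10, seed=3)
        assert all(polymorphism_count(d) is None for d in tumor.values())

    def test_determinism(self):
        a = gen_msi_data(100, 0.2, seed=4)
        b = gen_msi_data(100, 0.2, seed=4)
        assert a[0] == b[0] and a[1] == b[1] and a[3] == b[3]


class TestCnvGen:
    def test_diploid_pure_tumor_profile(self):
        exons, truth = gen_cnv_profile(
            [("chr1", 0, 10_000_000, 1, 1)], 1.0, n_exons=50, seed=0
        )
        rc = np.array([e.rc_mean for e in exons])
        assert abs(rc.mean() - 1.0) < 0.05
        afs = [v for e in exons for v in e.af_t]
        assert 0.5 <= np.mean(afs) < 0.55  # folded majority fractions sit just above 0.5

    def test_cn_loh_at_full_purity_reaches_af_one(self):
        exons, _ = gen_cnv_profile(
            [("chr1", 0, 10_000_000, 2, 0)], 1.0, n_exons=50, seed=1
        )
        afs = [v for e in exons for v in e.af_t]
        assert np.mean(afs) > 0.95
        assert expected_af(AllelicState(2, 0), 1.0) == 1.0
        assert expected_rc(AllelicState(2, 0), 1.0, 2.0) == 1.0

    def test_forward_model_formula_at_half_purity(self):
        exons, _ = gen_cnv_profile(
            [("chr1", 0, 50_000_000, 2, 1)], 0.5, n_exons=400,
            af_noise_sd=0.01, seed=2,
        )
        afs = [v for e in exons for v in e.af_t]
        assert np.mean(afs) == pytest.approx(0.6, abs=0.01)

    def test_invalid_allelic_state_rejected(self):
        with pytest.raises(ValueError):
            gen_cnv_profile([("chr1", 0, 1000, 0, 0)], 1.0)
        with pytest.raises(ValueError):
            gen_cnv_profile([("chr1", 0, 1000, 1, 2)], 1.0)

    def test_determinism(self):
        a, _ = gen_cnv_profile([("chr1", 0, 1_000_000, 2, 1)], 0.7, seed=5)
        b, _ = gen_cnv_profile([("chr1", 0, 1_000_000, 2, 1)], 0.7, seed=5)
        assert a == b


class TestVariantRecordGen:
    def test_no_corruption_passes_everything(self):
        records = gen_variant_records(200, {}, seed=0)
        assert all(r.truth_failed == frozenset() for r in records)
        assert all(apply_site_filters(r)[0] for r in records)

    def test_mq0_corruption_fails_only_mq0(self):
        records = gen_variant_records(200, {"mq0": 1.0}, seed=1)
        for r in records:
            assert r.mq0_reads >= 5
            _, failed = apply_site_filters(r)
            assert failed == {"mq0"}

    def test_sb_rate_half_hits_about_half(self):
        records = gen_variant_records(1000, {"sb": 0.5}, seed=2)
        n_sb = sum("sb" in r.truth_failed for r in records)
        assert abs(n_sb - 500) < 3 * np.sqrt(1000 * 0.25)  # 3 binomial SD

    def test_truth_labels_always_match_the_filter_engine(self):
        spec = {"conf": 0.2, "dp": 0.1, "mq0": 0.1, "sb": 0.2, "mmqs": 0.1,
                "amm": 0.1, "detp": 0.1, "ad": 0.2, "gad": 0.1, "ma": 0.1}
        for r in gen_variant_records(500, spec, seed=3):
            _, failed = apply_site_filters(r)
            assert failed == r.truth_failed

    def test_unknown_filter_name_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            gen_variant_records(10, {"bogus": 1.0})


class TestExpressionGen:
    def test_matrix_shape_and_nonnegativity(self):
        matrix, groups = gen_expression_matrix(500, [("A", 3), ("B", 2)], 1.0, seed=0)
        assert matrix.shape == (500, 5)
        assert (matrix.to_numpy() >= 0).all()
        assert set(groups.values()) == {"A", "B"}

    def test_determinism(self):
        a, _ = gen_expression_matrix(300, [("A", 3)], 1.0, seed=1)
        b, _ = gen_expression_matrix(300, [("A", 3)], 1.0, seed=1)
        assert a.equals(b)


class TestRoundTrips:
    def test_maf_round_trip(self, tmp_path, sparse_catalog):
        records, _ = gen_mutation_catalog(
            sparse_catalog, [0.5, 0.5], n_snv=40, n_indel=5, seed=0
        )
        path = tmp_path / "cat.maf.tsv"
        io.write_maf(records, path)
        assert io.read_maf(path) == records

    def test_variant_record_round_trip_preserves_truth_labels(self, tmp_path):
        records = gen_variant_records(50, {"sb": 0.5, "ma": 0.3}, seed=1)
        path = tmp_path / "var.maf.tsv"
        io.write_maf(records, path)
        assert io.read_maf(path) == records

    def test_vcf_is_readable_by_pysam(self, tmp_path, sparse_catalog):
        records, _ = gen_mutation_catalog(
            sparse_catalog, [0.5, 0.5], n_snv=20, n_indel=3, seed=2
        )
        for r in records:
            apply_site_filters(r)
        path = tmp_path / "cat.vcf"
        io.write_vcf(records, path)
        seen = list(pysam.VariantFile(str(path)))
        assert len(seen) == len(records)
        by_pos = {r.pos: r for r in records}
        for rec in seen:
            orig = by_pos[rec.pos]
            assert rec.ref == orig.ref
            assert rec.alts == (orig.alt,)
            assert rec.info["DPT"] == orig.tumor_depth
            assert list(rec.filter) == ["PASS"]

    def test_msi_tables_round_trip(self, tmp_path):
        loci, tumor, _, _ = gen_msi_data(30, 0.2, seed=3)
        io.write_loci(loci, tmp_path / "loci.tsv")
        io.write_repeat_counts(tumor, tmp_path / "t.tsv", "tumor")
        assert io.read_loci(tmp_path / "loci.tsv") == loci
        assert io.read_repeat_counts(tmp_path / "t.tsv") == tumor

    def test_exon_stats_round_trip(self, tmp_path):
        exons, _ = gen_cnv_profile(
            [("chr1", 0, 2_000_000, 2, 1)], 0.7, n_exons=30, seed=4
        )
        io.write_exon_stats(exons, tmp_path / "exons.tsv")
        back = io.read_exon_stats(tmp_path / "exons.tsv")
        assert len(back) == len(exons)
        for a, b in zip(back, exons):
            assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
            assert a.rc_mean == pytest.approx(b.rc_mean, rel=1e-5)
            assert a.af_t == pytest.approx(b.af_t, rel=1e-4)

    def test_expression_round_trip(self, tmp_path):
        matrix, _ = gen_expression_matrix(50, [("A", 3)], 1.0, seed=5)
        io.write_expression(matrix, tmp_path / "expr.tsv")
        back = io.read_expression(tmp_path / "expr.tsv")
        np.testing.assert_allclose(back.to_numpy(), matrix.to_numpy(), rtol=1e-9)

    def test_truth_sidecar_round_trip(self, tmp_path):
        truth = SimulationTruth(
            seed=7,
            signature_exposures={"1": 0.6, "2": 0.4},
            indel_fraction=0.2,
            purity_alpha=0.7,
            tumor_ploidy=2.1,
            segment_truth=[("chr1", 0, 1000, 2, 1)],
        )
        io.write_truth(truth, tmp_path / "truth.json")
        assert io.read_truth(tmp_path / "truth.json") == truth
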