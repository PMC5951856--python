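"""Genotype-pair calling and the ten-rule site filter engine."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import binom

from secmut.records import MutationRecord
from secmut.somatic_calling import (
    FILTER_NAMES,
    GENOTYPES,
    PairPriors,
    PileupSite,
    apply_site_filters,
    call_site,
    classify_genotype_pair,
    genotype_likelihoods,
    strand_bias_pvalue,
)

from conftest import make_reads, make_snv


# ---------------------------------------------------------------------------
# Genotype likelihoods
# ---------------------------------------------------------------------------

class TestGenotypeLikelihoods:
    def test_all_ref_reads_argmax_hom_ref(self):
        lls = genotype_likelihoods(make_reads("A" * 20))
        assert GENOTYPES[int(np.argmax(lls))] == "AA"

    def test_balanced_reads_argmax_het(self):
        lls = genotype_likelihoods(make_reads("A" * 10 + "T" * 10))
        assert GENOTYPES[int(np.argmax(lls))] == "AT"

    def test_fewer_than_eight_reads_skips_site(self):
        assert genotype_likelihoods(make_reads("A" * 7)) is None

    def test_duplicates_and_low_mapq_do_not_qualify(self):
        reads = make_reads("A" * 7)
        reads += [r for r in make_reads("A" * 5, mq=10)]  # below MQ20
        dup = make_reads("A")[0]
        dup.is_duplicate = True
        reads.append(dup)
        assert genotype_likelihoods(reads) is None

    def test_site_skipped_when_normal_underpowered(self):
        site = PileupSite(
            "chr1", 100, "A",
            tumor_reads=make_reads("A" * 10 + "T" * 10),
            normal_reads=make_reads("A" * 7),
        )
        assert call_site(site) is None


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def _pair_posterior_oracle(t_lls, n_lls, ref, priors: PairPriors):
    """Brute-force enumeration of the 100 genotype pairs, written from scratch."""
    nonref = priors.het_rate / 100
    log_rows = []
    for i, gn in enumerate(GENOTYPES):
        if gn == ref * 2:
            pn = 1.0 - priors.het_rate - nonref
        elif ref in gn:
            pn = priors.het_rate / 3
        else:
            pn = nonref / 6
        for j, gt in enumerate(GENOTYPES):
            pt = 1 - priors.somatic_rate if gt == gn else priors.somatic_rate / 9
            log_rows.append(
                math.log(pn) + math.log(pt) + n_lls[i] + t_lls[j]
            )
    log_rows = np.array(log_rows)
    post = np.exp(log_rows - logsumexp(log_rows)).reshape(10, 10)
    return post


class TestPairClassification:
    def test_identical_het_genotypes_are_germline(self):
        site = PileupSite(
            "chr1", 100, "A",
            tumor_reads=make_reads("A" * 10 + "T" * 10),
            normal_reads=make_reads("A" * 10 + "T" * 10),
        )
        call = call_site(site)
        assert call.category == "germline"
        assert call.tumor_genotype == call.normal_genotype == "AT"
        assert call.somatic_score is None

    def test_normal_het_tumor_hom_is_loh(self):
        site = PileupSite(
            "chr1", 100, "A",
            tumor_reads=make_reads("T" * 20),
            normal_reads=make_reads("A" * 10 + "T" * 10),
        )
        call = call_site(site)
        assert call.category == "LOH"
        assert call.tumor_genotype == "TT"

    def test_hom_ref_shortcut_below_two_alt_reads(self):
        site = PileupSite(
            "chr1", 100, "A",
            tumor_reads=make_reads("A" * 19 + "T"),
            normal_reads=make_reads("A" * 20),
        )
        call = call_site(site)
        assert call.category == "hom_ref"

    def test_clear_somatic_scores_high_and_matches_enumeration(self):
        t_lls = genotype_likelihoods(make_reads("A" * 10 + "T" * 10))
        n_lls = genotype_likelihoods(make_reads("A" * 20))
        priors = PairPriors()
        call = classify_genotype_pair(t_lls, n_lls, "A", priors)
        assert call.category == "somatic"
        assert call.somatic_score >= 15

        post = _pair_posterior_oracle(t_lls, n_lls, "A", priors)
        p_equal = float(np.trace(post))
        expected_ss = min(255.0, -10 * math.log10(p_equal))
        assert call.somatic_score == pytest.approx(expected_ss, abs=1e-6)
        # argmax pair agrees with the enumeration
        i, j = np.unravel_index(np.argmax(post), post.shape)
        assert (call.normal_genotype, call.tumor_genotype) == (
            GENOTYPES[i],
            GENOTYPES[j],
        )

    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_posterior_normalizes_and_score_shift_invariant(self, shift, seed):
        rng = np.random.default_rng(seed)
        t_lls = -rng.uniform(0, 30, 10)
        n_lls = -rng.uniform(0, 30, 10)
        call_a = classify_genotype_pair(t_lls, n_lls, "C")
        call_b = classify_genotype_pair(t_lls + shift, n_lls, "C")
        post = _pair_posterior_oracle(t_lls, n_lls, "C", PairPriors())
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert call_a.category == call_b.category
        if call_a.somatic_score is not None:
            assert call_a.somatic_score == pytest.approx(
                call_b.somatic_score, abs=1e-6
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_vanishing_somatic_rate_forbids_somatic_calls(self, seed):
        rng = np.random.default_rng(seed)
        t_lls = -rng.uniform(0, 30, 10)
        n_lls = -rng.uniform(0, 30, 10)
        call = classify_genotype_pair(
            t_lls, n_lls, "A", PairPriors(somatic_rate=0.0)
        )
        assert call.category != "somatic"


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

class TestSiteFilters:
    def test_clean_record_passes(self, clean_record):
        passed, failed = apply_site_filters(clean_record)
        assert passed and failed == frozenset()

    @pytest.mark.parametrize(
        "override, expected",
        [
            ({"somatic_score": 14.0, "genotype_quality": 14.0}, {"conf"}),
            ({"mq0_reads": 5}, {"mq0"}),
            ({"alt_fwd": 12, "alt_rev": 0}, {"sb"}),
            ({"mismatch_quality_sum": 20.5}, {"mmqs"}),
            ({"avg_mismatches": 1.6}, {"amm"}),
            ({"dist_to_3prime": 0.19}, {"detp"}),
            ({"dist_to_3prime": 0.81}, {"detp"}),
            ({"tumor_alt_depth": 3, "alt_fwd": 2, "alt_rev": 1,
              "alt_allele_support": {"T": 3}}, {"ad"}),
            ({"normal_alt_depth": 4}, {"gad"}),
            ({"alt_allele_support": {"T": 30, "G": 2}}, {"ma"}),
        ],
    )
    def test_single_metric_violations(self, clean_record, override, expected):
        rec = dataclasses.replace(clean_record, **override)
        passed, failed = apply_site_filters(rec)
        assert not passed
        assert failed == frozenset(expected)

    def test_conf_either_quality_suffices(self, clean_record):
        rec = dataclasses.replace(
            clean_record, somatic_score=10.0, genotype_quality=20.0
        )
        assert apply_site_filters(rec)[0]

    def test_missing_metric_fails_closed(self, clean_record):
        rec = dataclasses.replace(clean_record, mq0_reads=None)
        passed, failed = apply_site_filters(rec)
        assert not passed and "mq0" in failed

    def test_strand_bias_exact_tail(self):
        # 12 forward / 0 reverse: two-sided exact binomial p = 2 * 0.5**12
        p = strand_bias_pvalue(12, 0)
        assert p == pytest.approx(2 * 0.5**12, rel=1e-9)
        assert p <= 0.005


def _oracle_failed(rec: MutationRecord) -> set[str]:
    """Independent plain-inequality re-evaluation of all ten filters."""
    failed = set()
    quals = [q for q in (rec.genotype_quality, rec.somatic_score) if q is not None]
    if not any(q >= 15 for q in quals):
        failed.add("conf")
    if rec.tumor_depth is None or rec.normal_depth is None or (
        rec.tumor_depth + rec.normal_depth < 4
    ):
        failed.add("dp")
    if rec.mq0_reads is None or rec.mq0_reads >= 5:
        failed.add("mq0")
    if rec.alt_fwd is None or rec.alt_rev is None:
        failed.add("sb")
    else:
        n = rec.alt_fwd + rec.alt_rev
        if n > 0:
            pmf = binom.pmf(np.arange(n + 1), n, 0.5)
            p = pmf[pmf <= pmf[rec.alt_fwd] * (1 + 1e-9)].sum()
            if p <= 0.005:
                failed.add("sb")
    if rec.mismatch_quality_sum is None or rec.mismatch_quality_sum > 20:
        failed.add("mmqs")
    if rec.avg_mismatches is None or rec.avg_mismatches > 1.5:
        failed.add("amm")
    if rec.dist_to_3prime is None or not (0.2 <= rec.dist_to_3prime <= 0.8):
        failed.add("detp")
    if rec.tumor_alt_depth is None or rec.tumor_alt_depth < 4:
        failed.add("ad")
    if rec.normal_alt_depth is None or rec.normal_alt_depth > 3:
        failed.add("gad")
    if rec.alt_allele_support is None or (
        sum(1 for c in rec.alt_allele_support.values() if c >= 2) >= 2
    ):
        failed.add("ma")
    return failed


def fuzz_record(rng: np.random.Generator) -> MutationRecord:
    """Random metrics straddling every filter boundary."""
    depth_t = int(rng.integers(0, 30))
    depth_n = int(rng.integers(0, 30))
    alt_depth = int(rng.integers(0, depth_t + 1))
    n_strand = int(rng.integers(0, 25))
    fwd = int(rng.integers(0, n_strand + 1))
    support = {"T": int(rng.integers(0, 5))}
    if rng.random() < 0.5:
        support["G"] = int(rng.integers(0, 4))
    return make_snv(
        tumor_depth=depth_t,
        normal_depth=depth_n,
        tumor_alt_depth=alt_depth,
        normal_alt_depth=int(rng.integers(0, min(depth_n, 6) + 1)),
        mq0_reads=int(rng.integers(0, 8)),
        alt_fwd=fwd,
        alt_rev=n_strand - fwd,
        mismatch_quality_sum=float(rng.uniform(0, 40)),
        avg_mismatches=float(rng.uniform(0, 3)),
        dist_to_3prime=float(rng.uniform(0, 1)),
        somatic_score=None if rng.random() < 0.1 else float(rng.uniform(0, 40)),
        genotype_quality=None if rng.random() < 0.1 else float(rng.uniform(0, 40)),
        alt_allele_support=support,
    )


def test_filter_engine_agrees_with_brute_force_on_fuzzed_records():
    rng = np.random.default_rng(20240901)
    for _ in range(2000):
        rec = fuzz_record(rng)
        _, failed = apply_site_filters(rec)
        assert failed == _oracle_failed(rec)
        assert failed <= set(FILTER_NAMES)
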