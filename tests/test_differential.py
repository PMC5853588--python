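"""Replicate-intersection differential-editing test and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaincc

import orgedit as oe
from orgedit.differential import TestConfig
from orgedit.errors import ArgumentError, DesignError, InputError


class TestBonferroni:
    def test_reference_family(self):
        alpha = oe.bonferroni_threshold(1e-3, 612)
        assert alpha == pytest.approx(1.634e-6, rel=1e-3)
        assert f"{alpha:.1e}" == "1.6e-06"

    @pytest.mark.parametrize("fam,n,expect", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_division(self, fam, n, expect):
        assert oe.bonferroni_threshold(fam, n) == pytest.approx(expect)

    def test_invalid_arguments(self):
        with pytest.raises(ArgumentError):
            oe.bonferroni_threshold(1e-3, 0)
        with pytest.raises(ArgumentError):
            oe.bonferroni_threshold(1.5, 10)


def _closed_form(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


class TestChisq2x2:
    def test_exact_reference_tables(self):
        stat, p = oe.chisq_2x2(900, 100, 600, 400)
        assert stat == 240.0
        assert p < 1.6e-6
        stat, _ = oe.chisq_2x2(10, 0, 0, 10)
        assert stat == 20.0

    def test_identical_rows_no_evidence(self):
        stat, p = oe.chisq_2x2(50, 50, 50, 50)
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_defined_as_null(self):
        assert oe.chisq_2x2(0, 0, 5, 5) == (0.0, 1.0)
        assert oe.chisq_2x2(5, 5, 0, 0) == (0.0, 1.0)
        assert oe.chisq_2x2(0, 5, 0, 5) == (0.0, 1.0)

    def test_continuity_correction_shrinks_statistic(self):
        plain, _ = oe.chisq_2x2(30, 10, 20, 20)
        yates, _ = oe.chisq_2x2(30, 10, 20, 20, continuity=True)
        assert 0 < yates < plain

    def test_negative_counts_rejected(self):
        with pytest.raises(ArgumentError):
            oe.chisq_2x2(-1, 2, 3, 4)

    def test_oracle_equivalence_1000_random_tables(self):
        # independent oracle: closed-form Pearson statistic and the 1-df
        # upper tail via the regularized incomplete gamma function
        rng = np.random.default_rng(2024)
        tables = rng.integers(0, 5000, size=(1000, 4))
        for a, b, c, d in tables:
            stat, p = oe.chisq_2x2(int(a), int(b), int(c), int(d))
            expect_stat = _closed_form(int(a), int(b), int(c), int(d))
            assert stat == pytest.approx(expect_stat, rel=1e-10, abs=1e-300)
            expect_p = gammaincc(0.5, expect_stat / 2.0) if expect_stat > 0 else 1.0
            assert p == pytest.approx(expect_p, rel=1e-10, abs=1e-300)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.integers(0, 2000), b=st.integers(0, 2000),
           c=st.integers(0, 2000), d=st.integers(0, 2000),
           k=st.integers(2, 20))
    def test_scaling_monotonicity_and_row_symmetry(self, a, b, c, d, k):
        stat, _ = oe.chisq_2x2(a, b, c, d)
        scaled, _ = oe.chisq_2x2(a * k, b * k, c * k, d * k)
        assert scaled >= stat - 1e-9
        swapped, _ = oe.chisq_2x2(c, d, a, b)
        assert swapped == pytest.approx(stat, rel=1e-12, abs=1e-12)


class TestReplicatePvalues:
    def test_four_tests_wildtype_major_order(self):
        wt = [(900, 100), (880, 120)]
        mut = [(600, 400), (620, 380)]
        ps = oe.replicate_pvalues(wt, mut)
        assert len(ps) == 4
        # wildtype-major: (wt1,m1), (wt1,m2), (wt2,m1), (wt2,m2)
        expect = [oe.chisq_2x2(*w, *m)[1] for w in wt for m in mut]
        assert ps == expect

    def test_identical_counts_all_null(self):
        ps = oe.replicate_pvalues([(500, 500)] * 2, [(500, 500)] * 2)
        assert ps == [1.0] * 4

    def test_depth_floor_marks_not_assayed(self):
        assert oe.replicate_pvalues([(40, 40), (500, 500)],
                                    [(500, 500)] * 2,
                                    TestConfig(min_depth=100)) is None

    def test_strong_effect_always_detected(self):
        # true delta 0.4 at depth 2000: all four tests far below threshold
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            wt = [(int(e := rng.binomial(2000, 0.4)), 2000 - e)
                  for _ in range(2)]
            mut = [(int(e := rng.binomial(2000, 0.8)), 2000 - e)
                   for _ in range(2)]
            ps = oe.replicate_pvalues(wt, mut)
            hits += all(p < 1.6e-6 for p in ps)
        assert hits >= 99


class TestEffectDelta:
    def test_pooled_reference_value(self):
        wt = [(900, 100), (880, 120)]
        mut = [(600, 400), (620, 380)]
        assert oe.effect_delta(wt, mut, mode="pooled") == pytest.approx(-0.28)
        assert oe.effect_delta(wt, mut, mode="mean") == pytest.approx(-0.28)

    def test_identical_counts_zero(self):
        assert oe.effect_delta([(50, 50)], [(50, 50)]) == 0.0

    def test_undefined_side_is_nan(self):
        assert math.isnan(oe.effect_delta([(0, 0)], [(10, 10)]))

    def test_modes_differ_under_unequal_depth(self):
        wt = [(90, 10), (400, 600)]   # extents 0.9 and 0.4 at depths 100/1000
        mut = [(500, 500), (500, 500)]
        pooled = oe.effect_delta(wt, mut, mode="pooled")
        mean = oe.effect_delta(wt, mut, mode="mean")
        assert pooled != pytest.approx(mean)


class TestClassifySite:
    CFG = TestConfig(n_tests=612)

    @pytest.mark.parametrize("ps,delta,expect", [
        ([1e-9] * 4, 0.3, "increased"),
        ([1e-9] * 4, -0.3, "decreased"),
        ([1e-9] * 4, 0.05, "invariant"),        # effect floor
        ([1e-9, 1e-9, 1e-3, 1e-9], 0.3, "invariant"),  # all four must pass
        ([1.0] * 4, 0.5, "invariant"),
    ])
    def test_rule(self, ps, delta, expect):
        assert oe.classify_site(ps, delta, self.CFG) == expect

    def test_threshold_is_strict(self):
        alpha = self.CFG.nominal_alpha()
        assert oe.classify_site([alpha] * 4, 0.3, self.CFG) == "invariant"

    def test_empty_pvalues_rejected(self):
        with pytest.raises(ArgumentError):
            oe.classify_site([], 0.3, self.CFG)


class TestClassifyAll:
    def test_recovers_truth_at_depth_2000(self, small_truth, small_matrix):
        res = oe.classify_all(small_matrix, "wildtype", "mutant")
        truth_counts = small_truth.effect_class.value_counts()
        got = res.summary_counts()
        assert got["increased"] == truth_counts.get("increased", 0)
        assert got["decreased"] == truth_counts.get("decreased", 0)

    def test_alpha_uses_assayed_site_count(self, small_matrix):
        res = oe.classify_all(small_matrix, "wildtype", "mutant")
        assert res.alpha_nominal == pytest.approx(1e-3 / res.n_assayed)

    def test_invariant_to_sample_order(self, small_matrix):
        res1 = oe.classify_all(small_matrix, "wildtype", "mutant")
        reordered = small_matrix.select_samples(
            list(small_matrix.sample_ids)[::-1])
        res2 = oe.classify_all(reordered, "wildtype", "mutant")
        assert (res1.table["category"] == res2.table["category"]).all()

    def test_low_depth_site_not_assayed_and_excluded(self, small_matrix):
        m = small_matrix
        edited = m.edited.copy()
        unedited = m.unedited.copy()
        victim = m.site_ids[0]
        edited.loc[victim] = 5
        unedited.loc[victim] = 5
        low = oe.EditingMatrix(edited, unedited, sites=m.sites, design=m.design)
        res = oe.classify_all(low, "wildtype", "mutant")
        assert res.table.loc[victim, "category"] == "not_assayed"
        s = res.summary_counts()
        assert s["not_assayed"] == 1
        assert s["increased"] + s["decreased"] + s["invariant"] == len(m.site_ids) - 1

    def test_missing_wildtype_rejected(self, small_matrix):
        with pytest.raises(DesignError):
            oe.classify_all(small_matrix, "nosuch", "mutant")

    def test_null_intersection_rarely_passes(self, small_frame):
        # under the null the chance that all four pairwise tests pass at
        # alpha_nominal is itself at most alpha_nominal (the tests are
        # positively dependent through shared replicates)
        truth = oe.gen_truth(small_frame, frac_increased=0, frac_decreased=0,
                             seed=50)
        alpha = 0.1
        cfg = TestConfig(alpha_nominal=alpha, min_delta=0.0001, min_depth=1)
        hits = 0
        total = 0
        for b in range(100):
            m = oe.gen_counts(truth, oe.default_design(), depth=500,
                              seed=1000 + b)
            res = oe.classify_all(m, "wildtype", "mutant", config=cfg)
            pcols = [c for c in res.table.columns if c.startswith("p")]
            hits += int((res.table[pcols] < alpha).all(axis=1).sum())
            total += len(res.table)
        assert hits / total <= alpha


class TestIntersect:
    def test_common_and_single_mutant_sets(self, small_truth, small_matrix):
        res_a = oe.classify_all(small_matrix, "wildtype", "mutant")
        small_truth.copy_genotype("mutant", "mutant2")
        m2 = oe.gen_counts(small_truth, oe.default_design(
            genotypes=("wildtype", "mutant2")), depth=2000, seed=77)
        res_b = oe.classify_all(m2, "wildtype", "mutant2")
        inter = oe.intersect_classifications(res_a, res_b)
        # both mutants share the same truth at high depth: intersection
        # equals each single-mutant call set
        assert inter["n_common_increased"] == len(res_a.sites_in("increased"))
        assert inter["n_common_decreased"] == len(res_a.sites_in("decreased"))
        assert not inter["discordant"]

    def test_partial_overlap_bookkeeping(self, small_matrix):
        res_a = oe.classify_all(small_matrix, "wildtype", "mutant")
        res_b = oe.classify_all(small_matrix, "wildtype", "mutant")
        # demote one increased site in B to invariant
        site = res_a.sites_in("increased")[0]
        res_b.table.loc[site, "category"] = "invariant"
        inter = oe.intersect_classifications(res_a, res_b)
        assert site in inter["a_only"]["increased"]
        assert site not in inter["common_increased"]

    def test_mismatched_site_sets_rejected(self, small_matrix):
        res_a = oe.classify_all(small_matrix, "wildtype", "mutant")
        res_b = oe.classify_all(small_matrix, "wildtype", "mutant")
        res_b.table = res_b.table.iloc[1:]
        with pytest.raises(InputError):
            oe.intersect_classifications(res_a, res_b)
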