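import itertools
import math

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from scipy.special import comb as _comb

import coexpair as cx

from coexpair.crosscond import (
    AssociationResult,
    association_table,
    compare_conditions,
    hypergeom_tail,
    hypergeom_tail_log10,
    logistic_association,
    match_modules,
    overlap_table,
    recompute_fixed_membership,
    subgroup_eigengene_test,
)
from coexpair.modules import GREY


def exact_tail(N, K, n, x, strict=False):
    """Exact-rational hypergeometric upper tail via integer binomials."""
    lo = x + 1 if strict else x
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(lo, min(K, n) + 1))
    return Fraction(num, math.comb(N, n))


class TestHypergeomTail:
    def test_exhaustive_enumeration_all_small_instances(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(min(K, n) + 1):
                        expected = float(exact_tail(N, K, n, x))
                        got = hypergeom_tail(N, K, n, x)
                        assert got == pytest.approx(expected, rel=1e-10), (N, K, n, x)

    def test_five_of_five_draw(self):
        assert hypergeom_tail(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(1000, 30, 40, 0) == 1.0

    def test_extreme_tail_matches_exact_rationals(self):
        # genome-scale spot check far below double-precision underflow thresholds
        for x in (100, 105, 110):
            expected = exact_tail(21043, 194, 111, x)
            l10 = hypergeom_tail_log10(21043, 194, 111, x)
            exp_l10 = (math.log10(expected.numerator) - math.log10(expected.denominator))
            assert l10 == pytest.approx(exp_l10, abs=5e-3)

    def test_strict_convention_shifts_support(self):
        assert hypergeom_tail(20, 5, 5, 3, strict=True) == pytest.approx(
            float(exact_tail(20, 5, 5, 4)), rel=1e-10
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 5, 6)


class TestOverlapTable:
    @staticmethod
    def assignments():
        genes = [f"g{i}" for i in range(40)]
        a = pd.Series([GREY] * 40, index=genes, dtype=object)
        a.iloc[:10] = "blue"
        a.iloc[10:22] = "red"
        return genes, a

    def test_identical_assignments_diagonal_full_overlap(self):
        genes, a = self.assignments()
        t = overlap_table(a, a.copy())
        diag = t[t.module_a == t.module_b]
        assert (diag.percent_of_b == 100.0).all()
        off = t[t.module_a != t.module_b]
        assert (off.shared == 0).all()

    def test_disjoint_modules_unsurprising(self):
        genes, a = self.assignments()
        b = pd.Series([GREY] * 40, index=genes, dtype=object)
        b.iloc[22:34] = "green"
        t = overlap_table(a, b)
        assert (t.shared == 0).all()
        assert (t.p > 0.5).all()

    def test_mismatched_universes_rejected(self):
        genes, a = self.assignments()
        b = a.iloc[:30]
        with pytest.raises(ValueError):
            overlap_table(a, b)

    def test_grey_excluded_from_pairs(self):
        genes, a = self.assignments()
        t = overlap_table(a, a.copy())
        assert GREY not in set(t.module_a) | set(t.module_b)


class TestMatchModules:
    def test_identity_assignment_maps_identically(self):
        genes, a = TestOverlapTable.assignments()
        mapping = match_modules(overlap_table(a, a.copy()))
        assert mapping == {"blue": "blue", "red": "red"}

    def test_majority_overlap_wins(self):
        genes = [f"g{i}" for i in range(100)]
        a = pd.Series([GREY] * 100, index=genes, dtype=object)
        a.iloc[:40] = "blue"
        a.iloc[40:60] = "red"
        b = pd.Series([GREY] * 100, index=genes, dtype=object)
        b.iloc[:60] = "merged"  # overlaps blue 40, red 20
        mapping = match_modules(overlap_table(a, b))
        assert mapping["merged"] == "blue"

    def test_split_module_both_halves_map_to_parent(self):
        genes = [f"g{i}" for i in range(120)]
        a = pd.Series([GREY] * 120, index=genes, dtype=object)
        a.iloc[:80] = "blue"
        b = pd.Series([GREY] * 120, index=genes, dtype=object)
        b.iloc[:40] = "left"
        b.iloc[40:80] = "right"
        mapping = match_modules(overlap_table(a, b))
        assert mapping == {"left": "blue", "right": "blue"}


class TestLogisticAssociation:
    def test_null_betas_small_and_p_uniformish(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            me = pd.Series(rng.normal(size=300))
            status = pd.Series(rng.integers(0, 2, size=300))
            res = logistic_association(me, status)
            ps.append(res.wald_p)
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 200)

    def test_one_class_rejected(self):
        me = pd.Series(np.random.default_rng(1).normal(size=20))
        with pytest.raises(ValueError):
            logistic_association(me, pd.Series(np.ones(20)))

    def test_planted_logit_effect_recovered(self):
        rng = np.random.default_rng(2)
        n = 20_000
        me = pd.Series(rng.normal(size=n))
        logit = -0.2 + 1.5 * me
        status = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-logit))))
        res = logistic_association(me, status)
        assert abs(res.beta - 1.5) < 3 * res.se

    def test_aic_matches_independent_loglik(self):
        rng = np.random.default_rng(3)
        me = pd.Series(rng.normal(size=500))
        status = pd.Series(rng.binomial(1, 0.4, size=500))
        res = logistic_association(me, status)
        # independent Bernoulli log-likelihood at the fitted coefficients
        import statsmodels.api as sm

        fit = sm.Logit(status.to_numpy(), sm.add_constant(me.to_numpy())).fit(disp=False)
        eta = fit.params[0] + fit.params[1] * me.to_numpy()
        p = 1 / (1 + np.exp(-eta))
        ll = np.sum(status * np.log(p) + (1 - status) * np.log(1 - p))
        assert res.aic == pytest.approx(4 - 2 * ll, abs=1e-8)

    def test_perfect_separation_flagged(self):
        me = pd.Series(np.r_[np.full(20, -3.0), np.full(20, 3.0)]
                       + np.random.default_rng(4).normal(scale=0.01, size=40))
        status = pd.Series(np.r_[np.zeros(20), np.ones(20)].astype(int))
        res = logistic_association(me, status)
        assert res.separation


class TestCompareConditions:
    @staticmethod
    def result(beta, se, aic, module="m"):
        return AssociationResult(module, "", beta, se, 0.5, aic, 100, 100)

    def test_published_coefficient_pair(self):
        ra = self.result(-1.12, 0.49, 100.0)
        rb = self.result(-1.95, 0.49, 95.0)
        cmpres = compare_conditions(ra, rb)
        # the published figures were computed from unrounded coefficients;
        # recomputation from the printed two-decimal values agrees to 0.01
        assert cmpres.z == pytest.approx(1.19, abs=0.01)
        assert cmpres.one_sided_p == pytest.approx(0.11, abs=0.01)

    def test_delta_aic_to_likelihood_fold(self):
        ra = self.result(0.0, 1.0, 110.5)
        rb = self.result(0.0, 1.0, 100.0)
        cmpres = compare_conditions(ra, rb)
        assert cmpres.delta_aic == pytest.approx(-10.5)
        assert cmpres.likelihood_ratio == pytest.approx(math.exp(10.5 / 2), rel=1e-12)
        assert round(cmpres.likelihood_ratio) == 191  # ~190-fold

    def test_equal_results_are_null_comparison(self):
        ra = self.result(0.7, 0.2, 50.0)
        cmpres = compare_conditions(ra, self.result(0.7, 0.2, 50.0))
        assert cmpres.z == 0.0
        assert cmpres.one_sided_p == pytest.approx(0.5)
        assert cmpres.likelihood_ratio == pytest.approx(1.0)

    def test_separated_input_marks_unavailable(self):
        ra = self.result(0.7, 0.2, 50.0)
        bad = AssociationResult("m", "", math.inf, math.nan, math.nan, math.nan,
                                100, 100, separation=True)
        assert not compare_conditions(ra, bad).available


class TestFixedMembership:
    def test_same_matrix_reproduces_eigengenes(self, small_dataset, detected):
        ds, assign = small_dataset, detected["assign"]
        me, _ = recompute_fixed_membership(ds.expr_base, assign, include_grey=False)
        for mod in detected["me"].columns:
            r = np.corrcoef(me[mod], detected["me"][mod])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_grey_column_included_by_default(self, small_dataset, detected):
        me, _ = recompute_fixed_membership(small_dataset.expr_stim, detected["assign"])
        assert GREY in me.columns

    def test_noise_second_condition_drops_variance_explained(self, detected):
        assign = detected["assign"]
        rng = np.random.default_rng(5)
        noise = pd.DataFrame(rng.normal(size=(len(assign), 120)), index=assign.index,
                             columns=[f"S{j}" for j in range(120)])
        _, ve = recompute_fixed_membership(noise, assign, include_grey=False)
        for mod, v in ve.items():
            size = (assign == mod).sum()
            assert v < 5.0 / size + 0.1  # toward 1/|module|, random-matrix slack

    def test_missing_genes_reported(self, small_dataset, detected):
        truncated = small_dataset.expr_stim.iloc[:-5]
        with pytest.raises(KeyError):
            recompute_fixed_membership(truncated, detected["assign"])


class TestSubgroupEigengene:
    def test_full_module_subset_correlates_perfectly(self, small_dataset, detected):
        ds, assign = small_dataset, detected["assign"]
        mod = assign[assign != GREY].value_counts().idxmax()
        genes = assign.index[assign == mod]
        _, detail = subgroup_eigengene_test(
            ds.expr_base, ds.expr_stim, genes, ds.samples.status, parent_genes=genes
        )
        assert detail["parent_cor_a"] == pytest.approx(1.0, abs=1e-10)
        assert detail["parent_cor_b"] == pytest.approx(1.0, abs=1e-10)

    def test_unrelated_subset_uncorrelated_with_parent(self, small_dataset, detected):
        ds, assign = small_dataset, detected["assign"]
        mod = assign[assign != GREY].value_counts().idxmax()
        parent = assign.index[assign == mod]
        truth = ds.truth["labels"]  # true background, not detection leftovers
        background = list(truth.index[truth == GREY][:60])
        _, detail = subgroup_eigengene_test(
            ds.expr_base, ds.expr_stim, background, ds.samples.status, parent_genes=parent
        )
        assert abs(detail["parent_cor_a"]) < 0.3


def test_association_table_shape(small_dataset, detected):
    ds, assign = small_dataset, detected["assign"]
    me_a, _ = recompute_fixed_membership(ds.expr_base, assign)
    me_b, _ = recompute_fixed_membership(ds.expr_stim, assign)
    tab = association_table(me_a, me_b, ds.samples.status)
    assert set(tab.columns) >= {"beta_a", "se_a", "p_a", "aic_a",
                                "beta_b", "se_b", "p_b", "aic_b",
                                "delta_aic", "z", "one_sided_p"}
    assert GREY in tab.index
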