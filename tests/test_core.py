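"""Unit and property tests for the permutation FDR estimator building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permfdr.core import (
    EstimationConfig,
    PermutationEnsemble,
    PValueVector,
    ThresholdGrid,
    confidence_interval,
    count_rejections,
    estimate_pi0,
    fdr_table,
    fdr_table_from_counts,
    mv_fdr_point,
    se_log_fdr,
    summarize_permutations,
)


class TestCountRejections:
    def test_nothing_below_cutoff(self):
        assert count_rejections([0.5], 0.01) == 0

    def test_strict_rule_excludes_boundary(self):
        assert count_rejections([0.001, 0.01, 0.5], 0.01) == 1
        assert count_rejections([0.001, 0.01, 0.5], 0.01, strict=False) == 2

    def test_matches_elementwise_loop_on_random_fixtures(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 50))
            t = rng.uniform(0.001, 0.999)
            assert count_rejections(p, t) == sum(1 for x in p if x < t)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            count_rejections([], 0.05)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            count_rejections([0.5], 1.5)


class TestSummarizePermutations:
    def test_all_ones_give_zero_vbar(self):
        ens = PermutationEnsemble.from_pvalues(np.ones((3, 5)))
        vbar, var, n = summarize_permutations(ens, 0.5)
        assert vbar == 0.0 and var == 0.0 and n == 3

    def test_two_point_counts(self):
        # per-permutation rejection counts 3 and 5 -> mean 4, sample variance 2
        ens = PermutationEnsemble.from_counts(np.array([[3.0, 5.0]]), m=10, thresholds=[0.1])
        vbar, var, n = summarize_permutations(ens, 0.1)
        assert (vbar, var, n) == (4.0, 2.0, 2)

    def test_single_permutation_variance_unavailable(self):
        ens = PermutationEnsemble.from_pvalues(np.full((1, 4), 0.2))
        vbar, var, n = summarize_permutations(ens, 0.5)
        assert vbar == 4.0 and np.isnan(var) and n == 1

    def test_uniform_null_vbar_near_mt(self, rng):
        m, n_perm, t = 2000, 200, 0.01
        ens = PermutationEnsemble.from_pvalues(rng.uniform(size=(n_perm, m)))
        vbar, _, _ = summarize_permutations(ens, t)
        se = np.sqrt(m * t * (1 - t) / n_perm)
        assert abs(vbar - m * t) < 4 * se


class TestPointEstimate:
    def test_pi0_equal_counts(self):
        assert estimate_pi0(100, 7, 7.0) == 1.0

    def test_pi0_all_rejected(self):
        assert estimate_pi0(100, 100, 10.0) == 0.0

    def test_pi0_arithmetic(self):
        assert estimate_pi0(2000, 100, 10.0) == pytest.approx(1900 / 1990)

    def test_pi0_truncated_to_unit_interval(self):
        assert estimate_pi0(100, 5, 20.0) == 1.0  # S < Vbar

    def test_pi0_domain_error(self):
        with pytest.raises(ValueError):
            estimate_pi0(100, 5, 100.0)

    def test_fdr_null_case(self):
        assert mv_fdr_point(100, 10, 10.0, pi0=1.0) == 1.0

    def test_fdr_zero_vbar(self):
        assert mv_fdr_point(100, 10, 0.0, pi0=1.0) == 0.0

    def test_fdr_arithmetic(self):
        pi0 = estimate_pi0(2000, 100, 10.0)
        assert mv_fdr_point(2000, 100, 10.0, pi0) == pytest.approx(pi0 * 0.1)

    def test_fdr_cap(self):
        assert mv_fdr_point(100, 2, 30.0, pi0=1.0) == 1.0
        assert mv_fdr_point(100, 2, 30.0, pi0=1.0, cap_at_one=False) == 15.0

    def test_fdr_undefined_at_zero_rejections(self):
        with pytest.raises(ValueError):
            mv_fdr_point(100, 0, 5.0, pi0=1.0)


class TestSeLogFdr:
    def test_arithmetic(self):
        # sigma^2 = 1900/200000 + 1990/400000 = 0.014475
        se = se_log_fdr(2000, 100, 10.0, var_counts=np.nan, n_perm=20, c1=1.0)
        assert se == pytest.approx(np.sqrt(0.014475))
        assert se == pytest.approx(0.12031, abs=1e-5)

    def test_observed_term_vanishes_at_full_rejection(self):
        se = se_log_fdr(2000, 2000, 10.0, n_perm=20, c1=1.0)
        assert se**2 == pytest.approx(1990 / 400000)

    def test_doubling_permutations_halves_ensemble_term(self):
        base = se_log_fdr(2000, 2000, 10.0, n_perm=20, c1=1.0) ** 2
        double = se_log_fdr(2000, 2000, 10.0, n_perm=40, c1=1.0) ** 2
        assert double == pytest.approx(base / 2)

    def test_c1_estimated_from_overdispersion(self):
        m, vbar, var = 1000, 10.0, 30.0
        se_auto = se_log_fdr(m, 50, vbar, var_counts=var, n_perm=20)
        c1 = var / (vbar * (1 - vbar / m))
        se_fixed = se_log_fdr(m, 50, vbar, n_perm=20, c1=c1)
        assert se_auto == pytest.approx(se_fixed)

    def test_c1_floored_at_one(self):
        # underdispersed counts must not shrink the ensemble term below binomial
        se_under = se_log_fdr(1000, 50, 10.0, var_counts=1.0, n_perm=20)
        se_binom = se_log_fdr(1000, 50, 10.0, n_perm=20, c1=1.0)
        assert se_under == pytest.approx(se_binom)

    def test_undefined_without_rejections(self):
        with pytest.raises(ValueError):
            se_log_fdr(100, 0, 5.0, n_perm=10, c1=1.0)
        with pytest.raises(ValueError):
            se_log_fdr(100, 5, 0.0, n_perm=10, c1=1.0)


class TestConfidenceInterval:
    def test_collapses_as_se_vanishes(self):
        lo, hi = confidence_interval(0.3, 1e-12, 0.95)
        assert lo == pytest.approx(0.3) and hi == pytest.approx(0.3)

    def test_normal_quantile_arithmetic(self):
        lo, hi = confidence_interval(0.0955, 0.12031, 0.95)
        assert lo == pytest.approx(0.0754, abs=5e-4)
        assert hi == pytest.approx(0.1209, abs=5e-4)

    @given(
        fdr=st.floats(1e-4, 1.0),
        se=st.floats(1e-3, 3.0),
        cl=st.floats(0.5, 0.999),
    )
    @settings(deadline=None, max_examples=50)
    def test_log_scale_symmetry(self, fdr, se, cl):
        lo, hi = confidence_interval(fdr, se, cl)
        assert lo * hi == pytest.approx(fdr**2, rel=1e-9)

    def test_wider_at_higher_confidence(self):
        lo1, hi1 = confidence_interval(0.2, 0.3, 0.90)
        lo2, hi2 = confidence_interval(0.2, 0.3, 0.99)
        assert lo2 < lo1 and hi2 > hi1

    def test_cl_domain(self):
        with pytest.raises(ValueError):
            confidence_interval(0.5, 0.1, 1.2)


class TestFdrTable:
    def test_identical_observed_and_permuted_give_fdr_one(self, rng, grid):
        p = rng.uniform(1e-7, 1.0, size=500)
        obs = PValueVector(p)
        ens = PermutationEnsemble.from_pvalues(np.tile(p, (5, 1)))
        tab = fdr_table(obs, ens, grid, EstimationConfig(c1=1.0))
        defined = tab[tab["defined"]]
        assert len(defined) > 0
        assert np.allclose(defined["fdr"], 1.0)
        assert np.allclose(defined["wald_p"], 0.5)

    def test_rows_match_scalar_operations(self, grid):
        # compose the per-operation arithmetic on a known counts fixture
        rng = np.random.default_rng(5)
        m, P = 2000, 20
        S = np.sort(rng.integers(0, 200, size=len(grid)))[::-1].astype(float)
        C = rng.integers(0, 50, size=(len(grid), P)).astype(float)
        tab = fdr_table_from_counts(S, C, m, grid)
        for i in rng.choice(len(grid), size=8, replace=False):
            s, counts = S[i], C[i]
            vbar, var = counts.mean(), counts.var(ddof=1)
            row = tab.iloc[i]
            if s == 0:
                assert not row["defined"]
                continue
            vb = 0.5 / P if vbar == 0 else vbar
            pi0 = estimate_pi0(m, s, vb)
            fdr = mv_fdr_point(m, s, vb, pi0)
            se = se_log_fdr(m, s, vb, var, P)
            lo, hi = confidence_interval(fdr, se, 0.95)
            assert row["fdr"] == pytest.approx(fdr)
            assert row["se_log"] == pytest.approx(se)
            assert row["ci_lower"] == pytest.approx(lo)
            assert row["ci_upper"] == pytest.approx(hi)

    def test_s_nonincreasing_with_stricter_thresholds(self, uniform_inputs, grid):
        obs, ens = uniform_inputs
        tab = fdr_table(obs, ens, grid)
        assert np.all(np.diff(tab["S"]) <= 0)  # rows run loose -> strict

    def test_sufficiency_counts_equal_raw(self, uniform_inputs, grid):
        obs, ens = uniform_inputs
        raw = fdr_table(obs, ens, grid)
        s_obs = np.array([count_rejections(obs, t) for t in grid.thresholds], dtype=float)
        counts_ens = PermutationEnsemble.from_counts(
            ens.counts_at(grid.thresholds), m=obs.m, thresholds=grid.thresholds
        )
        reduced = fdr_table_from_counts(s_obs, counts_ens.counts_at(grid.thresholds), obs.m, grid)
        assert raw.equals(reduced)

    def test_continuity_substitution_flagged(self, grid):
        m, P = 100, 10
        S = np.linspace(40, 1, len(grid)).round()
        C = np.zeros((len(grid), P))
        tab = fdr_table_from_counts(S, C, m, grid)
        assert tab["continuity"].all()
        assert np.allclose(tab.loc[tab["defined"], "Vbar"], 0.0)
        expected_pi0 = np.clip((m - S) / (m - 0.5 / P), 0, 1)
        assert np.allclose(tab["pi0"], expected_pi0)

    def test_wald_half_iff_fdr_one(self, uniform_inputs, grid):
        obs, ens = uniform_inputs
        tab = fdr_table(obs, ens, grid)
        d = tab[tab["defined"]]
        at_one = d["fdr"] == 1.0
        assert np.allclose(d.loc[at_one, "wald_p"], 0.5)
        assert (d.loc[~at_one, "wald_p"] < 0.5).all()

    def test_ci_widens_with_confidence_level(self, uniform_inputs, grid):
        obs, ens = uniform_inputs
        t90 = fdr_table(obs, ens, grid, EstimationConfig(cl=0.90))
        t99 = fdr_table(obs, ens, grid, EstimationConfig(cl=0.99))
        d = t90["defined"] & (t90["fdr"] > 0)
        w90 = (t90["ci_upper"] - t90["ci_lower"])[d]
        w99 = (t99["ci_upper"] - t99["ci_lower"])[d]
        assert (w99 > w90).all()

    def test_m_mismatch_rejected(self, rng, grid):
        obs = PValueVector(rng.uniform(size=50))
        ens = PermutationEnsemble.from_pvalues(rng.uniform(size=(3, 40)))
        with pytest.raises(ValueError):
            fdr_table(obs, ens, grid)


class TestDomainTypes:
    def test_pvalues_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PValueVector([0.5, 0.0])
        with pytest.raises(ValueError):
            PValueVector([0.5, 1.2])
        with pytest.raises(ValueError):
            PValueVector([0.5, np.nan])

    def test_grid_accepts_either_orientation(self):
        a = ThresholdGrid([0.01, 0.001])
        b = ThresholdGrid([0.001, 0.01])
        assert np.allclose(a.thresholds, b.thresholds)
        assert a.thresholds[0] > a.thresholds[1]

    def test_grid_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            ThresholdGrid([0.01, 0.05, 0.001])

    def test_neg_log10_grid_has_expected_size(self):
        g = ThresholdGrid.from_neg_log10(2.0, 6.0, 0.1)
        assert len(g) == 41
        assert g.neg_log10[0] == pytest.approx(2.0)
        assert g.neg_log10[-1] == pytest.approx(6.0)

    def test_ensemble_requires_exactly_one_representation(self):
        with pytest.raises(ValueError):
            PermutationEnsemble(m=10)

    def test_counts_bounded_by_m(self):
        with pytest.raises(ValueError):
            PermutationEnsemble.from_counts([[11.0]], m=10, thresholds=[0.1])
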