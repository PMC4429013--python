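"""Contrast tests, TOST equivalence tests, intersection-union compounding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from combitax.stats import (A_VS_C, AB_VS_C, B_VS_C, INTERACTION, Contrast,
                            TostSpec, compound_iut, contrast_test, t_critical,
                            tost)

from conftest import make_fit


class TestContrast:
    def test_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError):
            Contrast({"A": 1.0, "C": -0.5}, "bad")

    def test_needs_two_nonzero_weights(self):
        with pytest.raises(ValueError):
            Contrast({"A": 0.0, "C": 0.0}, "bad")


class TestContrastTest:
    def test_zero_estimate_gives_half(self):
        fit = make_fit([(1.0, 1.0, 2.0, 5.0)], s2_tilde=0.01)
        for direction in ("greater", "less"):
            r = contrast_test(fit, "f0", A_VS_C, direction)
            assert r.estimate == 0.0
            assert r.p == pytest.approx(0.5)

    def test_known_t_statistic(self):
        # psi = 0.5, SE = 0.1 (s2 = 0.015, n = 3), df = 8 -> t = 5
        fit = make_fit([(0.0, 0.5, 0.0, 0.0)], s2_tilde=0.015, df_tilde=8)
        r = contrast_test(fit, "f0", A_VS_C, "greater")
        assert r.statistic == pytest.approx(5.0)
        assert r.p == pytest.approx(5.2e-4, rel=0.02)
        # mirrored direction is the complement
        r2 = contrast_test(fit, "f0", A_VS_C, "less")
        assert r.p + r2.p == pytest.approx(1.0)

    def test_interaction_zero_under_additivity(self):
        fit = make_fit([(0.0, 1.0, 1.0, 2.0)], s2_tilde=0.01)
        r = contrast_test(fit, "f0", INTERACTION, "greater")
        assert r.estimate == pytest.approx(0.0)

    def test_infinite_df_uses_normal(self):
        fit = make_fit([(0.0, 0.5, 0.0, 0.0)], s2_tilde=0.015,
                       df_tilde=math.inf)
        r = contrast_test(fit, "f0", A_VS_C, "greater")
        assert r.p == pytest.approx(sps.norm.sf(5.0), rel=1e-12)

    def test_opposite_directions_cannot_both_reject(self, rng):
        """p_greater + p_less = 1, so both below alpha < 0.5 is impossible."""
        means = np.column_stack([np.zeros(50), rng.normal(0, 2, 50),
                                 np.zeros(50), np.zeros(50)])
        fit = make_fit(means, s2_tilde=rng.gamma(2, 0.05, 50))
        for f in fit.feature_ids[:10]:
            pg = contrast_test(fit, f, A_VS_C, "greater").p
            pl = contrast_test(fit, f, A_VS_C, "less").p
            assert pg + pl == pytest.approx(1.0)
            assert not (pg < 0.45 and pl < 0.45)

    def test_degenerate_feature_flagged(self):
        fit = make_fit([(0.0, 1.0, 1.0, 2.0)], s2_tilde=0.01)
        fit.degenerate.iloc[0] = True
        r = contrast_test(fit, "f0", A_VS_C, "greater")
        assert r.degenerate and math.isnan(r.p)


class TestBruteForceOracle:
    def test_matches_classical_contrast_t(self, rng):
        """With no shrinkage (d0 = 0) the moderated contrast test is the
        classical pooled-variance contrast t-test, checked against an
        independent from-scratch implementation."""
        from combitax.model import (DesignMap, EBPrior, ExpressionMatrix,
                                    fit_condition_means, moderate, CONDITIONS)
        import pandas as pd

        n = 3
        values = rng.normal(0, 0.3, size=(100, 4 * n))
        cols = [f"{c}_{i}" for c in CONDITIONS for i in range(n)]
        m = ExpressionMatrix.from_dataframe(pd.DataFrame(
            values, columns=cols, index=[f"f{i}" for i in range(100)]))
        design = DesignMap({f"{c}_{i}": c for c in CONDITIONS for i in range(n)})
        fit = fit_condition_means(m, design)
        mod = moderate(fit, EBPrior(d0=0.0, s0_2=1.0), design.replicate_counts)

        for contrast in (A_VS_C, B_VS_C, INTERACTION, AB_VS_C):
            w = [contrast.weights.get(c, 0.0) for c in CONDITIONS]
            for i in range(100):
                # brute force: per-condition means and residual SS from raw data
                blocks = [values[i, j * n:(j + 1) * n] for j in range(4)]
                mns = [b.mean() for b in blocks]
                ss = sum(((b - b.mean()) ** 2).sum() for b in blocks)
                s2 = ss / (4 * n - 4)
                est = sum(wj * mj for wj, mj in zip(w, mns))
                se = math.sqrt(s2 * sum(wj * wj / n for wj in w))
                p_ref = sps.t.sf(est / se, 4 * n - 4)
                p = contrast_test(mod, f"f{i}", contrast, "greater").p
                assert abs(p - p_ref) < 1e-10


class TestTost:
    def test_worked_example(self):
        # psi = 0, SE = 0.05 (s2 = 0.00375, n = 3), eps = 0.15, df = 8
        fit = make_fit([(0.0, 0.0, 1.0, 1.0)], s2_tilde=0.00375, df_tilde=8)
        r = tost(fit, "f0", A_VS_C, TostSpec(0.15), alpha=0.05)
        assert r.u_upper == pytest.approx(3.0)
        assert r.u_lower == pytest.approx(3.0)
        assert r.p == pytest.approx(8.5e-3, rel=0.02)
        assert r.critical == pytest.approx(1.860, abs=5e-4)
        assert r.accepted

    def test_estimate_at_tolerance_edge_never_accepted(self):
        fit = make_fit([(0.0, 0.15, 0.0, 0.0)], s2_tilde=0.00375, df_tilde=8)
        r = tost(fit, "f0", A_VS_C, TostSpec(0.15), alpha=0.05)
        assert r.u_upper == pytest.approx(0.0)
        assert r.p_upper == pytest.approx(0.5)
        assert not r.accepted

    def test_degenerate_interval_never_accepted(self):
        fit = make_fit([(0.0, 0.01, 0.0, 0.0)], s2_tilde=0.00375, df_tilde=8)
        r = tost(fit, "f0", A_VS_C, TostSpec(1e-12), alpha=0.05)
        assert r.p >= 0.5

    def test_eps_must_be_positive(self):
        with pytest.raises(ValueError):
            TostSpec(0.0)

    @settings(deadline=None, derandomize=True)
    @given(est=st.floats(-1, 1), se=st.floats(0.01, 0.5),
           eps1=st.floats(0.01, 1), eps2=st.floats(0.01, 1))
    def test_p_nonincreasing_in_eps(self, est, se, eps1, eps2):
        """Widening the tolerance interval can only make equivalence easier."""
        lo, hi = sorted((eps1, eps2))
        fit = make_fit([(0.0, est, 0.0, 0.0)], s2_tilde=se * se * 1.5,
                       df_tilde=8)
        p_lo = tost(fit, "f0", A_VS_C, TostSpec(lo)).p
        p_hi = tost(fit, "f0", A_VS_C, TostSpec(hi)).p
        assert p_hi <= p_lo + 1e-12


class TestCompoundIUT:
    def test_max_rule(self):
        accepted, p = compound_iut([0.01, 0.04, 0.02], alpha=0.05)
        assert accepted and p == 0.04

    def test_one_failing_partial_rejects(self):
        accepted, p = compound_iut([0.01, 0.06], alpha=0.05)
        assert not accepted and p == 0.06

    def test_single_partial_identity(self):
        accepted, p = compound_iut([0.03], alpha=0.05)
        assert accepted and p == 0.03

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            compound_iut([], alpha=0.05)

    def test_nan_partial_treated_as_one(self):
        accepted, p = compound_iut([0.01, math.nan], alpha=0.05)
        assert not accepted and p == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_order_invariance(self, ps):
        """The max rule is commutative: partial order never matters."""
        _, p1 = compound_iut(ps, 0.05)
        _, p2 = compound_iut(list(reversed(ps)), 0.05)
        _, p3 = compound_iut(sorted(ps), 0.05)
        assert p1 == p2 == p3


def test_t_critical_infinite_df_is_normal_quantile():
    assert t_critical(math.inf, 0.05) == pytest.approx(1.6449, abs=1e-4)
    assert t_critical(8, 0.05) == pytest.approx(1.8595, abs=1e-4)
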