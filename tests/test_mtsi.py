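"""Closed-form first-passage-time statistics: worked examples, limits,
monotonicity, and the finite-receptor correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from tsi import (
    Criterion,
    SurfaceContext,
    UnreachableCriterionError,
    mtsi_2d,
    mtsi_3d,
    mtsi_corrected,
    mtsi_cv,
    mtsi_stats_3d,
    mtsi_variance_3d,
    n_productive,
)
from tsi.mtsi import mean_binding_events, mean_bound_receptors

C10_4 = Criterion(N=10, tau=4.0)

log_rate = st.floats(min_value=-3, max_value=3)  # log10 of a rate


def _mtsi(criterion, k_off, propensity):
    """MTSI at a stated total binding propensity (events/s)."""
    return mtsi_3d(criterion, k_on=propensity, k_off=k_off, rho=1.0, N_R=1.0)


class TestNProductive:
    def test_ten_e_fourth(self):
        assert n_productive(C10_4, 1.0) == pytest.approx(10 * math.e**4)

    @pytest.mark.parametrize("criterion, k_off", [
        (Criterion(N=10, tau=0.0), 7.3),
        (Criterion(N=10, tau=4.0), 0.0),
    ])
    def test_no_attrition_edge_cases(self, criterion, k_off):
        assert n_productive(criterion, k_off) == 10

    def test_negative_koff_rejected(self):
        with pytest.raises(ValueError):
            n_productive(C10_4, -0.1)


class TestWorkedExample:
    def test_foreign_ligand_59_seconds(self):
        t = _mtsi(C10_4, k_off=1.0, propensity=10.0)
        assert t == pytest.approx(4 + 10 * math.e**4 / 10, rel=1e-12)
        assert round(t) == 59

    def test_self_ligand_five_million_seconds(self):
        t = _mtsi(C10_4, k_off=5.0, propensity=1000.0)
        assert t == pytest.approx(4 + 10 * math.e**20 / 1000, rel=1e-12)
        assert t == pytest.approx(4.86e6, rel=1e-2)

    def test_tau_zero_is_erlang_mean(self):
        c = Criterion(N=10, tau=0.0)
        assert _mtsi(c, k_off=3.0, propensity=10.0) == pytest.approx(1.0)


class TestVarianceAndCV:
    def test_variance_worked_example(self):
        v = mtsi_variance_3d(C10_4, k_on=10.0, k_off=1.0, rho=1.0, N_R=1.0)
        assert v == pytest.approx(10 * math.e**4 / 100, rel=1e-12)  # 5.4598

    def test_tau_zero_variance_is_erlang(self):
        c = Criterion(N=10, tau=0.0)
        assert mtsi_variance_3d(c, 1.0, 2.0, 1.0, 1.0) == pytest.approx(10.0)

    def test_doubling_rho_quarters_variance(self):
        v1 = mtsi_variance_3d(C10_4, 5.0, 0.5, 1e-8, 3e4)
        v2 = mtsi_variance_3d(C10_4, 5.0, 0.5, 2e-8, 3e4)
        assert v1 / v2 == pytest.approx(4.0, rel=1e-12)

    def test_cv_worked_example(self):
        cv = mtsi_cv(C10_4, k_on=10.0, k_off=1.0, rho=1.0, N_R=1.0)
        assert cv == pytest.approx(math.sqrt(5.4598) / 58.598, rel=1e-3)

    def test_cv_tau_zero_is_one_over_sqrt_n(self):
        for N in (1, 10, 400):
            c = Criterion(N=N, tau=0.0)
            assert mtsi_cv(c, 2.0, 1.0, 1.0, 1.0) == pytest.approx(
                1 / math.sqrt(N), rel=1e-12)

    def test_cv_vanishes_for_large_n(self):
        c = Criterion(N=10**6, tau=4.0)
        assert mtsi_cv(c, 10.0, 1.0, 1.0, 1.0) < 0.01


class TestTwoDimensional:
    def test_matches_3d_at_equal_propensity(self):
        surface = SurfaceContext(M_R=50.0, M_L=30.0, A_c=2.0,
                                 kon2d=0.01, koff2d=0.7)
        propensity = 0.01 * 50 * 30 * 2
        stats2d = mtsi_2d(C10_4, surface)
        assert stats2d.mean == pytest.approx(
            _mtsi(C10_4, 0.7, propensity), rel=1e-12)
        assert stats2d.variance == pytest.approx(
            mtsi_variance_3d(C10_4, propensity, 0.7, 1.0, 1.0), rel=1e-12)

    def test_tau_offset_identity(self):
        surface = SurfaceContext(M_R=5.0, M_L=4.0, A_c=1.0,
                                 kon2d=0.5, koff2d=0.3)
        with_tau = mtsi_2d(C10_4, surface)
        without = mtsi_2d(Criterion(N=10, tau=0.0), surface)
        assert with_tau.mean - 4.0 == pytest.approx(
            without.mean * math.exp(4.0 * 0.3), rel=1e-12)

    def test_simple_mean(self):
        surface = SurfaceContext(M_R=10.0, M_L=1.0, A_c=1.0,
                                 kon2d=1.0, koff2d=1.0)
        stats = mtsi_2d(Criterion(N=10, tau=0.0), surface)
        assert stats.mean == pytest.approx(1.0)

    def test_mean_at_least_tau(self):
        surface = SurfaceContext(M_R=1e4, M_L=1e4, A_c=10.0,
                                 kon2d=10.0, koff2d=1e-3)
        assert mtsi_2d(C10_4, surface).mean >= 4.0


class TestOverflowPolicy:
    def test_huge_mean_becomes_inf_with_warning(self):
        c = Criterion(N=10, tau=100.0)
        with pytest.warns(RuntimeWarning, match="1e30"):
            assert math.isinf(mtsi_3d(c, 1.0, 5.0, 1.0, 1.0))


class TestCorrected:
    def test_bc_closed_forms_match_ode(self):
        """Reconstructed B(t), C(t) agree with direct ODE integration."""
        k_on, k_off, rho, n_r = 1e5, 0.5, 1e-8, 3e4

        def rhs(t, y):
            b, _ = y
            db = k_on * rho * (n_r - b) - k_off * b
            dc = k_on * rho * (n_r - b)
            return [db, dc]

        t_end = 20.0
        sol = solve_ivp(rhs, (0, t_end), [0.0, 0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        for t in np.linspace(0.1, t_end, 7):
            b_num, c_num = sol.sol(t)
            assert mean_bound_receptors(t, k_on, k_off, rho, n_r) == \
                pytest.approx(b_num, rel=1e-6)
            assert mean_binding_events(t, k_on, k_off, rho, n_r) == \
                pytest.approx(c_num, rel=1e-6)

    def test_agrees_with_uncorrected_when_nprime_small(self, sp_4p):
        # SP 4P at 10 nM: N' ~ 10.7 << N_R = 30000
        plain = mtsi_3d(C10_4, sp_4p.k_on, sp_4p.k_minus, 1e-8, 30000)
        corrected = mtsi_corrected(C10_4, sp_4p.k_on, sp_4p.k_minus,
                                   1e-8, 30000)
        assert corrected == pytest.approx(plain, rel=0.01)
        assert corrected >= plain  # receptor depletion only slows binding

    def test_exact_reduction_at_koff_zero_large_pool(self):
        c = Criterion(N=5, tau=2.0)
        plain = mtsi_3d(c, 1e4, 0.0, 1e-9, 1e7)
        corrected = mtsi_corrected(c, 1e4, 0.0, 1e-9, 1e7)
        assert corrected == pytest.approx(plain, rel=1e-5)

    def test_unreachable_when_receptors_exhausted(self):
        # k_off = 0: each receptor binds once, so N' > N_R is impossible
        c = Criterion(N=100, tau=0.0)
        with pytest.raises(UnreachableCriterionError):
            mtsi_corrected(c, k_on=1.0, k_off=0.0, rho=1.0, N_R=50)

    def test_correction_is_substantial_when_pool_is_small(self):
        # N' ~ 27 productive targets against only 50 receptors
        c = Criterion(N=10, tau=2.0)
        plain = mtsi_3d(c, 0.2, 0.5, 1.0, 50)
        corrected = mtsi_corrected(c, 0.2, 0.5, 1.0, 50)
        assert corrected > 1.05 * plain


class TestInvariantsAndMonotonicity:
    @given(log_k_off=st.floats(-3, 0.5), log_prop=log_rate,
           tau=st.floats(0, 8), N=st.integers(1, 200))
    @settings(max_examples=150, deadline=None)
    def test_mean_at_least_tau(self, log_k_off, log_prop, tau, N):
        c = Criterion(N=N, tau=tau)
        mean = _mtsi(c, 10.0**log_k_off, 10.0**log_prop)
        assert mean >= tau

    @given(log_k_on=log_rate, log_k_off=st.floats(-3, 0.5),
           log_rho=st.floats(-10, -4), log_nr=st.floats(2, 5),
           tau=st.floats(0.1, 8.0), N=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_pairwise_monotonicity(self, log_k_on, log_k_off, log_rho,
                                   log_nr, tau, N):
        # tau > 0: at tau = 0 the dwell filter is inert and the mean is
        # independent of k_off, so strict monotonicity in k_off needs tau > 0
        k_on, k_off = 10.0**log_k_on, 10.0**log_k_off
        rho, n_r = 10.0**log_rho, 10.0**log_nr
        c = Criterion(N=N, tau=tau)
        base = mtsi_3d(c, k_on, k_off, rho, n_r)
        assert mtsi_3d(c, k_on, k_off, rho * 2, n_r) < base
        assert mtsi_3d(c, k_on * 2, k_off, rho, n_r) < base
        assert mtsi_3d(c, k_on, k_off, rho, n_r * 2) < base
        assert mtsi_3d(c, k_on, k_off * 1.5 + 0.1, rho, n_r) > base
        assert mtsi_3d(Criterion(N=N, tau=tau + 1), k_on, k_off, rho, n_r) > base
        assert mtsi_3d(Criterion(N=N + 1, tau=tau), k_on, k_off, rho, n_r) > base

    @given(log_k_off=st.floats(-3, 0.5), log_prop=log_rate,
           tau=st.floats(0, 8), N=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_n_at_fixed_tau(self, log_k_off, log_prop, tau, N):
        k_off, prop = 10.0**log_k_off, 10.0**log_prop
        t_n = _mtsi(Criterion(N=N, tau=tau), k_off, prop)
        t_2n = _mtsi(Criterion(N=2 * N, tau=tau), k_off, prop)
        assert t_2n - tau == pytest.approx(2 * (t_n - tau), rel=1e-9)

    def test_small_rho_limit_scales_inversely(self):
        c, vals = C10_4, []
        for rho in (1e-12, 1e-13, 1e-14):
            vals.append((mtsi_3d(c, 1e5, 0.5, rho, 3e4) - 4.0) * rho)
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)
        assert vals[1] == pytest.approx(vals[2], rel=1e-9)

    def test_large_rho_limit_is_tau(self):
        assert mtsi_3d(C10_4, 1e5, 0.5, 1e3, 3e4) == pytest.approx(
            4.0, abs=1e-6)

    def test_stats_bundle_is_self_consistent(self):
        stats = mtsi_stats_3d(C10_4, 1e5, 0.8, 1e-8, 3e4)
        assert stats.cv == pytest.approx(
            math.sqrt(stats.variance) / stats.mean, rel=1e-12)
        assert stats.n_prime == pytest.approx(10 * math.exp(4 * 0.8))
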