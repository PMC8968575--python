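"""Closed-form model functions: stated values, reductions, invariants."""

import numpy as np
import pytest

from adkin import (
    DualPoolParams,
    DualPoolSinglePhaseParams,
    FirstOrderParams,
    GompertzParams,
    ThreePhaseParams,
    TwoPhaseParams,
    dual_pool_trajectory,
    eval_dual_pool_single,
    eval_first_order,
    eval_gompertz,
    eval_sa,
    eval_sb,
    eval_sc,
    eval_sd,
    eval_three_phase,
    eval_two_phase,
    integrate_pool_odes,
)
from conftest import PRINTED_SETS


MSW = PRINTED_SETS["msw"]


class TestDualPoolStates:
    def test_substrate_starts_at_initial_amount(self):
        for p in PRINTED_SETS.values():
            assert eval_sa(p, [0.0])[0] == pytest.approx(p.s_a0, rel=1e-14)

    def test_single_pool_reduction_of_substrate(self):
        p = DualPoolParams(10.0, 0.01, 0.3, 0.2, 0.1, 1.0)
        t = np.linspace(0.0, 30.0, 31)
        np.testing.assert_allclose(eval_sa(p, t), 10.0 * np.exp(-0.3 * t), rtol=1e-14)

    def test_substrate_against_ode_oracle_at_30d(self):
        traj = integrate_pool_odes(MSW, [0.0, 30.0], rtol=1e-11)
        assert eval_sa(MSW, [30.0])[0] == pytest.approx(traj.s_a[1], rel=1e-9)

    def test_hydrolysate_zero_at_start_and_for_pure_fast_pool(self):
        assert eval_sb(MSW, [0.0])[0] == 0.0
        p = DualPoolParams(10.0, 0.01, 0.3, 0.2, 0.1, 1.0)
        np.testing.assert_array_equal(eval_sb(p, np.linspace(0, 50, 11)), 0.0)

    def test_hydrolysate_coincident_rate_limit(self):
        # k_2 = k_L exactly: S_B = S_A0 (1-α) k_L t e^(-k_L t)
        p = DualPoolParams(5.0, 0.25, 1.0, 0.25, 0.8, 0.4)
        t = np.linspace(0.0, 40.0, 81)
        expected = 5.0 * 0.6 * 0.25 * t * np.exp(-0.25 * t)
        np.testing.assert_allclose(eval_sb(p, t), expected, rtol=1e-12, atol=1e-15)
        traj = integrate_pool_odes(p, t)
        np.testing.assert_allclose(eval_sb(p, t), traj.s_b, rtol=1e-7, atol=1e-9)

    def test_vfa_initial_condition_and_slope(self):
        assert eval_sc(MSW, [0.0])[0] == 0.0
        # dS_C/dt at 0 is α k_R S_A0 (only the fast pool feeds VFA instantly)
        h = 1e-7
        slope = eval_sc(MSW, [h])[0] / h
        assert slope == pytest.approx(MSW.alpha * MSW.k_r * MSW.s_a0, rel=1e-5)

    def test_vfa_against_ode_oracle_at_10d(self):
        p = PRINTED_SETS["pretreated"]
        traj = integrate_pool_odes(p, [0.0, 10.0], rtol=1e-11)
        assert eval_sc(p, [10.0])[0] == pytest.approx(traj.s_c[1], rel=1e-8)

    def test_biogas_boundary_values(self):
        assert eval_sd(MSW, [0.0])[0] == 0.0
        assert eval_sd(MSW, [1e6])[0] == pytest.approx(MSW.s_a0, rel=1e-9)

    def test_biogas_reduces_to_three_phase_without_fast_pool(self):
        t = np.linspace(0.0, 300.0, 121)
        p = DualPoolParams(38.0, 0.0133, 0.9, 0.1274, 0.1181, 0.0)
        ref = eval_three_phase(ThreePhaseParams(38.0, 0.0133, 0.1274, 0.1181), t)
        np.testing.assert_allclose(eval_sd(p, t), ref, rtol=1e-12, atol=1e-12 * 38.0)

    def test_biogas_reduces_to_two_phase_without_slow_pool(self):
        t = np.linspace(0.0, 60.0, 121)
        p = DualPoolParams(38.0, 0.01, 0.1532, 0.7, 0.1181, 1.0)
        ref = eval_two_phase(TwoPhaseParams(38.0, 0.1532, 0.1181), t)
        np.testing.assert_allclose(eval_sd(p, t), ref, rtol=1e-12, atol=1e-12 * 38.0)

    def test_negative_time_rejected(self):
        for fn in (eval_sa, eval_sb, eval_sc, eval_sd):
            with pytest.raises(ValueError):
                fn(MSW, [-0.5])


class TestDualPoolInvariants:
    def test_mass_balance_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rates = 10.0 ** rng.uniform(-2, np.log10(3.0), 4)
            p = DualPoolParams(50.0, *rates, rng.uniform(0.0, 1.0))
            t = rng.uniform(0.0, 10.0 / rates.min(), 5)
            traj = dual_pool_trajectory(p, np.sort(t))
            np.testing.assert_allclose(traj.total, p.s_a0, rtol=1e-9)

    def test_monotonicity_of_substrate_and_biogas(self):
        t = np.linspace(0.0, 400.0, 401)
        for p in PRINTED_SETS.values():
            sd = eval_sd(p, t)
            sa = eval_sa(p, t)
            assert np.all(np.diff(sd) >= -1e-12 * p.s_a0)
            assert np.all(np.diff(sa) <= 1e-12 * p.s_a0)

    def test_trajectory_states_start_empty(self):
        traj = dual_pool_trajectory(MSW, np.linspace(0, 10, 11))
        assert traj.s_b[0] == 0.0 and traj.s_c[0] == 0.0 and traj.s_d[0] == 0.0


class TestComparators:
    def test_first_order_values(self):
        assert eval_first_order(FirstOrderParams(1.0, 1.0), [0.0])[0] == 0.0
        assert eval_first_order(FirstOrderParams(1.0, 1.0), [1.0])[0] == pytest.approx(
            1.0 - np.exp(-1.0), rel=1e-14
        )
        assert eval_first_order(FirstOrderParams(100.0, 0.2), [5.0])[0] == pytest.approx(
            100.0 * (1.0 - np.exp(-1.0)), rel=1e-14
        )

    def test_two_phase_fast_methanation_limit_is_first_order(self):
        t = np.linspace(0.0, 30.0, 61)
        fast = eval_two_phase(TwoPhaseParams(50.0, 0.2, 500.0), t)
        ref = eval_first_order(FirstOrderParams(50.0, 0.2), t)
        np.testing.assert_allclose(fast, ref, rtol=2e-3, atol=0.05)

    def test_three_phase_fast_tail_limit_is_first_order(self):
        t = np.linspace(0.0, 30.0, 61)
        fast = eval_three_phase(ThreePhaseParams(50.0, 0.2, 800.0, 900.0), t)
        ref = eval_first_order(FirstOrderParams(50.0, 0.2), t)
        np.testing.assert_allclose(fast, ref, rtol=3e-3, atol=0.08)

    def test_dual_pool_single_reductions(self):
        t = np.linspace(0.0, 30.0, 61)
        one_pool = eval_dual_pool_single(DualPoolSinglePhaseParams(9.0, 1.0, 0.4, 0.05), t)
        np.testing.assert_allclose(
            one_pool, eval_first_order(FirstOrderParams(9.0, 0.4), t), rtol=1e-14
        )
        equal_rates = eval_dual_pool_single(DualPoolSinglePhaseParams(9.0, 0.5, 0.3, 0.3), t)
        np.testing.assert_allclose(
            equal_rates, eval_first_order(FirstOrderParams(9.0, 0.3), t), rtol=1e-14
        )

    def test_gompertz_stated_points(self):
        p = GompertzParams(244.463, 35.399, 2.0)
        assert eval_gompertz(p, [2.0])[0] == pytest.approx(244.463 * np.exp(-np.e), rel=1e-12)
        assert eval_gompertz(p, [1e6])[0] == pytest.approx(244.463, rel=1e-9)

    def test_gompertz_positive_at_time_zero(self):
        # the sigmoid cannot satisfy the zero-initial-biogas condition
        p = GompertzParams(10.0, 3.0, 0.0)
        assert eval_gompertz(p, [0.0])[0] == pytest.approx(10.0 * np.exp(-np.e), rel=1e-12)
        assert eval_gompertz(p, [0.0])[0] > 0.0


class TestParamValidation:
    def test_pool_sizes_partition_substrate(self):
        p = MSW
        assert p.c_r + p.c_l == pytest.approx(p.s_a0, rel=1e-14)
        assert p.c_r == pytest.approx(p.alpha * p.s_a0, rel=1e-14)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(s_a0=-1.0, k_l=0.1, k_r=0.2, k_2=0.3, k_3=0.4, alpha=0.5),
            dict(s_a0=1.0, k_l=0.0, k_r=0.2, k_2=0.3, k_3=0.4, alpha=0.5),
            dict(s_a0=1.0, k_l=0.1, k_r=0.2, k_2=0.3, k_3=0.4, alpha=1.2),
        ],
    )
    def test_invalid_dual_pool_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DualPoolParams(**kwargs)

    def test_invalid_gompertz_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(-1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            GompertzParams(1.0, 2.0, -0.5)
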