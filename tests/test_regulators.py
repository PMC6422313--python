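import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lateralstep.geometry import derive_state_series, FootPlacementTrial
from lateralstep.regulators import (
    UNCONSTRAINED,
    ConstraintSpec,
    MultiObjectiveSpec,
    RegulatorSpec,
    SimulationConfig,
    calibrate_additive_noise,
    clamp_to_constraints,
    control_input,
    optimal_gain,
    simulate_multi_objective,
    simulate_trials,
    simulate_uni_objective,
    state_update,
    swing_foot_for_target,
    violation_rates,
)


class TestOptimalGain:
    @pytest.mark.parametrize(
        "sigma_m, goa, expected",
        [
            (0.0, 0.0, 1.0),  # unbiased proportional limit
            (1.0, 0.0, 0.5),
            (0.00257, 0.1, 0.90908549),  # frozen direct evaluation
        ],
    )
    def test_closed_form(self, sigma_m, goa, expected):
        assert optimal_gain(sigma_m, goa) == pytest.approx(expected, abs=1e-7)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            optimal_gain(-0.1, 0.0)
        with pytest.raises(ValueError):
            optimal_gain(0.0, -0.1)

    @given(
        sm=st.floats(0, 5, allow_nan=False),
        dm=st.floats(1e-6, 5, allow_nan=False),
        goa=st.floats(0, 5, allow_nan=False),
        dg=st.floats(1e-6, 5, allow_nan=False),
    )
    def test_strictly_decreasing_in_noise_and_cost(self, sm, dm, goa, dg):
        g0 = optimal_gain(sm, goa)
        assert optimal_gain(sm + dm, goa) < g0
        assert optimal_gain(sm, goa + dg) < g0
        assert 0 < g0 <= 1


class TestControlLaw:
    def test_zero_error_gives_zero_input(self):
        spec = RegulatorSpec("w")
        assert control_input(spec.q_star, spec) == 0.0

    def test_unbiased_limit_is_full_proportional_feedback(self):
        spec = RegulatorSpec("z_B", sigma_m=0.0, gamma_over_alpha=0.0)
        assert spec.gain == 1.0
        assert control_input(0.05, spec) == pytest.approx(-0.05)
        # full one-step correction, no noise
        u = control_input(0.05, spec)
        assert state_update(0.05, u, 0.0, 0.0, spec) == pytest.approx(spec.q_star)

    def test_partial_gain_input(self):
        spec = RegulatorSpec("w", sigma_m=0.00257, gamma_over_alpha=0.1, q_star=0.0)
        assert control_input(0.02, spec) == pytest.approx(-0.0181817, abs=1e-6)

    def test_noise_free_map_and_pure_drift(self):
        spec = RegulatorSpec("w")
        assert state_update(0.1, -0.02, 0.0, 0.0, spec) == pytest.approx(0.08)
        drift_spec = RegulatorSpec("w", sigma_a=0.01)
        assert state_update(0.1, 0.0, 0.0, 1.0, drift_spec) == pytest.approx(0.11)

    def test_geometric_error_contraction_rate(self):
        # no noise, g=1: the controlled variable's error shrinks by (1-G) each step
        spec = RegulatorSpec("w", sigma_a=0.0, sigma_m=0.0, gamma_over_alpha=0.25)
        G = spec.gain
        config = SimulationConfig(n_steps=10, seed=0, w0=spec.q_star + 0.1)
        trial = simulate_uni_objective(spec, config, UNCONSTRAINED)
        err = derive_state_series(trial).w - spec.q_star
        ratios = err[1:] / err[:-1]
        np.testing.assert_allclose(ratios, 1.0 - G, rtol=1e-6)

    def test_monte_carlo_unbiasedness_at_full_gain(self, rng):
        spec = RegulatorSpec("w", sigma_m=0.0, gamma_over_alpha=0.0)
        n = 100_000
        q_n = spec.q_star + 0.05
        u = control_input(q_n, spec)
        nu_a = rng.standard_normal(n)
        q_next = state_update(q_n, u, 0.0, nu_a, spec)
        err = q_next - spec.q_star
        sem = spec.sigma_a / np.sqrt(n)
        assert abs(err.mean()) < 4 * sem


class TestSwingFootForTarget:
    def test_width_inversion(self):
        assert swing_foot_for_target("w", 0.12, stance_z=0.10, swing_side="L") == pytest.approx(-0.02)

    def test_position_inversion(self):
        assert swing_foot_for_target("z_B", 0.0, stance_z=-0.06, swing_side="R") == pytest.approx(0.06)

    def test_heading_inversion_forward_checked(self):
        # placing the swing foot there must realize the heading target exactly
        z_new = swing_foot_for_target("dz_B", 0.0, stance_z=0.10, swing_side="L", z_B_prev=0.02)
        assert z_new == pytest.approx(-0.06)
        trial = FootPlacementTrial(
            z_L=np.array([-0.06, z_new]),  # step 0 chosen so z_B_prev = 0.02
            z_R=np.array([0.10, 0.10]),
            placed_side=np.array(["R", "L"], dtype=object),
        )
        state = derive_state_series(trial)
        assert state.z_B[0] == pytest.approx(0.02)
        assert state.dz_B[0] == pytest.approx(0.0, abs=1e-15)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown stepping variable"):
            swing_foot_for_target("speed", 0.0, 0.0, "L")


class TestClampToConstraints:
    def test_inside_limits_passes_through(self):
        z, b, w = clamp_to_constraints(-0.02, 0.10, "L", ConstraintSpec())
        assert (z, b, w) == (-0.02, False, False)

    def test_boundary_projection(self):
        z, b, w = clamp_to_constraints(0.90, 0.70, "R", ConstraintSpec())
        assert z == pytest.approx(0.885)
        assert b and not w

    def test_width_projection_at_printed_lower_limit(self):
        # swing L at +0.05 vs stance R at 0 implies w = -0.05 < -0.0015
        z, b, w = clamp_to_constraints(0.05, 0.0, "L", ConstraintSpec())
        assert z == pytest.approx(0.0015)
        assert w and not b

    def test_pass_through_when_not_enforcing(self):
        z, b, w = clamp_to_constraints(5.0, 0.0, "R", UNCONSTRAINED)
        assert (z, b, w) == (5.0, False, False)

    def test_empty_feasible_interval_rejected(self):
        with pytest.raises(ValueError, match="empty feasible"):
            clamp_to_constraints(0.0, 1.2, "L", ConstraintSpec())


class TestUniObjectiveSimulation:
    def test_noise_free_width_control_is_steady(self):
        spec = RegulatorSpec("w", sigma_a=0.0, sigma_m=0.0)
        trial = simulate_uni_objective(spec, SimulationConfig(n_steps=50, seed=0), UNCONSTRAINED)
        state = derive_state_series(trial)
        np.testing.assert_allclose(state.w, 0.127, atol=1e-12)
        np.testing.assert_allclose(state.z_B, state.z_B[0], atol=1e-12)

    def test_same_seed_gives_bit_identical_trials(self):
        spec = RegulatorSpec("w")
        cfg = SimulationConfig(n_steps=100, seed=99)
        t1 = simulate_uni_objective(spec, cfg, ConstraintSpec())
        t2 = simulate_uni_objective(spec, cfg, ConstraintSpec())
        assert np.array_equal(t1.z_L, t2.z_L) and np.array_equal(t1.z_R, t2.z_R)

    def test_sides_alternate_and_stance_is_carried(self):
        spec = RegulatorSpec("z_B")
        trial = simulate_uni_objective(spec, SimulationConfig(n_steps=30, seed=3), UNCONSTRAINED)
        assert all(a != b for a, b in zip(trial.placed_side[:-1], trial.placed_side[1:]))
        for i in range(1, trial.n_steps):
            carried = trial.z_R if trial.placed_side[i] == "L" else trial.z_L
            assert carried[i] == carried[i - 1]

    def test_width_control_has_lag1_autocorr_near_one_minus_gain(self):
        spec = RegulatorSpec("w")
        trials = simulate_trials(spec, SimulationConfig(n_steps=290, n_trials=30, seed=5),
                                 UNCONSTRAINED)
        acs = []
        for t in trials:
            w = t.z_R - t.z_L
            wc = w - w.mean()
            acs.append(np.sum(wc[1:] * wc[:-1]) / np.sum(wc * wc))
        assert np.mean(acs) == pytest.approx(1.0 - spec.gain, abs=0.05)


class TestMultiObjectiveSimulation:
    def test_degenerate_rho_one_equals_uni_objective(self):
        width = RegulatorSpec("w")
        mix = MultiObjectiveSpec(
            spec1=RegulatorSpec("z_B").with_noise_zeroed(), spec2=width, rho=1.0
        )
        cfg = SimulationConfig(n_steps=150, seed=7)
        tm = simulate_multi_objective(mix, cfg, UNCONSTRAINED)
        tu = simulate_uni_objective(width, cfg, UNCONSTRAINED)
        assert np.array_equal(tm.z_L, tu.z_L) and np.array_equal(tm.z_R, tu.z_R)

    def test_noise_free_mixture_converges_to_joint_fixed_point(self):
        pos = RegulatorSpec("z_B").with_noise_zeroed()
        wid = RegulatorSpec("w").with_noise_zeroed()
        mix = MultiObjectiveSpec(spec1=pos, spec2=wid, rho=0.5)
        cfg = SimulationConfig(n_steps=200, seed=0, z_B0=0.3, w0=0.2)
        trial = simulate_multi_objective(mix, cfg, UNCONSTRAINED)
        assert trial.z_L[-1] == pytest.approx(pos.q_star - wid.q_star / 2, abs=1e-8)
        assert trial.z_R[-1] == pytest.approx(pos.q_star + wid.q_star / 2, abs=1e-8)

    def test_distinct_variables_required(self):
        with pytest.raises(ValueError, match="distinct"):
            MultiObjectiveSpec(spec1=RegulatorSpec("w"), spec2=RegulatorSpec("w"), rho=0.5)


class TestViolationRates:
    def _legal_trial(self, n=290):
        z_L = np.full(n, -0.06)
        z_R = np.full(n, 0.06)
        sides = np.array([("L", "R")[i % 2] for i in range(n)], dtype=object)
        return z_L, z_R, sides

    def test_all_legal_steps_give_zero(self):
        z_L, z_R, sides = self._legal_trial()
        trial = FootPlacementTrial(z_L=z_L, z_R=z_R, placed_side=sides)
        assert violation_rates(trial, ConstraintSpec()) == (0.0, 0.0)

    def test_single_boundary_violation_counted(self):
        z_L, z_R, sides = self._legal_trial()
        i = next(k for k in range(10) if sides[k] == "R")
        z_R = z_R.copy()
        z_R[i] = 0.90  # placed foot off the path; width 0.96 also illegal there
        z_L = z_L.copy()
        z_L[i] = 0.90 - 0.10  # keep width legal
        trial = FootPlacementTrial(z_L=z_L, z_R=z_R, placed_side=sides)
        pct_b, pct_w = violation_rates(trial, ConstraintSpec())
        assert pct_b == pytest.approx(100.0 / 290)
        assert pct_w == 0.0

    def test_constrained_simulation_never_violates(self, baseline_trials):
        cons = ConstraintSpec()
        for trial in baseline_trials:
            assert violation_rates(trial, cons) == (0.0, 0.0)


class TestCalibrateAdditiveNoise:
    def test_full_gain_passthrough_and_zero_target(self):
        spec = RegulatorSpec("w", sigma_m=0.0, gamma_over_alpha=0.0)
        assert calibrate_additive_noise(0.02, spec) == pytest.approx(0.02)
        assert calibrate_additive_noise(0.0, spec) == 0.0

    def test_closed_form_value(self):
        spec = RegulatorSpec("w", sigma_m=0.00257, gamma_over_alpha=0.1)
        sigma_a = calibrate_additive_noise(0.0257, spec)
        assert sigma_a == pytest.approx(0.02559, abs=2e-5)

    def test_long_run_simulation_matches_target(self):
        target = 0.0257
        spec = RegulatorSpec("w", sigma_m=0.00257, gamma_over_alpha=0.1)
        sigma_a = calibrate_additive_noise(target, spec)
        from dataclasses import replace

        tuned = replace(spec, sigma_a=sigma_a)
        trial = simulate_uni_objective(
            tuned, SimulationConfig(n_steps=20_000, seed=4), UNCONSTRAINED
        )
        w = trial.z_R - trial.z_L
        assert np.std(w[100:], ddof=1) == pytest.approx(target, rel=0.05)

    def test_non_stationary_configuration_rejected(self):
        spec = RegulatorSpec("w", sigma_m=0.0, gamma_over_alpha=0.0, g=2.5)
        with pytest.raises(ValueError, match="non-stationary"):
            calibrate_additive_noise(0.02, spec)
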