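"""Feedback ODE model: structural contracts, closed forms, steady states."""

import numpy as np
import pytest

from rootgrn import (AnalysisError, CalibrationError, InvalidArgument,
                     ModelParams, calibrate_overexpression,
                     genotype_scenarios, rhs, simulate, solve_gstar,
                     steady_state_batch, steady_states)


class TestRhs:
    def test_no_repressor_gives_linear_rsl4_equation(self, wt_params):
        for R in (0.0, 0.5, 2.0):
            dR, _ = rhs((R, 0.0), wt_params)
            assert dR == pytest.approx(wt_params.k1 - wt_params.deg_R * R)

    def test_no_activator_gives_pure_gtl1_decay(self):
        for variant in ("EQN1", "EQN2"):
            p = ModelParams(variant=variant)
            for G in (0.0, 0.3, 4.0):
                _, dG = rhs((0.0, G), p)
                assert dG == pytest.approx(-p.deg_G * G)

    def test_eqn2_production_dominates_eqn1_on_grid(self):
        p1, p2 = ModelParams(variant="EQN1"), ModelParams(variant="EQN2")
        grid = np.linspace(0.0, 5.0, 20)
        for R in grid:
            for G in grid:
                f1 = rhs((R, G), p1)[1] + p1.deg_G * G
                f2 = rhs((R, G), p2)[1] + p2.deg_G * G
                assert f2 >= f1 - 1e-15

    def test_promoter_activity_monotone(self):
        p = ModelParams(variant="EQN1")
        base = rhs((1.0, 1.0), p)[1]
        assert rhs((2.0, 1.0), p)[1] > base       # increasing in R
        assert rhs((1.0, 2.0), p)[1] < base - (2.0 - 1.0) * p.deg_G + 1e-12 \
            or rhs((1.0, 2.0), p)[1] < base       # decreasing in G

    def test_invalid_state_and_params(self, wt_params):
        with pytest.raises(InvalidArgument):
            rhs((-0.1, 0.0), wt_params)
        with pytest.raises(InvalidArgument):
            rhs((0.0, float("nan")), wt_params)
        with pytest.raises(InvalidArgument):
            ModelParams(k1=-1.0)
        with pytest.raises(InvalidArgument):
            ModelParams(k2=-0.5)
        with pytest.raises(InvalidArgument):
            ModelParams(variant="EQN3")


class TestSimulate:
    def test_null_gtl1_closed_form(self, wt_params):
        p = wt_params.with_(k2=0.0)
        traj = simulate(p, init=(0.0, 0.0), t_end=40.0)
        assert np.all(traj[:, 2] == 0.0)
        assert traj[-1, 1] == pytest.approx(p.k1 / p.deg_R, rel=1e-6)

    def test_pure_decay_closed_form(self):
        p = ModelParams(k1=1e-300, k2=0.0, deg_R=0.7)
        traj = simulate(p, init=(2.0, 0.0), t_end=5.0, n_out=11)
        expected = 2.0 * np.exp(-0.7 * traj[:, 0])
        np.testing.assert_allclose(traj[:, 1], expected, rtol=1e-6,
                                   atol=1e-9)

    def test_long_run_matches_steady_state(self, wt_params):
        traj = simulate(wt_params, t_end=200.0)
        [ss] = steady_states(wt_params)
        assert traj[-1, 1] == pytest.approx(ss.R_star, rel=1e-6)
        assert traj[-1, 2] == pytest.approx(ss.G_star, rel=1e-6)

    def test_invalid_inputs(self, wt_params):
        with pytest.raises(InvalidArgument):
            simulate(wt_params, t_end=0.0)
        with pytest.raises(InvalidArgument):
            simulate(wt_params, init=(-1.0, 0.0))


class TestSteadyStates:
    def test_eqn2_unit_params_has_exactly_one(self, wt_params):
        states = steady_states(wt_params)
        assert len(states) == 1
        assert states[0].stable

    def test_eqn1_count_surfaced(self):
        # The implemented promoter logic provably yields exactly one
        # nonnegative steady state for EQN1 as well (the reduced
        # one-dimensional equation is strictly decreasing); the count is
        # surfaced rather than assumed.
        states = steady_states(ModelParams(variant="EQN1"))
        assert len(states) == 1

    def test_k2_zero_closed_form_to_1e10(self, wt_params):
        [ss] = steady_states(wt_params.with_(k2=0.0))
        assert abs(ss.R_star - wt_params.k1 / wt_params.deg_R) < 1e-10
        assert abs(ss.G_star) < 1e-10

    def test_residuals_below_tolerance_independently(self, wt_params):
        for k2 in (0.3, 1.0, 7.0):
            for ss in steady_states(wt_params.with_(k2=k2)):
                dR, dG = rhs((ss.R_star, ss.G_star), wt_params.with_(k2=k2))
                assert max(abs(dR), abs(dG)) < 1e-8

    def test_counts_across_random_positive_parameters(self):
        # log-uniform sample; EQN2 must always have exactly one state in
        # the closed nonnegative quadrant, and it must be stable
        rng = np.random.default_rng(42)
        for _ in range(30):
            vals = 10.0 ** rng.uniform(-1.5, 1.5, 7)
            p = ModelParams(k1=vals[0], k2=vals[1], deg_R=vals[2],
                            deg_G=vals[3], hill_K_RG=vals[4],
                            hill_K_GR=vals[5], hill_K_GG=vals[6],
                            n1=float(rng.integers(1, 4)),
                            n_R=float(rng.integers(1, 4)))
            states = steady_states(p)
            assert len(states) == 1
            assert states[0].stable

    def test_convergence_from_random_initial_states(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            vals = 10.0 ** rng.uniform(-1.0, 1.0, 4)
            p = ModelParams(k1=vals[0], k2=vals[1], hill_K_GR=vals[2],
                            hill_K_RG=vals[3])
            [ss] = steady_states(p)
            for _ in range(5):
                init = rng.uniform(0.0, 5.0, 2)
                traj = simulate(p, init=init, t_end=400.0, n_out=3)
                assert traj[-1, 1] == pytest.approx(ss.R_star, rel=1e-5,
                                                    abs=1e-8)
                assert traj[-1, 2] == pytest.approx(ss.G_star, rel=1e-5,
                                                    abs=1e-8)

    def test_monotone_in_k2(self, wt_params):
        rng = np.random.default_rng(9)
        for _ in range(10):
            vals = 10.0 ** rng.uniform(-1.0, 1.0, 3)
            p = ModelParams(k1=vals[0], hill_K_GR=vals[1], hill_K_RG=vals[2])
            k2_grid = np.linspace(0.0, 10.0, 15)
            R, G = steady_state_batch(
                {"k2": k2_grid}, base=p)
            assert np.all(np.diff(R) <= 1e-9)   # R* non-increasing
            assert np.all(np.diff(G) >= -1e-9)  # G* non-decreasing

    def test_batch_agrees_with_scan(self, wt_params):
        R, G = steady_state_batch({"k2": np.array([0.0, 0.5, 2.0])},
                                  base=wt_params)
        for k2, r, g in zip((0.0, 0.5, 2.0), R, G):
            [ss] = steady_states(wt_params.with_(k2=k2))
            assert r == pytest.approx(ss.R_star, rel=1e-8, abs=1e-10)
            assert g == pytest.approx(ss.G_star, rel=1e-8, abs=1e-10)


class TestCalibration:
    def test_identity_fold(self, wt_params):
        assert calibrate_overexpression(wt_params, 1.0).k2 \
            == pytest.approx(wt_params.k2, rel=1e-6)

    def test_fold_15_reached_and_rsl4_falls(self, wt_params):
        oe = calibrate_overexpression(wt_params, 15.0)
        assert oe.k2 > wt_params.k2
        assert solve_gstar(oe) / solve_gstar(wt_params) \
            == pytest.approx(15.0, rel=1e-6)
        [ss_oe] = steady_states(oe)
        [ss_wt] = steady_states(wt_params)
        assert ss_oe.R_star < ss_wt.R_star

    def test_null_wild_type_rejected(self, wt_params):
        with pytest.raises(CalibrationError):
            calibrate_overexpression(wt_params.with_(k2=0.0), 15.0)


class TestScenarios:
    def test_three_scenarios_with_expected_directions(self, wt_params):
        wt, oe, null = genotype_scenarios(wt_params, t_end=60.0, n_out=31)
        assert (wt.label, oe.label, null.label) == ("WT", "OE", "NULL")
        assert wt.ratio_R == pytest.approx(1.0) \
            and wt.ratio_G == pytest.approx(1.0)
        # overexpression of the repressor lowers RSL4
        assert oe.ratio_G == pytest.approx(15.0, rel=1e-6)
        assert oe.ratio_R < 1.0
        # the double null de-represses RSL4 to the closed form k1/deg_R
        assert null.steady_state.G_star == 0.0
        assert abs(null.steady_state.R_star
                   - wt_params.k1 / wt_params.deg_R) < 1e-10
        assert null.ratio_R > 1.0

    def test_trajectories_shape_and_nonnegativity(self, wt_params):
        for sc in genotype_scenarios(wt_params, t_end=30.0, n_out=16):
            assert sc.trajectory.shape == (16, 3)
            assert (sc.trajectory[:, 1:] >= 0.0).all()
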