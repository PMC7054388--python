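"""Integration engine tests: closed forms, the RK4 oracle, termination and
summaries."""

import math

import numpy as np
import pytest

from clonalgc import (
    GCParameters,
    SeedingConfig,
    SolverSettings,
    StateLayout,
    Trajectory,
    conservation_residual,
    detect_termination,
    integrate,
    rk4_reference,
    summarize,
)


def _relerr(a, b, floor=1e-3):
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), floor))


class TestRK4ClosedForms:
    def test_pure_b_cell_decay_without_selection(self):
        """With sigma = sigma_c = 0 the founder cells just die at d_B."""
        p = GCParameters(n=3, sigma=0.0, sigma_c=0.0)
        traj = rk4_reference(p, SeedingConfig(), dt=1e-3, t_end=1.0)
        lay = StateLayout(3)
        expected = 50.0 * math.exp(-0.8)
        assert traj.states[-1, lay.B1.start] == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(22.466, abs=1e-3)

    def test_tfh_exponential_decay_without_b_cells(self):
        p = GCParameters(n=3)
        seeding = SeedingConfig(B1_0=0, B2_0=0)
        traj = rk4_reference(p, seeding, dt=1e-2, t_end=10.0)
        lay = StateLayout(3)
        assert traj.states[-1, lay.G1] == pytest.approx(
            5000 * math.exp(-0.1), rel=1e-8
        )

    def test_invalid_step_rejected(self, toy_params):
        with pytest.raises(ValueError):
            rk4_reference(toy_params, dt=0.0)

    def test_fourth_order_refinement(self, toy_params):
        """Halving dt cuts the error against a much finer run ~16x."""
        ref = rk4_reference(toy_params, dt=0.0025, t_end=2.0).states[-1]
        e1 = np.abs(rk4_reference(toy_params, dt=0.04, t_end=2.0).states[-1] - ref)
        e2 = np.abs(rk4_reference(toy_params, dt=0.02, t_end=2.0).states[-1] - ref)
        ratio = e1.max() / e2.max()
        assert 10 < ratio < 24


class TestAdaptiveIntegration:
    def test_matches_rk4_oracle_on_toy_system(self, toy_params):
        """Adaptive and fixed-step paths agree componentwise on n=2."""
        probe = np.arange(1.0, 30.1, 1.0)
        adaptive = integrate(toy_params, settings=SolverSettings(t_max=30.0,
                             termination_floor=1e-9), t_eval=probe)
        fixed = rk4_reference(toy_params, dt=1e-3, t_end=30.0)
        fixed_at = {round(t, 9): s for t, s in zip(fixed.times, fixed.states)}
        for t, state in zip(adaptive.times, adaptive.states):
            key = round(float(t), 9)
            if key in fixed_at:
                assert _relerr(state, fixed_at[key]) < 1e-5

    def test_baseline_rises_then_collapses(self, baseline_params):
        traj = integrate(baseline_params)
        tb = traj.total_B
        assert tb.max() > 3 * tb[0]
        assert traj.terminated
        assert 20 < traj.termination_time < 30

    def test_symmetry_limit_clones_identical(self):
        """eta = f = 0 with sigma_c = 0.5 sigma and equal seeding makes the
        two clones' selection inputs coincide, so their trajectories match."""
        p = GCParameters(n=8, eta=0.0, f=0.0)
        traj = integrate(p)
        lay = traj.layout
        b1, b2 = traj.states[:, lay.B1], traj.states[:, lay.B2]
        assert _relerr(b1, b2, floor=1e-6) < 1e-8
        assert _relerr(traj.P1, traj.P2, floor=1e-6) < 1e-8

    def test_clone_decoupling_with_empty_seed(self, baseline_params):
        traj = integrate(baseline_params, SeedingConfig(B1_0=0, B2_0=100))
        lay = traj.layout
        assert np.all(traj.states[:, lay.B1] == 0.0)
        assert np.all(traj.states[:, lay.H1] == 0.0)
        expected = 5000 * np.exp(-0.01 * traj.times)
        np.testing.assert_allclose(traj.states[:, lay.G1], expected, rtol=1e-7)

    def test_plasma_monotone_along_trajectory(self, baseline_params):
        traj = integrate(baseline_params)
        assert np.all(np.diff(traj.P1) >= -1e-9)
        assert np.all(np.diff(traj.P2) >= -1e-9)

    def test_termination_monotone_in_death_rate(self):
        """Raising the B-cell death rate never prolongs the reaction."""
        times = [integrate(GCParameters(n=8, d_B=db)).termination_time
                 for db in (0.7, 0.8, 0.9)]
        assert times[0] >= times[1] >= times[2]


class TestTerminationDetection:
    def test_exponential_decay_closed_form(self):
        """Without selection, 100 founders cross 1 cell at ln(100)/d_B."""
        p = GCParameters(n=3, sigma=0.0, sigma_c=0.0)
        traj = integrate(p, settings=SolverSettings(t_max=40.0))
        t_star = detect_termination(traj, floor=1.0)
        assert t_star == pytest.approx(math.log(100) / 0.8, abs=1e-3)
        assert traj.termination_time == pytest.approx(t_star, abs=1e-3)

    def test_degenerate_empty_seeding_warns(self, toy_params):
        traj = integrate(toy_params, SeedingConfig(B1_0=0, B2_0=0),
                         SolverSettings(t_max=5.0))
        with pytest.warns(UserWarning):
            assert math.isnan(detect_termination(traj))

    def test_never_collapsing_horizon_warns(self, baseline_params):
        traj = integrate(baseline_params, settings=SolverSettings(t_max=10.0))
        assert not traj.terminated
        with pytest.warns(UserWarning):
            assert math.isnan(detect_termination(traj))


class TestSummaries:
    @pytest.mark.parametrize("p1, p2, label", [
        (150.0, 50.0, "monoclonal_broad"),
        (50.0, 150.0, "monoclonal_specific"),
        (150.0, 150.0, "biclonal"),
        (50.0, 50.0, "none"),
        (100.0, 150.0, "monoclonal_specific"),  # threshold is strict
    ])
    def test_clonality_labels(self, toy_params, p1, p2, label):
        lay = StateLayout(2)
        states = np.zeros((2, lay.size))
        states[1, lay.P1], states[1, lay.P2] = p1, p2
        traj = Trajectory(times=np.array([0.0, 1.0]), states=states,
                          params=toy_params)
        out = summarize(traj)
        assert out.clonality == label
        assert out.success_1 == (p1 > 100) and out.success_2 == (p2 > 100)

    def test_baseline_biclonal_with_comparable_output(self, baseline_params):
        out = summarize(integrate(baseline_params))
        assert out.clonality == "biclonal"
        assert abs(out.P1_final - out.P2_final) < 0.1 * out.P1_final

    def test_empty_trajectory_rejected(self, toy_params):
        traj = Trajectory(times=np.empty(0),
                          states=np.empty((0, StateLayout(2).size)),
                          params=toy_params)
        with pytest.raises(ValueError):
            summarize(traj)


class TestConservation:
    def test_residual_small_on_baseline(self, baseline_params):
        traj = integrate(baseline_params)
        assert conservation_residual(traj, baseline_params) < 1e-6

    def test_residual_tiny_without_availability_exchange(self):
        p = GCParameters(n=8, eta=0.0, f=0.0)
        traj = integrate(p)
        assert conservation_residual(traj, p) < 1e-8

    def test_perturbed_trajectory_detected(self, baseline_params):
        traj = integrate(baseline_params)
        lay = traj.layout
        corrupted = traj.states.copy()
        corrupted[len(corrupted) // 2:, lay.G1] *= 1.01
        bad = Trajectory(times=traj.times, states=corrupted,
                         params=baseline_params)
        assert conservation_residual(bad, baseline_params) > 1e-3


class TestTrajectoryExport:
    def test_tidy_frame_shape_and_content(self, toy_params):
        traj = integrate(toy_params, settings=SolverSettings(t_max=5.0))
        frame = traj.to_frame()
        assert list(frame.columns) == ["time", "variable", "clone", "stage",
                                       "value"]
        assert len(frame) == traj.times.size * StateLayout(2).size
        assert set(frame["variable"]) == {"G", "H", "B", "P"}
        b_stages = frame.loc[frame["variable"] == "B", "stage"]
        assert set(b_stages.dropna()) == {0, 1, 2}

    def test_csv_round_trip(self, toy_params, tmp_path):
        import pandas as pd

        traj = integrate(toy_params, settings=SolverSettings(t_max=5.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == len(traj.to_frame())
        assert back["value"].iloc[0] == pytest.approx(traj.states[0, 0])
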