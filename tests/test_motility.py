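import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from motile_ctrw import (
    Trajectory,
    build_master,
    convert_units,
    drift_speed,
    empirical_pdf,
    ensemble_moments,
    log_bin_edges,
    segment_steps,
    step_correlation,
)


def um_traj(x, y, freq=4.0, cell_id=0):
    x = np.asarray(x, dtype=float)
    return Trajectory(cell_id, np.arange(x.size) / freq, x, np.asarray(y, float), "um")


class TestConvertUnits:
    def test_camera_conversion_conventions(self):
        """1000 frames @ 8 Hz = 125 s; 1 px @ 20X = 0.65 µm; window 665.6 µm."""
        traj = Trajectory(0, [0.0, 1000.0], [0.0, 1.0], [0.0, 1024.0], "px")
        out = convert_units(traj, frequency=8.0, magnification=20.0)
        assert out.t[1] == pytest.approx(125.0)
        assert out.x[1] == pytest.approx(0.65)
        assert out.y[1] == pytest.approx(665.6)

    def test_50x_pixel_size(self):
        traj = Trajectory(0, [0.0, 1.0], [0.0, 1.0], [0.0, 0.0], "px")
        out = convert_units(traj, frequency=4.0, magnification=50.0)
        assert out.x[1] == pytest.approx(0.26)

    @pytest.mark.parametrize("freq,mag", [(0.0, 20.0), (8.0, -1.0)])
    def test_invalid_metadata_rejected(self, freq, mag):
        traj = Trajectory(0, [0.0, 1.0], [0.0, 1.0], [0.0, 0.0], "px")
        with pytest.raises(ValueError):
            convert_units(traj, freq, mag)


class TestSegmentSteps:
    def test_straight_run_is_one_step_with_total_length(self):
        x = np.arange(20) * 5.0  # 5 µm per frame, straight
        steps = segment_steps(um_traj(x, np.zeros(20)), body_length=3.0)
        assert len(steps) == 1
        assert steps.loc[0, "eps_um"] == pytest.approx(19 * 5.0)
        assert steps.loc[0, "tau_wait_s"] == 0.0

    def test_right_angle_turn_splits_into_two_steps(self):
        x = np.concatenate([np.arange(10) * 5.0, np.full(9, 45.0)])
        y = np.concatenate([np.zeros(10), np.arange(1, 10) * 5.0])
        steps = segment_steps(um_traj(x, y), body_length=3.0)
        assert len(steps) == 2
        np.testing.assert_allclose(steps["eps_um"], [45.0, 45.0])

    def test_sub_body_jitter_accumulates_into_waiting_time(self):
        """40 sub-body displacements of jitter, then one run: tau_wait = 40/freq."""
        rng = np.random.default_rng(0)
        jitter = rng.uniform(-0.5, 0.5, size=(41, 2))  # << body length 3 µm
        run = np.cumsum(np.full((10, 2), [5.0, 0.0]), axis=0) + jitter[-1]
        xy = np.vstack([jitter, run])
        steps = segment_steps(um_traj(xy[:, 0], xy[:, 1]), body_length=3.0)
        assert len(steps) == 1
        assert steps.loc[0, "tau_wait_s"] == pytest.approx(40 / 4.0)
        assert steps.loc[0, "tau_run_s"] == pytest.approx(10 / 4.0)

    def test_pure_wait_trajectory_emits_terminal_wait_record(self):
        steps = segment_steps(um_traj(np.zeros(21), np.zeros(21)), body_length=3.0)
        assert len(steps) == 1
        assert steps.loc[0, "eps_um"] == 0.0
        assert steps.loc[0, "tau_s"] == pytest.approx(5.0)

    def test_small_turns_extend_the_run(self):
        # 3° per frame stays inside the ±5° deviation from the run mean
        angles = np.deg2rad(np.cumsum(np.r_[0.0, np.full(3, 2.0)]))
        xy = np.vstack([[0, 0], np.cumsum(
            5.0 * np.column_stack([np.cos(angles), np.sin(angles)]), axis=0)])
        steps = segment_steps(um_traj(xy[:, 0], xy[:, 1]), body_length=3.0)
        assert len(steps) == 1

    def test_too_short_trajectory_gives_empty_table(self):
        assert len(segment_steps(um_traj([0.0], [0.0]), body_length=3.0)) == 0

    @given(st.floats(0.0, 2 * np.pi), st.floats(-50.0, 50.0), st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rotation_and_translation_invariance(self, angle, tx, ty):
        rng = np.random.default_rng(12)
        xy = np.cumsum(rng.normal(0, 4.0, size=(30, 2)), axis=0)
        base = segment_steps(um_traj(xy[:, 0], xy[:, 1]), body_length=3.0)
        c, s = np.cos(angle), np.sin(angle)
        rot = xy @ np.array([[c, s], [-s, c]]) + [tx, ty]
        moved = segment_steps(um_traj(rot[:, 0], rot[:, 1]), body_length=3.0)
        assert len(base) == len(moved)
        np.testing.assert_allclose(moved["eps_um"], base["eps_um"], atol=1e-8)
        np.testing.assert_allclose(moved["tau_s"], base["tau_s"], atol=1e-9)

    def test_taus_partition_the_trajectory_duration(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 4.0, size=(80, 2)), axis=0)
        traj = um_traj(xy[:, 0], xy[:, 1])
        steps = segment_steps(traj, body_length=3.0)
        assert steps["tau_s"].sum() == pytest.approx(traj.duration, abs=0.25)


class TestMasterTable:
    def test_concatenation_preserves_rows_and_order(self):
        a = segment_steps(um_traj(np.arange(10) * 5.0, np.zeros(10), cell_id=1), 3.0)
        x = np.concatenate([np.arange(10) * 5.0, np.full(9, 45.0)])
        y = np.concatenate([np.zeros(10), np.arange(1, 10) * 5.0])
        b = segment_steps(um_traj(x, y, cell_id=2), 3.0)
        master = build_master([a, b])
        assert len(master) == len(a) + len(b)
        assert list(master["cell_id"].unique()) == [1, 2]

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            master = build_master([])
        assert len(master) == 0

    def test_master_marginal_matches_generator(self, segmentable_ensemble):
        """Segmented jump lengths agree with the ground-truth marginal (KS)."""
        params, trajs, truth = segmentable_ensemble
        master = build_master(
            [segment_steps(t, params.body_length) for t in trajs]
        )
        seg = np.round(master.loc[master["eps_um"] > 0, "eps_um"].to_numpy(), 6)
        ref = np.round(truth["eps_um"].to_numpy(), 6)
        assert len(master) >= 10_000
        assert stats.ks_2samp(seg, ref).pvalue > 0.01


class TestEmpiricalPDF:
    def test_point_mass_occupies_one_bin(self):
        pdf = empirical_pdf(np.full(50, 2.5), np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(pdf.density, [0.0, 0.0, 1.0])

    def test_uniform_samples_have_unit_density(self):
        rng = np.random.default_rng(0)
        pdf = empirical_pdf(rng.uniform(0, 1, 200_000), np.linspace(0, 1, 11))
        np.testing.assert_allclose(pdf.density, 1.0, atol=0.05)

    def test_exponential_density_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.exponential(1.0, n)
        edges = np.linspace(0.0, 5.0, 26)
        pdf = empirical_pdf(x, edges)
        for left, right, dens in zip(edges[:-1], edges[1:], pdf.density):
            p = np.exp(-left) - np.exp(-right)
            se = np.sqrt(p * (1 - p) / n) / (right - left)
            # in-range renormalisation inflates densities by 1/P(X<5)
            expect = p / (right - left) / (1 - np.exp(-5.0))
            assert abs(dens - expect) < 4 * se + 1e-3

    @given(st.integers(1, 500), st.integers(2, 40))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_density_integrates_to_one(self, n, bins):
        rng = np.random.default_rng(n)
        x = rng.exponential(2.0, n)
        edges = np.linspace(0.0, float(x.max()) + 1.0, bins + 1)
        pdf = empirical_pdf(x, edges)
        assert np.all(pdf.density >= 0)
        assert np.sum(pdf.density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_log_bins_and_empty_values_rejected(self):
        edges = log_bin_edges(0.1, 100.0, 30)
        assert np.allclose(np.diff(np.log10(edges)), np.diff(np.log10(edges))[0])
        with pytest.raises(ValueError):
            empirical_pdf([], edges)


class TestEnsembleMoments:
    def test_identical_trajectories_have_zero_variance(self):
        xy = np.cumsum(np.full((30, 2), 2.0), axis=0)
        trajs = [um_traj(xy[:, 0], xy[:, 1], cell_id=i) for i in range(60)]
        mom = ensemble_moments(trajs, min_unique=50)
        np.testing.assert_allclose(mom.variance, 0.0, atol=1e-18)

    def test_deterministic_radial_motion_mean_is_exact(self):
        trajs = []
        for i in range(60):
            th = 2 * np.pi * i / 60
            t = np.arange(30) / 4.0
            trajs.append(Trajectory(i, t, 2.0 * t * np.cos(th), 2.0 * t * np.sin(th)))
        mom = ensemble_moments(trajs, min_unique=50)
        np.testing.assert_allclose(mom.mean_disp, 2.0 * mom.times, atol=1e-9)
        assert drift_speed(mom) == pytest.approx(2.0)

    def test_brownian_variance_slope(self, brownian_trajs):
        """Radial variance of a 2-D Brownian ensemble grows as 4 D0 t."""
        trajs, D0 = brownian_trajs
        mom = ensemble_moments(trajs, min_unique=50)
        slope = np.polyfit(mom.times, mom.variance, 1)[0]
        assert slope == pytest.approx(4 * D0, rel=0.05)

    def test_series_truncated_at_unique_trajectory_cutoff(self):
        long = [um_traj(np.arange(40) * 5.0, np.zeros(40), cell_id=i) for i in range(60)]
        short = [um_traj(np.arange(10) * 5.0, np.zeros(10), cell_id=100 + i) for i in range(5)]
        mom = ensemble_moments(long + short, min_unique=60)
        assert np.all(mom.n_alive >= 60)
        assert mom.times[-1] == pytest.approx(39 / 4.0)

    def test_no_sufficient_coverage_warns_and_returns_empty(self):
        trajs = [um_traj(np.arange(10) * 5.0, np.zeros(10))]
        with pytest.warns(UserWarning):
            mom = ensemble_moments(trajs, min_unique=50)
        assert len(mom) == 0
        with pytest.raises(ValueError):
            drift_speed(mom)


class TestStepCorrelation:
    @staticmethod
    def master_from(eps, tau, cell_id=0):
        n = len(eps)
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "step_index": np.arange(n),
                "dx_um": eps,
                "dy_um": 0.0,
                "eps_um": eps,
                "tau_s": tau,
                "tau_wait_s": 0.0,
                "tau_run_s": tau,
            }
        )

    def test_iid_steps_are_uncorrelated(self):
        rng = np.random.default_rng(0)
        m = self.master_from(rng.exponential(5, 5000), rng.exponential(2, 5000))
        corr = step_correlation(m)
        bound = 3.0 / np.sqrt(corr.n_pairs_eps)
        assert abs(corr.eps_corr) < bound and abs(corr.tau_corr) < bound

    def test_alternating_waits_are_anticorrelated(self):
        tau = np.tile([10.0, 0.5], 50)
        m = self.master_from(np.full(100, 5.0) + np.random.default_rng(1).normal(0, 0.1, 100), tau)
        assert step_correlation(m).tau_corr < -0.9

    def test_injected_jump_correlation_recovered(self, segmentable_ensemble):
        params, _, truth = segmentable_ensemble
        assert abs(step_correlation(truth).eps_corr) < 0.05  # corr 0 injected

    def test_pairs_do_not_cross_cells_and_sparse_flag(self):
        a = self.master_from([1.0, 2.0], [1.0, 1.0], cell_id=0)
        b = self.master_from([100.0, 200.0], [1.0, 1.0], cell_id=1)
        corr = step_correlation(pd.concat([a, b], ignore_index=True))
        assert corr.n_pairs_eps == 2  # one pair per cell, none across
        assert corr.sparse
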