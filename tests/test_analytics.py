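"""Physical-unit conversion and the behavioral metrics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from geotrack import (
    CoordinateMatrix,
    ROI,
    RunConfig,
    Trajectory,
    bootstrap_rho_ratio,
    climbing_curve,
    detect_drops,
    first_crossing_time,
    speed_angle,
    summarize,
    to_physical,
    turning_rate,
)
from geotrack.analytics import summarize_fly, write_summary_json

DT = 1 / 30


def traj_from_y(y_mm, dt=DT):
    pos = np.column_stack([np.zeros(len(y_mm)), y_mm])
    return Trajectory(pos, dt=dt)


def traj_from_xy(x_mm, y_mm, dt=DT):
    return Trajectory(np.column_stack([x_mm, y_mm]), dt=dt)


class TestToPhysical:
    def test_y_flip_and_scale(self):
        roi = ROI(0, 0, 50, 140)
        positions = np.zeros((1, 2, 2))
        positions[0, :, 1] = [140, 130.3]  # px from the top
        matrix = CoordinateMatrix(positions=positions)
        (traj,) = to_physical(matrix, roi, px_per_mm=4.85, dt=DT)
        assert traj.y_mm[0] == pytest.approx(0.0)  # ROI bottom
        assert traj.y_mm[1] == pytest.approx(9.7 / 4.85)  # 9.7 px = 2 mm

    def test_x_unchanged_by_flip(self):
        roi = ROI(0, 0, 50, 140)
        positions = np.zeros((1, 2, 2))
        positions[0, :, 0] = [9.7, 19.4]
        matrix = CoordinateMatrix(positions=positions)
        (traj,) = to_physical(matrix, roi, px_per_mm=4.85, dt=DT)
        assert np.allclose(traj.positions_mm[:, 0], [2.0, 4.0])

    def test_bad_scale(self):
        matrix = CoordinateMatrix(positions=np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            to_physical(matrix, ROI(0, 0, 5, 5), px_per_mm=0, dt=DT)


class TestSpeedAngle:
    def test_three_four_five_triangle(self):
        traj = traj_from_xy([0, 0.9], [0, 1.2])
        series = speed_angle(traj)
        assert series.dr_mm[0] == pytest.approx(1.5)
        assert series.speed_mm_s[0] == pytest.approx(45.0)
        assert series.theta_deg[0] == pytest.approx(np.degrees(np.arctan2(1.2, 0.9)), abs=1e-6)
        assert series.theta_deg[0] == pytest.approx(53.13, abs=0.01)

    def test_leftward_equals_rightward(self):
        left = speed_angle(traj_from_xy([0, -1], [0, 1]))
        right = speed_angle(traj_from_xy([0, 1], [0, 1]))
        assert left.theta_deg[0] == pytest.approx(45.0)
        assert left.theta_deg[0] == right.theta_deg[0]

    def test_gate_is_inclusive(self):
        series = speed_angle(traj_from_xy([0, 4.0], [0, 0]), gate_mm=4.0)
        assert series.gated[0]
        assert np.isnan(series.speed_mm_s[0]) and np.isnan(series.theta_deg[0])

    def test_stationary_pair_has_no_angle_but_zero_speed(self):
        series = speed_angle(traj_from_xy([1, 1], [2, 2]))
        assert np.isnan(series.theta_deg[0])
        assert series.speed_mm_s[0] == 0.0
        assert not series.gated[0]

    def test_pure_vertical_angles(self):
        up = speed_angle(traj_from_xy([0, 0], [0, 1]))
        down = speed_angle(traj_from_xy([0, 0], [1, 0]))
        assert up.theta_deg[0] == pytest.approx(90.0)
        assert down.theta_deg[0] == pytest.approx(-90.0)


class TestTurningRate:
    def test_constant_angle_never_turns(self):
        y = np.arange(31) * 0.5
        assert turning_rate(speed_angle(traj_from_y(y))) == 0.0

    def test_alternating_direction_turns_every_pair(self):
        # theta flips between +45 and -45 every frame for 1 s at 30 Hz:
        # 30 angle samples give 29 consecutive non-zero changes
        steps = np.tile([1.0, -1.0], 15)
        x = np.arange(31) * 0.5
        y = np.concatenate([[0], np.cumsum(steps * 0.5)])
        rate = turning_rate(speed_angle(traj_from_xy(x, y)))
        assert rate == pytest.approx(29.0)

    def test_undefined_angle_breaks_the_chain(self):
        # up, up, stationary, right: the only defined consecutive pair
        # with equal angles contributes nothing; no pair straddles the gap
        y = np.array([0, 1, 2, 2, 2])
        x = np.array([0, 0, 0, 0, 1])
        assert turning_rate(speed_angle(traj_from_xy(x, y))) == 0.0


class TestClimbingCurve:
    def test_first_crossing_only_counted_once(self):
        y = np.concatenate([np.linspace(0, 80, 61), np.linspace(80, 40, 30), np.linspace(40, 90, 30)])
        traj = traj_from_y(y)
        t = first_crossing_time(traj, 70.0)
        # crosses 70 mm on the way up and never again counts
        first_above = np.nonzero(y > 70)[0][0]
        assert t == pytest.approx(first_above * DT)
        curve = climbing_curve([[traj]], 70.0)
        assert len(curve.times) == 1 and curve.times[0] == t

    def test_no_crossing_gives_flat_zero(self):
        curve = climbing_curve([[traj_from_y(np.linspace(0, 30, 50))]], 70.0)
        assert curve.times.size == 0

    def test_trial_average_steps(self):
        t1 = traj_from_y(np.concatenate([[0], np.full(99, 80.0)]))  # crosses at frame 1
        t2 = traj_from_y(np.concatenate([np.zeros(91), np.full(9, 80.0)]))  # crosses at frame 91
        curve = climbing_curve([[t1], [t2]], 70.0)
        assert np.allclose(curve.mean_counts, [0.5, 1.0])
        assert curve.n_trials == 2

    def test_monotone_and_bounded(self, rng):
        trials = []
        for _ in range(4):
            trajs = [traj_from_y(np.cumsum(rng.normal(0.5, 2.0, size=200)).clip(0, 140)) for _ in range(7)]
            trials.append(trajs)
        curve = climbing_curve(trials, 46.67)
        assert (np.diff(curve.mean_counts) >= -1e-12).all()
        assert curve.mean_counts.size == 0 or curve.mean_counts[-1] <= 7

    def test_identical_trials_reproduce_single_staircase(self):
        y = np.linspace(0, 100, 80)
        curve = climbing_curve([[traj_from_y(y)]] * 3, 70.0)
        assert np.allclose(curve.mean_counts, 1.0)
        assert np.allclose(curve.sem_counts, 0.0)

    def test_target_above_vial_rejected(self):
        with pytest.raises(ValueError, match="exceeds vial height"):
            climbing_curve([[traj_from_y(np.zeros(10))]], 150.0, vial_height_mm=140.0)


class TestDrops:
    def test_slip_fall_boundaries(self):
        events = detect_drops(traj_from_y([50, 38.0, 38, 25.9, 25.9, 21.4]))
        kinds = [e.kind for e in events]
        drops = [e.drop_mm for e in events]
        assert kinds == ["slip", "fall", "slip"]  # 12.0 slip, 12.1 fall, 4.5 slip
        assert drops == pytest.approx([12.0, 12.1, 4.5])

    def test_below_slip_min_ignored(self):
        assert detect_drops(traj_from_y([50, 45.6])) == []

    def test_full_drop_has_ratio_one(self):
        (event,) = detect_drops(traj_from_y([20, 0.0]))
        assert event.kind == "fall"
        assert event.ratio == pytest.approx(1.0)
        assert event.pre_drop_height_mm == pytest.approx(20.0)

    def test_drops_and_speed_series_are_disjoint(self, rng):
        # any pair counted as a slip/fall (>= 4.5 mm drop) necessarily
        # exceeds the 4 mm displacement gate and so is excluded from (s, θ)
        for _ in range(20):
            y = np.cumsum(rng.normal(0, 3.0, size=100)).clip(0, 140)
            traj = traj_from_y(y)
            series = speed_angle(traj, gate_mm=4.0)
            for event in detect_drops(traj):
                assert series.gated[event.frame_index]
                assert np.isnan(series.speed_mm_s[event.frame_index])


from oracles import spearman_oracle


class TestSpearman:
    @pytest.mark.filterwarnings("ignore:An input array is constant")
    def test_scipy_matches_rank_pearson_oracle_with_ties(self, rng):
        # the implementation's Spearman (scipy) against a brute-force
        # average-rank + Pearson oracle on small tied datasets
        for _ in range(300):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 3, size=n).astype(float)
            y = rng.integers(0, 3, size=n).astype(float)
            expected = spearman_oracle(x, y)
            got = stats.spearmanr(x, y).statistic
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestBootstrapRho:
    def test_perfect_monotonicity_gives_unit_ratio(self):
        theta = np.concatenate([np.linspace(5, 80, 50), np.linspace(-80, -5, 50)])
        speed = theta + 100.0  # strictly increasing with theta in both strata
        est = bootstrap_rho_ratio(speed, theta, n_replicates=50, seed=0)
        assert est.rho_plus == pytest.approx(1.0)
        assert est.rho_minus == pytest.approx(1.0)
        assert est.ratio_mean == pytest.approx(1.0)
        assert est.ratio_sd == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(-80, 80, 400)
        speed = rng.uniform(0, 30, 400) + 0.1 * theta
        a = bootstrap_rho_ratio(speed, theta, n_replicates=100, seed=11)
        b = bootstrap_rho_ratio(speed, theta, n_replicates=100, seed=11)
        assert a.ratio_mean == b.ratio_mean and a.ratio_sd == b.ratio_sd

    def test_sample_size_matches_data(self):
        theta = np.concatenate([np.linspace(10, 80, 10), np.linspace(-80, -10, 10)])
        speed = np.arange(20, dtype=float)
        est = bootstrap_rho_ratio(speed, theta, n_replicates=10, seed=0)
        assert est.n_sample == 20

    def test_degenerate_stratum_rejected(self):
        theta = np.full(20, 30.0)  # no downward movements at all
        with pytest.raises(ValueError, match="stratum"):
            bootstrap_rho_ratio(np.arange(20.0), theta, n_replicates=10, seed=0)

    def test_tiny_stratum_replicates_are_discarded_and_counted(self):
        theta = np.concatenate([np.linspace(10, 80, 30), [-10.0, -20.0, -30.0]])
        speed = np.arange(33, dtype=float)
        est = bootstrap_rho_ratio(speed, theta, n_replicates=200, seed=1)
        assert est.n_discarded > 0
        assert est.n_discarded < 200


class TestSummarize:
    def constant_up_trial(self, speed_mm_s=10.0, seconds=10.0):
        n = int(seconds * 30) + 1
        y = np.arange(n) * speed_mm_s * DT
        return traj_from_y(y)

    def test_constant_climber_summary(self):
        traj = self.constant_up_trial()
        cfg = RunConfig(rng_seed=0, target_heights_mm=[46.67, 70.0], vial_height_mm=140.0)
        summary = summarize({"wt": [[traj]]}, cfg)
        fly = summary.groups[0]["flies"][0]
        assert fly.ave_speed == pytest.approx(10.0)
        assert fly.ave_angle == pytest.approx(90.0)
        assert fly.distance_traveled == pytest.approx(100.0)
        assert fly.turn_rate == 0.0
        assert fly.n_slips == 0 and fly.n_falls == 0

    def test_identical_flies_share_group_mean(self):
        traj = self.constant_up_trial()
        cfg = RunConfig(rng_seed=0, target_heights_mm=[70.0])
        summary = summarize({"wt": [[traj, traj]]}, cfg)
        speeds = [f.ave_speed for f in summary.groups[0]["flies"]]
        assert speeds[0] == speeds[1] == pytest.approx(np.mean(speeds))

    def test_matlab_style_query_path_resolves(self):
        traj = self.constant_up_trial()
        cfg = RunConfig(rng_seed=0, target_heights_mm=[70.0])
        summary = summarize({"wt": [[traj, traj]]}, cfg)
        assert summary.resolve("Group(1).Fly_no(2).AveSpeed") == pytest.approx(10.0)
        assert summary.resolve("Group(1).Names") == "wt"
        with pytest.raises(KeyError):
            summary.resolve("Group(1).Fly_no(2).Nope")

    def test_summary_json_written(self, tmp_path):
        traj = self.constant_up_trial()
        cfg = RunConfig(rng_seed=0, target_heights_mm=[70.0])
        summary = summarize({"wt": [[traj]]}, cfg)
        out = tmp_path / "summary.json"
        write_summary_json(summary, out)
        import json

        payload = json.loads(out.read_text())
        assert payload["groups"][0]["flies"][0]["ave_speed"] == pytest.approx(10.0)

    def test_gated_pairs_omitted_from_average_speed(self):
        # one artifactual 6 mm jump in an otherwise 10 mm/s climb must not
        # inflate the average speed
        y = np.concatenate([np.arange(10) * (10.0 * DT), [10 * 10.0 * DT + 6.0]])
        fly = summarize_fly(traj_from_y(y), RunConfig(rng_seed=0, target_heights_mm=[70.0]))
        assert fly.ave_speed == pytest.approx(10.0)


class TestPlots:
    def test_figures_render_without_display(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from geotrack.plots import plot_climbing_curve, plot_drop_scatter, plot_speed_angle

        y = np.linspace(0, 100, 120)
        traj = traj_from_y(y)
        curve = climbing_curve([[traj]], 70.0)
        fallers = traj_from_y([50, 30.0, 30, 24.0])
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        plot_climbing_curve(curve, ax=axes[0])
        plot_speed_angle([speed_angle(traj_from_xy(np.arange(40) * 0.3, np.arange(40) * 0.4))], ax=axes[1])
        plot_drop_scatter(detect_drops(fallers), ax=axes[2])
        fig.savefig(tmp_path / "plots.png", dpi=50)
        plt.close(fig)
        assert (tmp_path / "plots.png").stat().st_size > 0
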