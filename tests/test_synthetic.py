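import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reaim import synthetic
from reaim.circular import AngleSample, circular_mean_variance, wrap_deg


class TestForcedSchedule:
    def test_design_counts(self):
        spec = synthetic.ScheduleSpec(seed=0)
        sched = synthetic.build_forced_schedule(spec)
        windows = [s[0] for s in sched]
        test_windows = sorted(set(w for w in windows
                                  if w not in (0.0, 1200.0)))
        assert len(test_windows) == 17
        assert test_windows[0] == 200.0 and test_windows[-1] == 600.0
        assert len(sched) == 35 * 17 + 14 + 15 == 624
        for w in test_windows:
            assert windows.count(w) == 35
        assert windows.count(1200.0) == 14
        assert windows.count(0.0) == 15
        assert all(s[2] == (s[0] == 0.0) for s in sched)

    def test_seeded_determinism(self):
        spec = synthetic.ScheduleSpec(seed=42)
        assert synthetic.build_forced_schedule(spec) == \
            synthetic.build_forced_schedule(spec)

    def test_nonpositive_counts_rejected(self):
        spec = synthetic.ScheduleSpec(seed=0, n_catch=0)
        with pytest.raises(ValueError):
            synthetic.build_forced_schedule(spec)


class TestTargetSequence:
    @pytest.mark.parametrize("seed", range(100))
    def test_12t_never_repeats_consecutively(self, seed):
        seq = synthetic.build_target_sequence(12, 300, seed)
        assert all(a != b for a, b in zip(seq, seq[1:]))

    @pytest.mark.parametrize("seed", range(100))
    def test_2t_max_run_of_two(self, seed):
        seq = synthetic.build_target_sequence(2, 300, seed)
        for i in range(len(seq) - 2):
            assert len(set(seq[i:i + 3])) > 1

    def test_counts_balanced(self):
        seq = synthetic.build_target_sequence(8, 200, 0)
        counts = pd.Series(seq).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_singleton_set_rejected(self):
        with pytest.raises(ValueError):
            synthetic.build_target_sequence(1, 10, 0)


class TestFreeSchedule:
    def test_pair_and_rotation_counts(self):
        pairs = synthetic.build_free_schedule(seed=0)
        assert len(pairs) == 140
        rotations = pd.Series([p[2] for p in pairs])
        assert rotations.nunique() == 13
        counts = rotations.value_counts()
        assert counts[0.0] == 20
        assert all(counts[r] == 10 for r in counts.index if r != 0.0)

    def test_execution_differs_from_learning_target(self):
        for learn, execute, _ in synthetic.build_free_schedule(seed=1):
            assert execute != learn
            assert learn in synthetic.FREE_LEARNING_TARGETS
            assert execute in synthetic.FREE_LEARNING_TARGETS


class TestForcedCohort:
    def test_angles_wrapped_and_on_time_rule(self, mr_forced_cohort):
        a = mr_forced_cohort["hand_angle_deg"]
        assert ((a > -180.0) & (a <= 180.0)).all()

    def test_on_time_flag_consistent_everywhere(self):
        cfg = synthetic.CohortConfig(n_subjects=3, seed=0)
        df = synthetic.simulate_forced_cohort(cfg)
        expected = df["rt_ms"] <= df["window_ms"] + 100.0
        assert (df["on_time"] == expected).all()

    def test_pre_preparation_reaches_are_uniform(self):
        params = synthetic.StrategyParams(t0_ms=400.0)
        cfg = synthetic.CohortConfig(n_subjects=6, strategy_params=params,
                                     seed=3)
        df = synthetic.simulate_forced_cohort(cfg)
        early = df[df["rt_ms"] < 200.0]["hand_angle_deg"]
        ks = stats.kstest(early, stats.uniform(-180, 360).cdf)
        assert ks.pvalue > 0.01

    def test_mr_asymptotic_mean_matches_generating_equation(self):
        # noise-free limit: circular mean -> gain * solution
        params = synthetic.StrategyParams(p_flip=0.0, p_lapse=0.0,
                                          kappa_motor=np.inf, gain=0.95)
        cfg = synthetic.CohortConfig(n_subjects=4, strategy_params=params,
                                     dispersion_cv=0.0, seed=5)
        df = synthetic.simulate_forced_cohort(cfg)
        asym = df[(df["window_ms"] == 1200.0)]["hand_angle_deg"]
        mean = circular_mean_variance(AngleSample(asym.to_numpy())).mean_deg
        assert mean == pytest.approx(85.5, abs=1e-9)

    def test_rc_swap_fraction_matches_binomial_oracle(self):
        # tight motor noise so "within 15 deg of -solution" counts swaps only
        params = synthetic.StrategyParams(strategy="RC", p_swap=0.1,
                                          p_lapse=0.0, t0_ms=150.0,
                                          kappa_motor=200.0)
        cfg = synthetic.CohortConfig(n_subjects=20, strategy_params=params,
                                     seed=6)
        df = synthetic.simulate_forced_cohort(cfg)
        long_rt = df[(df["rt_ms"] > 400.0) & (~df["is_catch"])]
        frac = np.mean(np.abs(long_rt["hand_angle_deg"] + 90.0) < 15.0)
        n = len(long_rt)
        band = 4 * np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < band + 0.01  # +VM tail spill allowance

    def test_byte_identical_under_same_seed(self):
        cfg = synthetic.CohortConfig(n_subjects=2, seed=11)
        a = synthetic.simulate_forced_cohort(cfg)
        b = synthetic.simulate_forced_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            synthetic.StrategyParams(strategy="XX")


@pytest.fixture(scope="module")
def cohort():
    cfg = synthetic.CohortConfig(n_subjects=5, seed=4, rt_noise_sd_ms=5.0)
    return synthetic.simulate_exp1_cohort(cfg)


class TestExp1Cohort:

    def test_early_rt_cost_scales_with_rotation(self, cohort):
        rot = cohort[cohort["block"] == "rotation"]
        early = rot[rot.groupby("subject_id").cumcount() < 72]
        m = early.groupby("rotation_deg")["rt_ms"].mean()
        # generator arithmetic: pace 2.5 * (75 - 25) = 125 ms
        assert m[75.0] - m[25.0] == pytest.approx(125.0, abs=25.0)

    def test_late_2t_cost_vanishes(self, cohort):
        rot = cohort[(cohort["block"] == "rotation")
                     & (cohort["set_size"] == 2)]
        late = rot[rot.groupby("subject_id").cumcount() >= 288]
        m = late.groupby("rotation_deg")["rt_ms"].mean()
        assert abs(m[75.0] - m[25.0]) < 15.0

    def test_cycle_lengths_by_set_size(self, cohort):
        # one cycle visits each target once: 2 trials in 2T, 12 in 12T
        for set_size in (2, 12):
            sub = cohort[(cohort["set_size"] == set_size)
                         & (cohort["block"] == "rotation")]
            one = sub[sub["subject_id"] == sub["subject_id"].iloc[0]]
            first_cycle = one.head(set_size)["target_angle_deg"]
            assert first_cycle.nunique() == set_size


class TestFreeCohort:
    def test_flip_fraction_matches_default_rate(self):
        # tight motor noise: a sign mismatch then isolates generated flips
        params = synthetic.StrategyParams(kappa_motor=200.0)
        cfg = synthetic.CohortConfig(n_subjects=40, strategy_params=params,
                                     seed=8)
        df = synthetic.simulate_free_cohort(cfg)
        ex = synthetic.free_execution_trials(df)
        rot = ex[ex["rotation_deg"] != 0.0]
        flipped = np.sign(rot["hand_angle_deg"]) != np.sign(
            rot["rotation_deg"])
        assert np.mean(flipped) == pytest.approx(0.087, abs=0.015)

    def test_null_rotation_angles_near_zero(self, mr_free_cohort):
        ex = synthetic.free_execution_trials(mr_free_cohort)
        null = ex[ex["rotation_deg"] == 0.0]["hand_angle_deg"]
        assert np.abs(null).mean() < 30.0

    def test_noiseless_rt_is_exact_line(self):
        params = synthetic.StrategyParams(kappa_motor=np.inf, p_flip=0.0,
                                          p_lapse=0.0)
        cfg = synthetic.CohortConfig(n_subjects=1, strategy_params=params,
                                     dispersion_cv=0.0, rt_noise_sd_ms=0.0,
                                     seed=9)
        ex = synthetic.free_execution_trials(
            synthetic.simulate_free_cohort(cfg))
        rot = ex[ex["rotation_deg"] != 0.0]
        slope = np.polyfit(rot["hand_angle_deg"].abs(), rot["rt_ms"], 1)[0]
        assert slope == pytest.approx(2.5, abs=1e-9)


class TestGeneralizationCohort:
    def test_local_transfer_closed_form(self):
        params = synthetic.StrategyParams(strategy="RC", kappa_motor=np.inf,
                                          sigma_transfer_deg=30.0)
        sched = synthetic.ScheduleSpec(set_size=2)
        cfg = synthetic.CohortConfig(n_subjects=2, strategy_params=params,
                                     schedule=sched, seed=10)
        df = synthetic.simulate_generalization_cohort(cfg)
        probes = df[(df["block"] == "generalization") & (~df["feedback"])]
        d = np.minimum(np.abs(wrap_deg(probes["target_angle_deg"] - 20.0)),
                       np.abs(wrap_deg(probes["target_angle_deg"] - 160.0)))
        at60 = probes[np.isclose(d, 60.0)]["hand_angle_deg"]
        assert at60.mean() == pytest.approx(45.0 * np.exp(-2.0), abs=1e-6)
        at0 = df[(df["block"] == "generalization") & df["feedback"]]
        assert at0["hand_angle_deg"].mean() == pytest.approx(45.0, abs=1e-6)

    def test_global_transfer_is_distance_independent(self):
        params = synthetic.StrategyParams(strategy="MR")
        sched = synthetic.ScheduleSpec(set_size=8)
        cfg = synthetic.CohortConfig(n_subjects=20, strategy_params=params,
                                     schedule=sched, seed=12)
        df = synthetic.simulate_generalization_cohort(cfg)
        probes = df[(df["block"] == "generalization") & (~df["feedback"])]
        training = synthetic.exp4_training_targets(8)
        d = np.min(np.abs(wrap_deg(
            probes["target_angle_deg"].to_numpy()[:, None]
            - np.array(training))), axis=1)
        slope, _, _, p, _ = stats.linregress(d, probes["hand_angle_deg"])
        assert abs(slope) < 0.03


class TestTrajectory:
    def test_sampling_interval(self):
        pos, dt = synthetic.simulate_trajectory(0.0, 250.0, 0.07)
        assert dt == pytest.approx(1.0 / 140.0)

    def test_round_trip_angle(self):
        pos, _ = synthetic.simulate_trajectory(37.0, 120.0, 0.07)
        end = pos[-1]
        assert np.rad2deg(np.arctan2(end[1], end[0])) == pytest.approx(37.0)

    def test_invalid_mt_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_trajectory(0.0, 0.0, 0.07)
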