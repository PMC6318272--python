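"""Synthetic cohorts for the visuomotor-rotation tasks.

Generates trial schedules matching each task design and simulates subjects
who solve the rotation either by parametric mental rotation (MR: the re-aim
angle ramps up with preparation time at a per-subject pace, in ms/deg) or by
discrete response caching (RC: once prepared, the full cached response is
emitted, occasionally the wrong one — a "swap"). All hand angles are
produced directly in the aligned, target-relative frame where positive
values compensate the rotation.

Tasks
-----
EXP1    blocked learning, 2x2 design crossing rotation {25, 75} deg and
        set size {2T, 12T}; RT carries the mental-rotation cost early in
        learning and, for 12T only, late as well.
FREE    140 learning/execution trial pairs with rotations -90:15:90 deg;
        execution RT is linear in the re-aim magnitude.
FORCED  forced-response task: 17 test RT windows (200-600 by 25 ms),
        an asymptotic 1200 ms window and 0 ms catch trials, under a fixed
        90 deg rotation.
EXP4    45 deg rotation trained on a 140 deg-wide region (2 or 8 targets)
        followed by no-feedback generalization probes in the remaining
        220 deg of the workspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .circular import wrap_deg

__all__ = [
    "ScheduleSpec",
    "StrategyParams",
    "CohortConfig",
    "TRIAL_COLUMNS",
    "build_forced_schedule",
    "build_target_sequence",
    "build_free_schedule",
    "simulate_forced_cohort",
    "simulate_exp1_cohort",
    "simulate_free_cohort",
    "simulate_generalization_cohort",
    "simulate_trajectory",
    "free_execution_trials",
]

TRIAL_COLUMNS = [
    "subject_id", "experiment_id", "set_size", "rotation_deg", "block",
    "trial_index", "target_angle_deg", "hand_angle_deg", "rt_ms", "mt_ms",
    "on_time", "feedback", "window_ms", "is_catch",
]

MR = "MR"
RC = "RC"

FORCED_TARGETS = tuple(float(a) for a in range(10, 360, 30))
FREE_LEARNING_TARGETS = (10.0, 100.0, 190.0, 280.0)
SAMPLING_HZ = 140.0

# FORCED realized RTs: subjects tend to move before the deadline; earliness
# relative to the window is truncated-normal (mean 40 ms, sd 40 ms, floor 0)
EARLINESS_MEAN_MS = 40.0
EARLINESS_SD_MS = 40.0
ON_TIME_SLACK_MS = 100.0


@dataclass
class ScheduleSpec:
    experiment_id: str = "FORCED"
    set_size: int = 12
    target_angles_deg: tuple = FORCED_TARGETS
    rotation_deg: float = 90.0
    block_lengths: tuple = (64, 624, 48)
    rt_windows_ms: tuple = tuple(float(w) for w in range(200, 601, 25))
    repeats_per_window: int = 35
    n_asymptotic: int = 14
    n_catch: int = 15
    asymptotic_window_ms: float = 1200.0
    seed: int = 0

    def __post_init__(self):
        angles = tuple(float(a) for a in self.target_angles_deg)
        if len(set(angles)) != len(angles):
            raise ValueError("target angles must be distinct")
        if any(not 0.0 <= a < 360.0 for a in angles):
            raise ValueError("target angles must lie in [0, 360)")
        self.target_angles_deg = angles
        windows = tuple(float(w) for w in self.rt_windows_ms)
        if any(b <= a for a, b in zip(windows, windows[1:])):
            raise ValueError("rt_windows_ms must be strictly increasing")
        self.rt_windows_ms = windows
        if any(b <= 0 for b in self.block_lengths):
            raise ValueError("block lengths must be positive")


@dataclass
class StrategyParams:
    """Population-level generative parameters for one strategy.

    pace_ms_per_deg  time cost per degree of mental rotation (MR ramp slope)
    t0_ms            preparation time before any directed responding
    p_flip           probability the re-aim sign is inverted (MR signature)
    p_swap           probability the wrong cached response is retrieved (RC)
    p_lapse          residual random-reach probability after t0
    kappa_motor      von Mises concentration of motor noise (inf = none)
    gain             under-rotation multiplier on the solution, in (0, 1]
    solution_deg     required compensation angle (the rotation magnitude)
    """

    strategy: str = MR
    pace_ms_per_deg: float = 2.5
    t0_ms: float = 150.0
    p_flip: float = 0.087
    p_swap: float = 0.05
    p_lapse: float = 0.05
    kappa_motor: float = 10.0
    gain: float = 0.95
    solution_deg: float = 90.0
    sigma_transfer_deg: float = 30.0   # RC: Gaussian generalization width
    global_transfer_gain: float = 0.9  # MR: distance-independent transfer

    def __post_init__(self):
        if self.strategy not in (MR, RC):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("p_flip", "p_swap", "p_lapse"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pace_ms_per_deg <= 0:
            raise ValueError("pace must be positive")
        if self.kappa_motor < 0:
            raise ValueError("kappa_motor must be non-negative")
        if not 0.0 < self.gain <= 1.0:
            raise ValueError("gain must lie in (0, 1]")


@dataclass
class CohortConfig:
    n_subjects: int = 32
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    strategy_params: StrategyParams = field(default_factory=StrategyParams)
    dispersion_cv: float = 0.2   # between-subject lognormal cv on pace, t0
    rt_noise_sd_ms: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.dispersion_cv < 0:
            raise ValueError("dispersion must be non-negative")


# ---------------------------------------------------------------------------
# schedules


def build_forced_schedule(spec: ScheduleSpec):
    """Pseudorandomized FORCED rotation-block schedule.

    Returns a list of (window_ms, target_angle_deg, is_catch): each test
    window repeated ``repeats_per_window`` times, plus asymptotic-window and
    0 ms catch trials, shuffled by the spec seed.
    """
    if spec.experiment_id != "FORCED":
        raise ValueError("spec is not a FORCED schedule")
    if spec.repeats_per_window <= 0 or spec.n_asymptotic <= 0 \
            or spec.n_catch <= 0:
        raise ValueError("trial counts must be positive")
    rng = np.random.default_rng(spec.seed)
    windows = ([w for w in spec.rt_windows_ms
                for _ in range(spec.repeats_per_window)]
               + [spec.asymptotic_window_ms] * spec.n_asymptotic
               + [0.0] * spec.n_catch)
    order = rng.permutation(len(windows))
    targets = rng.choice(spec.target_angles_deg, size=len(windows))
    return [(windows[i], float(targets[j]), windows[i] == 0.0)
            for j, i in enumerate(order)]


def build_target_sequence(set_size: int, n_trials: int, seed,
                          target_angles_deg=None):
    """Balanced pseudorandom target sequence.

    Each cycle of ``set_size`` trials visits every target once (counts
    balanced within +-1 overall). For set sizes >= 3 the same location never
    repeats on consecutive trials; for 2 targets the same location never
    occurs more than twice in a row.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if set_size < 2:
        raise ValueError("set_size < 2 cannot satisfy repetition constraints")
    if target_angles_deg is None:
        target_angles_deg = tuple(
            float(a) for a in np.arange(set_size) * (360.0 / set_size))
    if len(target_angles_deg) != set_size:
        raise ValueError("need one angle per target")
    rng = np.random.default_rng(seed)
    max_run = 2 if set_size == 2 else 1
    seq: list[int] = []
    while len(seq) < n_trials:
        for _ in range(10_000):
            cycle = list(rng.permutation(set_size))
            if _run_ok(seq, cycle, max_run):
                seq.extend(cycle)
                break
        else:  # pragma: no cover - constraints are always satisfiable here
            raise RuntimeError("could not satisfy sequence constraint")
    return [float(target_angles_deg[i]) for i in seq[:n_trials]]


def _run_ok(prefix, cycle, max_run):
    tail = prefix[-max_run:] if prefix else []
    seq = tail + cycle
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return False
    return True


def build_free_schedule(seed, rotations_deg=None, n_per_rotation: int = 10,
                        n_null: int = 20):
    """FREE-task trial pairs: (learning_target, execution_target, rotation).

    Thirteen rotations (-90:15:90 deg); each non-null rotation appears on
    10 pairs and the 0 deg rotation on 20 (140 pairs). The execution target
    is one of the three locations where the learning target did not appear.
    """
    if rotations_deg is None:
        rotations_deg = [float(r) for r in range(-90, 91, 15)]
    rng = np.random.default_rng(seed)
    rotations = []
    for r in rotations_deg:
        rotations.extend([r] * (n_null if r == 0.0 else n_per_rotation))
    rng.shuffle(rotations)
    pairs = []
    for rot in rotations:
        learn = float(rng.choice(FREE_LEARNING_TARGETS))
        others = [t for t in FREE_LEARNING_TARGETS if t != learn]
        execute = float(rng.choice(others))
        pairs.append((learn, execute, float(rot)))
    return pairs


# ---------------------------------------------------------------------------
# cohort simulation


def _subject_rng_children(seed, n_subjects):
    return np.random.SeedSequence(seed).spawn(n_subjects)


def _lognormal_jitter(rng, mean, cv):
    """Mean-preserving multiplicative lognormal jitter."""
    if cv == 0:
        return mean
    sigma = np.sqrt(np.log1p(cv * cv))
    return mean * np.exp(rng.normal(-sigma * sigma / 2.0, sigma))


def _motor_noise(rng, kappa, size=None):
    if np.isinf(kappa):
        return 0.0 if size is None else np.zeros(size)
    return np.rad2deg(rng.vonmises(0.0, kappa, size=size))


def _uniform_angle(rng, size=None):
    return rng.uniform(-180.0, 180.0, size=size)


def _draw_earliness(rng, size):
    a = (0.0 - EARLINESS_MEAN_MS) / EARLINESS_SD_MS
    return stats.truncnorm.rvs(a, np.inf, loc=EARLINESS_MEAN_MS,
                               scale=EARLINESS_SD_MS, size=size,
                               random_state=rng)


def simulate_forced_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a FORCED rotation block for a cohort of one strategy.

    MR subjects ramp their re-aim at their pace once preparation exceeds t0
    (capped at gain * solution); RC subjects jump straight to +-solution,
    taking the wrong sign with probability p_swap. Preparation shorter than
    t0, catch trials, and lapses yield uniform reach directions.
    """
    p = config.strategy_params
    if p.strategy not in (MR, RC):
        raise ValueError(f"unknown strategy {p.strategy!r}")
    rows = []
    for s_idx, child in enumerate(
            _subject_rng_children(config.seed, config.n_subjects)):
        rng = np.random.default_rng(child)
        pace = _lognormal_jitter(rng, p.pace_ms_per_deg, config.dispersion_cv)
        t0 = _lognormal_jitter(rng, p.t0_ms, config.dispersion_cv)
        spec = replace(config.schedule,
                       seed=int(rng.integers(2 ** 31)))
        schedule = build_forced_schedule(spec)
        earliness = _draw_earliness(rng, len(schedule))
        for t_idx, (window, target, is_catch) in enumerate(schedule):
            rt = max(window - earliness[t_idx], 0.0)
            on_time = rt <= window + ON_TIME_SLACK_MS
            angle = _strategy_angle(rng, p, pace, t0, rt, is_catch)
            rows.append({
                "subject_id": f"s{s_idx:03d}",
                "experiment_id": "FORCED",
                "set_size": config.schedule.set_size,
                "rotation_deg": p.solution_deg,
                "block": "rotation",
                "trial_index": t_idx,
                "target_angle_deg": target,
                "hand_angle_deg": angle,
                "rt_ms": rt,
                "mt_ms": max(float(rng.normal(128.0, 15.0)), 30.0),
                "on_time": bool(on_time),
                "feedback": True,
                "window_ms": window,
                "is_catch": bool(is_catch),
            })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _strategy_angle(rng, p: StrategyParams, pace, t0, rt, is_catch):
    if is_catch or rt < t0 or rng.uniform() < p.p_lapse:
        return float(_uniform_angle(rng))
    if p.strategy == MR:
        theta = min(p.gain * p.solution_deg, max(0.0, (rt - t0) / pace))
        sign = -1.0 if rng.uniform() < p.p_flip else 1.0
    else:
        theta = p.solution_deg
        sign = -1.0 if rng.uniform() < p.p_swap else 1.0
    return float(wrap_deg(sign * theta + _motor_noise(rng, p.kappa_motor)))


def simulate_exp1_cohort(config: CohortConfig,
                         rotations=(25.0, 75.0), set_sizes=(2, 12),
                         block_lengths=(36, 300, 36)) -> pd.DataFrame:
    """Blocked 2x2 learning cohort (rotation magnitude x set size).

    ``config.n_subjects`` subjects are simulated per cell. Early in learning
    every cell pays the mental-rotation cost (RT = base + pace * |rotation|);
    the cost persists for 12T but decays to zero for 2T as responses are
    cached. Hand angles converge on the solution (with residual
    under-rotation in 12T) and washout shows a small use-dependent bias in
    the 2T / 25 deg cell only.
    """
    p = config.strategy_params
    n_base, n_rot, n_wash = block_lengths
    rows = []
    cell_idx = 0
    for set_size in set_sizes:
        for rot in rotations:
            for s in range(config.n_subjects):
                child = np.random.SeedSequence(
                    config.seed).spawn(cell_idx * config.n_subjects + s + 1)[0]
                rng = np.random.default_rng(child)
                pace = _lognormal_jitter(rng, p.pace_ms_per_deg,
                                         config.dispersion_cv)
                rows.extend(_exp1_subject(
                    rng, f"{set_size}T{int(rot)}_s{s:03d}", set_size, rot,
                    pace, p, config, n_base, n_rot, n_wash))
            cell_idx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _exp1_subject(rng, sid, set_size, rot, pace, p, config,
                  n_base, n_rot, n_wash):
    base_rt = 500.0
    tau_learn = 10.0
    targets = build_target_sequence(set_size, n_base + n_rot + n_wash,
                                    int(rng.integers(2 ** 31)))
    aftereffect = 3.0 if (set_size == 2 and rot == 25.0) else 1.0
    angle_gain = p.gain if set_size == 12 else 1.0
    rows = []
    t_idx = 0
    for block, n_trials in (("baseline", n_base), ("rotation", n_rot),
                            ("washout", n_wash)):
        for k in range(n_trials):
            noise = _motor_noise(rng, p.kappa_motor)
            rt_noise = rng.normal(0.0, config.rt_noise_sd_ms)
            if block == "baseline":
                angle, rt = noise, base_rt + rt_noise
            elif block == "rotation":
                angle = (angle_gain * rot * (1.0 - np.exp(-(k + 1) / tau_learn))
                         + noise)
                rt = base_rt + _mr_cost_weight(set_size, k) * pace * rot \
                    + rt_noise
            else:
                angle, rt = aftereffect + noise, base_rt + rt_noise
            rows.append({
                "subject_id": sid, "experiment_id": "EXP1",
                "set_size": set_size, "rotation_deg": rot, "block": block,
                "trial_index": t_idx, "target_angle_deg": targets[t_idx],
                "hand_angle_deg": float(wrap_deg(angle)),
                "rt_ms": max(float(rt), 0.0),
                "mt_ms": max(float(rng.normal(200.0, 20.0)), 50.0),
                "on_time": True, "feedback": block != "washout",
                "window_ms": float("nan"), "is_catch": False,
            })
            t_idx += 1
    return rows


def _mr_cost_weight(set_size, rotation_trial_index):
    """Weight of the pace * |rotation| RT term across the rotation block.

    12T keeps the full cost throughout; 2T keeps it over the first 72 trials
    then ramps it off by trial 150 (responses become cached).
    """
    if set_size >= 12:
        return 1.0
    k = rotation_trial_index
    if k < 72:
        return 1.0
    if k >= 150:
        return 0.0
    return 1.0 - (k - 72) / (150.0 - 72.0)


def simulate_free_cohort(config: CohortConfig) -> pd.DataFrame:
    """FREE-task cohort of 140 trial pairs per subject.

    Trials alternate learning (even trial_index) and execution (odd
    trial_index) within pairs; both rows of a pair share rotation_deg.
    Execution re-aims are gain * rotation with sign flips at p_flip; their
    RT is t0 + pace * |realized angle| + Gaussian noise.
    """
    p = config.strategy_params
    rows = []
    for s_idx, child in enumerate(
            _subject_rng_children(config.seed, config.n_subjects)):
        rng = np.random.default_rng(child)
        pace = _lognormal_jitter(rng, p.pace_ms_per_deg, config.dispersion_cv)
        t0 = _lognormal_jitter(rng, p.t0_ms, config.dispersion_cv)
        pairs = build_free_schedule(int(rng.integers(2 ** 31)))
        for pair_idx, (learn_t, exec_t, rot) in enumerate(pairs):
            learn_angle = _motor_noise(rng, p.kappa_motor)
            rows.append(_free_row(rng, s_idx, 2 * pair_idx, learn_t, rot,
                                  learn_angle,
                                  400.0 + rng.normal(0, config.rt_noise_sd_ms)))
            if rot == 0.0:
                exec_angle = _motor_noise(rng, p.kappa_motor)
            else:
                sign = -1.0 if rng.uniform() < p.p_flip else 1.0
                exec_angle = wrap_deg(sign * p.gain * rot
                                      + _motor_noise(rng, p.kappa_motor))
            rt = t0 + pace * abs(exec_angle) \
                + rng.normal(0.0, config.rt_noise_sd_ms)
            rows.append(_free_row(rng, s_idx, 2 * pair_idx + 1, exec_t,
                                  rot, exec_angle, rt))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _free_row(rng, s_idx, t_idx, target, rot, angle, rt):
    return {
        "subject_id": f"s{s_idx:03d}", "experiment_id": "FREE",
        "set_size": len(FREE_LEARNING_TARGETS), "rotation_deg": rot,
        "block": "rotation", "trial_index": t_idx,
        "target_angle_deg": target,
        "hand_angle_deg": float(wrap_deg(angle)),
        "rt_ms": max(float(rt), 0.0),
        "mt_ms": max(float(rng.normal(208.0, 20.0)), 50.0),
        "on_time": True, "feedback": True,
        "window_ms": float("nan"), "is_catch": False,
    }


def free_execution_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Execution trials of a FREE cohort (odd trial_index within pairs)."""
    return trials[(trials["experiment_id"] == "FREE")
                  & (trials["trial_index"] % 2 == 1)].copy()


def exp4_training_targets(set_size: int):
    """Training targets spanning the 140-deg region [20, 160]."""
    if set_size == 2:
        return (20.0, 160.0)
    if set_size == 8:
        return tuple(float(a) for a in np.linspace(20.0, 160.0, 8))
    raise ValueError("generalization design uses 2 or 8 training targets")


def exp4_probe_targets():
    """Ten equally spaced novel locations in the 220-deg untrained region."""
    return tuple(float(wrap_deg(a) % 360.0)
                 for a in 160.0 + 20.0 * np.arange(1, 11))


def simulate_generalization_cohort(config: CohortConfig,
                                   rotation_deg: float = 45.0,
                                   n_training: int = 144,
                                   n_generalization: int = 140
                                   ) -> pd.DataFrame:
    """One generalization-task group (2T or 8T) of one transfer type.

    RC subjects transfer locally: probe re-aim falls off as a Gaussian of
    the circular distance to the nearest training target (width
    sigma_transfer_deg). MR subjects transfer globally at a
    distance-independent gain. Training trials asymptote near the solution;
    feedback appears on half the training trials and never on probes.
    """
    p = config.strategy_params
    set_size = config.schedule.set_size
    training = exp4_training_targets(set_size)
    probes = exp4_probe_targets()
    half_gen = n_generalization // 2
    rows = []
    for s_idx, child in enumerate(
            _subject_rng_children(config.seed, config.n_subjects)):
        rng = np.random.default_rng(child)
        t_idx = 0
        train_seq = build_target_sequence(
            set_size, n_training, int(rng.integers(2 ** 31)),
            target_angles_deg=training)
        for k, target in enumerate(train_seq):
            angle = rotation_deg * (1.0 - np.exp(-(k + 1) / 8.0)) \
                + _motor_noise(rng, p.kappa_motor)
            rows.append(_exp4_row(s_idx, set_size, rotation_deg, "rotation",
                                  t_idx, target, angle,
                                  rng, config, feedback=bool(k % 2 == 0)))
            t_idx += 1
        gen_targets = ([float(rng.choice(training)) for _ in range(half_gen)]
                       + [probes[i % len(probes)] for i in range(
                           n_generalization - half_gen)])
        rng.shuffle(gen_targets)
        for target in gen_targets:
            is_probe = target not in training
            if not is_probe:
                angle = rotation_deg + _motor_noise(rng, p.kappa_motor)
            elif p.strategy == RC:
                d = np.min(np.abs(wrap_deg(np.array(training) - target)))
                angle = rotation_deg * np.exp(
                    -d * d / (2.0 * p.sigma_transfer_deg ** 2)) \
                    + _motor_noise(rng, p.kappa_motor)
            else:
                angle = rotation_deg * p.global_transfer_gain \
                    + _motor_noise(rng, p.kappa_motor)
            rows.append(_exp4_row(s_idx, set_size, rotation_deg,
                                  "generalization", t_idx, target, angle,
                                  rng, config, feedback=not is_probe))
            t_idx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _exp4_row(s_idx, set_size, rot, block, t_idx, target, angle, rng,
              config, feedback):
    return {
        "subject_id": f"s{s_idx:03d}", "experiment_id": "EXP4",
        "set_size": set_size, "rotation_deg": rot, "block": block,
        "trial_index": t_idx, "target_angle_deg": float(target),
        "hand_angle_deg": float(wrap_deg(angle)),
        "rt_ms": max(float(450.0 + rng.normal(0, config.rt_noise_sd_ms)), 0.0),
        "mt_ms": max(float(rng.normal(200.0, 20.0)), 50.0),
        "on_time": True, "feedback": bool(feedback),
        "window_ms": float("nan"), "is_catch": False,
    }


def simulate_trajectory(angle_deg: float, mt_ms: float,
                        ring_radius_m: float = 0.07):
    """Straight constant-speed reach sampled at 140 Hz.

    Returns (positions, dt_s): positions is an (n, 2) array in meters from
    the start to the target-ring crossing; consecutive samples are 1/140 s
    apart and the average speed equals ring_radius_m / mt.
    """
    if mt_ms <= 0:
        raise ValueError("movement time must be positive")
    dt = 1.0 / SAMPLING_HZ
    n_steps = max(1, int(round(mt_ms / 1000.0 / dt)))
    speed = ring_radius_m / (mt_ms / 1000.0)
    t = np.arange(n_steps + 1) * dt
    direction = np.array([np.cos(np.deg2rad(angle_deg)),
                          np.sin(np.deg2rad(angle_deg))])
    return speed * t[:, None] * direction[None, :], dt
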