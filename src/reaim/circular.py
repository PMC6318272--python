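"""Circular statistics and shared kinematic preprocessing.

All public angle interfaces are in degrees, target-relative, wrapped into
(-180, 180] with positive values pointing in the direction that compensates
the imposed rotation. Reaction-time (RT) binning, outlier exclusion, the
sign-error taxonomy, and reach-speed computation live here because every
downstream analysis consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AngleSample",
    "CircularSummary",
    "BinSpec",
    "wrap_deg",
    "wrap_and_align",
    "circular_mean_variance",
    "circular_mode",
    "exclude_outliers",
    "classify_sign_errors",
    "assign_rt_bins",
    "cycle_median_rts",
    "average_speed",
]

_R_TOL = 1e-9  # resultant length below which the circular mean is undefined


def wrap_deg(angle_deg):
    """Wrap angles (degrees) into the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass
class AngleSample:
    """A sample of target-relative reach angles in (-180, 180] degrees."""

    angles_deg: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        self.angles_deg = wrap_deg(a)

    def __len__(self) -> int:
        return self.angles_deg.size


@dataclass
class CircularSummary:
    mean_deg: float
    resultant_length: float
    variance: float
    n: int
    defined: bool


@dataclass
class BinSpec:
    """RT bins: half-open 25 ms bins [0, 400) plus an overflow bin.

    Bin k covers [25(k-1), 25k) ms for k = 1..16; bin 17 is [400, inf).
    """

    width_ms: float = 25.0
    n_closed: int = 16

    @property
    def n_bins(self) -> int:
        return self.n_closed + 1

    @property
    def edges_ms(self) -> np.ndarray:
        return np.arange(self.n_closed + 1) * self.width_ms

    def lower_edge(self, bin_index: int) -> float:
        """Lower edge in ms of a 1-based bin index."""
        if not 1 <= bin_index <= self.n_bins:
            raise ValueError(f"bin index {bin_index} outside 1..{self.n_bins}")
        return (bin_index - 1) * self.width_ms


def wrap_and_align(raw_hand_angle_deg, target_angle_deg, rotation_sign):
    """Express a workspace hand angle relative to its target, mirrored to a
    common sign convention.

    ``rotation_sign`` is +1 or -1 according to the counterbalanced direction
    of the imposed rotation for that subject; after mirroring, positive
    aligned angles always point toward the compensating solution.
    """
    sign = np.sign(rotation_sign)
    if np.any(sign == 0):
        raise ValueError("rotation_sign must be nonzero")
    return wrap_deg(sign * wrap_deg(np.asarray(raw_hand_angle_deg, float)
                                    - np.asarray(target_angle_deg, float)))


def circular_mean_variance(sample: AngleSample) -> CircularSummary:
    """Circular mean and variance (1 - mean resultant length).

    The mean is flagged undefined when the resultant length is numerically
    zero (e.g., an antipodal pair), in which case ``mean_deg`` is NaN.
    """
    a = np.deg2rad(np.asarray(sample.angles_deg
                              if isinstance(sample, AngleSample) else sample,
                              dtype=float))
    if a.size == 0:
        raise ValueError("empty angle sample")
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    rbar = float(np.hypot(c, s))
    defined = rbar >= _R_TOL
    mean = float(wrap_deg(np.rad2deg(np.arctan2(s, c)))) if defined else float("nan")
    return CircularSummary(mean_deg=mean, resultant_length=rbar,
                           variance=1.0 - rbar, n=a.size, defined=defined)


def circular_mode(sample, bin_width_deg: float = 10.0) -> float:
    """Modal reach direction from a circular histogram.

    Bins tile (-180, 180]; ties among maximal bins are broken toward the bin
    center closest (circularly) to the circular mean, then toward the lowest
    bin index — a deterministic rule.
    """
    angles = np.asarray(sample.angles_deg if isinstance(sample, AngleSample)
                        else sample, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if not np.isclose(360.0 / bin_width_deg, round(360.0 / bin_width_deg)):
        raise ValueError("bin width must divide 360")
    n_bins = int(round(360.0 / bin_width_deg))
    edges = -180.0 + bin_width_deg * np.arange(n_bins + 1)
    # wrapped angles lie in (-180, 180]; clipping makes 180 land in the top bin
    idx = np.clip(np.searchsorted(edges, angles, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = wrap_deg(edges[:-1] + bin_width_deg / 2.0)
    maximal = np.flatnonzero(counts == counts.max())
    if maximal.size == 1:
        return float(centers[maximal[0]])
    summary = circular_mean_variance(AngleSample(angles))
    anchor = summary.mean_deg if summary.defined else 0.0
    dist = np.abs(wrap_deg(centers[maximal] - anchor))
    return float(centers[maximal[np.argmin(dist)]])


def exclude_outliers(trials: pd.DataFrame, by: str = "rt",
                     threshold_sd: float = 3.0):
    """Per-subject 3-SD exclusion of RTs or movement angles.

    A single pass: each subject's mean/SD are computed over all of that
    subject's candidate trials (the candidate itself included), and a trial
    is dropped iff |value - mean| > threshold_sd * SD. Subjects with a single
    trial, or zero within-subject SD, lose nothing. Returns the retained
    table and the number excluded. Angle-based exclusion must be skipped for
    sign-error analyses (call with by='rt' only there).
    """
    col = {"rt": "rt_ms", "angle": "hand_angle_deg"}.get(by)
    if col is None:
        raise ValueError(f"unknown exclusion criterion {by!r}")
    g = trials.groupby("subject_id")[col]
    mean = g.transform("mean")
    sd = g.transform("std")  # ddof=1; NaN for n=1
    z_ok = (trials[col] - mean).abs() <= threshold_sd * sd
    keep = z_ok | sd.isna() | (sd == 0.0)
    excluded = int((~keep).sum())
    return trials.loc[keep].copy(), excluded


def classify_sign_errors(trials: pd.DataFrame, rotation_deg: float,
                         threshold_deg: float = -15.0):
    """Label sign errors and compute the predicted swap/flip anchors.

    A sign error is a reach at or beyond ``threshold_deg`` (default -15 deg)
    on the wrong side of the target. Under response caching, the predicted
    error is retrieval of the cached response for the opposite target
    (180 deg away): aligned direction rotation - 180, wrapped. Under mental
    rotation it is a sign flip of the re-aim: -rotation.
    """
    labelled = trials.copy()
    labelled["sign_error"] = labelled["hand_angle_deg"] <= threshold_deg
    anchors = swap_flip_anchors(rotation_deg)
    return labelled, anchors


def swap_flip_anchors(rotation_deg: float) -> dict:
    """Predicted aligned reach directions for swap and flip errors."""
    return {
        "swap_deg": float(wrap_deg(rotation_deg - 180.0)),
        "flip_deg": float(wrap_deg(-rotation_deg)),
    }


def assign_rt_bins(rt_ms, spec: BinSpec | None = None) -> np.ndarray:
    """1-based RT bin index per trial; the last bin absorbs all RTs >= 400 ms."""
    spec = spec or BinSpec()
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt < 0):
        raise ValueError("negative RT")
    return np.minimum(rt // spec.width_ms, spec.n_closed).astype(int) + 1


def cycle_median_rts(trials: pd.DataFrame, cycle_length: int,
                     n_summary_cycles: int = 6) -> pd.DataFrame:
    """Per-subject per-cycle median RT with early/late summary means.

    Cycles are consecutive non-overlapping groups of ``cycle_length`` trials
    in presentation order (2 trials in 2T, 12 in 12T, so each cycle holds one
    exposure per target). Early = mean of the first six cycle medians; late =
    mean of the last six.
    """
    if cycle_length < 1:
        raise ValueError("cycle_length must be positive")
    out = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial_index")
        cyc = np.arange(len(sub)) // cycle_length
        med = sub.groupby(cyc)["rt_ms"].median()
        if len(med) < n_summary_cycles:
            raise ValueError(
                f"subject {sid}: {len(med)} cycles < {n_summary_cycles}")
        out.append({
            "subject_id": sid,
            "early_rt_ms": float(med.iloc[:n_summary_cycles].mean()),
            "late_rt_ms": float(med.iloc[-n_summary_cycles:].mean()),
            "cycle_medians": med.to_numpy(),
        })
    return pd.DataFrame(out)


def average_speed(positions: np.ndarray, dt_s: float,
                  start_exit_index: int, ring_cross_index: int) -> float:
    """Mean hand speed between leaving the start circle and crossing the
    target ring, as the average magnitude of the position derivative."""
    pos = np.asarray(positions, dtype=float)
    if not 0 <= start_exit_index < ring_cross_index < len(pos):
        raise ValueError("invalid sample window")
    window = pos[start_exit_index:ring_cross_index + 1]
    if len(window) < 2:
        raise ValueError("speed window needs at least two samples")
    step = np.linalg.norm(np.diff(window, axis=0), axis=1) / dt_s
    return float(step.mean())
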