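"""Mental-rotation pace estimation and the critical-RT-bin boundary.

The "pace" is the time cost per degree of re-aiming (ms/deg). In the FREE
task it is the slope of execution-trial RT regressed on the absolute
realized movement angle. In the FORCED task the regression runs the other
way — aligned reach angle on RT over the full (unbinned) distribution after
the critical bin — so the pace is the reciprocal of that slope. The
critical bin is the first RT bin at which reaches become non-random,
detected as the first significant drop in per-subject circular variance
between adjacent bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import stats as st
from .circular import AngleSample, BinSpec, assign_rt_bins, \
    circular_mean_variance

__all__ = [
    "PaceEstimate",
    "CriticalBinResult",
    "detect_critical_bin",
    "estimate_pace_free",
    "estimate_pace_forced",
    "fit_sigmoid_pace",
    "compare_paces",
]

_SLOPE_FLOOR_DEG_PER_MS = 1e-3   # below this the FORCED ramp is flat
_SLOPE_ALPHA = 0.05              # and the ramp must be reliably positive
_MIN_TRIALS = 10


@dataclass
class PaceEstimate:
    subject_id: str
    task: str
    pace_ms_per_deg: float
    slope_raw: float
    intercept: float
    r: float
    p: float
    method: str = "linear"
    defined: bool = True
    extra: dict | None = None

    def to_record(self) -> dict:
        return {"subject_id": self.subject_id, "task": self.task,
                "method": self.method,
                "pace_ms_per_deg": self.pace_ms_per_deg,
                "slope_raw": self.slope_raw, "intercept": self.intercept,
                "r": self.r, "p": self.p, "defined": self.defined}


@dataclass
class CriticalBinResult:
    first_nonrandom_bin: int
    defined: bool
    tests: pd.DataFrame


def detect_critical_bin(trials: pd.DataFrame,
                        binspec: BinSpec | None = None,
                        alpha: float = 0.05) -> CriticalBinResult:
    """First RT bin at which reaches are reliably non-random.

    Computes each subject's circular variance per RT bin, then scans
    adjacent bin pairs in order for the first significant one-tailed paired
    decrease (alpha = 0.05, no multiplicity correction). The later bin of
    that pair is returned as the boundary; the analysis set is that bin
    onward. ``defined`` is False when no pair shows a decrease.
    """
    binspec = binspec or BinSpec()
    df = trials.copy()
    if "rt_bin" not in df.columns:
        df["rt_bin"] = assign_rt_bins(df["rt_ms"], binspec)
    if df["subject_id"].nunique() < 2:
        raise ValueError("critical-bin detection needs at least two subjects")
    var = (df.groupby(["subject_id", "rt_bin"])["hand_angle_deg"]
             .apply(lambda a: circular_mean_variance(AngleSample(
                 a.to_numpy())).variance)
             .unstack("rt_bin"))
    tests = []
    boundary, defined = -1, False
    for b in range(1, binspec.n_bins):
        if b not in var.columns or (b + 1) not in var.columns:
            continue
        pair = var[[b, b + 1]].dropna()
        if len(pair) < 2:
            continue
        res = st.paired_t(pair[b], pair[b + 1])
        # one-tailed: variance must DECREASE from bin b to b+1
        p_one = res.p_two_sided / 2.0 if res.t > 0 else 1.0 - \
            res.p_two_sided / 2.0
        significant = p_one < alpha
        tests.append({"bin_pair": (b, b + 1), "t": res.t, "df": res.df,
                      "p_one_tailed": p_one, "significant": significant,
                      "n_subjects": len(pair)})
        if significant and not defined:
            boundary, defined = b + 1, True
    return CriticalBinResult(first_nonrandom_bin=boundary, defined=defined,
                             tests=pd.DataFrame(tests))


def estimate_pace_free(execution_trials: pd.DataFrame,
                       predictor: str = "movement_angle") -> list:
    """Per-subject FREE-task pace estimates.

    Uses rotated execution trials only. The pace is the OLS slope of RT (ms)
    on the absolute realized movement angle (deg); the absolute angle is
    used because sign flips preserve re-aim magnitude. Also reports the
    accuracy slope (|movement angle| on |rotation|) and, with
    ``predictor='rotation'``, the cross-check regression on the imposed
    rotation magnitude instead of the realized angle.
    """
    if predictor not in ("movement_angle", "rotation"):
        raise ValueError("predictor must be 'movement_angle' or 'rotation'")
    out = []
    rotated = execution_trials[execution_trials["rotation_deg"] != 0.0]
    for sid, sub in rotated.groupby("subject_id", sort=True):
        x_angle = sub["hand_angle_deg"].abs().to_numpy()
        x = x_angle if predictor == "movement_angle" \
            else sub["rotation_deg"].abs().to_numpy()
        y = sub["rt_ms"].to_numpy()
        if len(sub) < _MIN_TRIALS or np.ptp(x) == 0:
            out.append(PaceEstimate(sid, "FREE", float("nan"), float("nan"),
                                    float("nan"), float("nan"), float("nan"),
                                    defined=False))
            continue
        reg = st.linear_regression(y, x, names=["abs_angle"])
        acc = st.linear_regression(x_angle, sub["rotation_deg"].abs(),
                                   names=["abs_rotation"])
        corr = st.correlations(x, y)
        slope = float(reg.params[1])
        out.append(PaceEstimate(
            sid, "FREE", pace_ms_per_deg=slope, slope_raw=slope,
            intercept=float(reg.params[0]), r=corr["pearson_r"],
            p=float(reg.pvalues[1]),
            defined=slope > 0,
            extra={"accuracy_slope": float(acc.params[1]),
                   "predictor": predictor}))
    return out


def estimate_pace_forced(trials: pd.DataFrame, critical_bin: int,
                         binspec: BinSpec | None = None,
                         rt_max_ms: float | None = 400.0) -> list:
    """Per-subject FORCED-task pace estimates.

    On-time trials with RT from the critical bin's lower edge up to
    ``rt_max_ms`` enter an unbinned OLS of aligned angle (deg) on RT (ms);
    the pace is 1/slope, flagged undefined when the slope is at or below a
    small positive floor or not reliably positive (no ramp — the
    response-caching signature, where angles sit at the solution
    throughout).

    The default upper cut is the top of the closed RT-binning range: the
    overflow bin pools everything above 400 ms because the preparation ramp
    is complete there, and a line fitted across that plateau (or across
    asymptotic-window trials) measures a secant of the ramp rather than its
    slope. Pass ``rt_max_ms=None`` to regress over the full post-critical
    distribution instead.
    """
    binspec = binspec or BinSpec()
    edge = binspec.lower_edge(critical_bin)
    usable = trials[(trials["on_time"]) & (~trials["is_catch"])
                    & (trials["rt_ms"] >= edge)]
    if rt_max_ms is not None:
        usable = usable[usable["rt_ms"] <= rt_max_ms]
    out = []
    for sid, sub in usable.groupby("subject_id", sort=True):
        y = sub["hand_angle_deg"].to_numpy()
        x = sub["rt_ms"].to_numpy()
        if len(sub) < _MIN_TRIALS or np.ptp(x) == 0:
            out.append(PaceEstimate(sid, "FORCED", float("nan"), float("nan"),
                                    float("nan"), float("nan"), float("nan"),
                                    defined=False))
            continue
        reg = st.linear_regression(y, x, names=["rt_ms"])
        corr = st.correlations(x, y)
        slope = float(reg.params[1])  # deg/ms
        defined = slope > _SLOPE_FLOOR_DEG_PER_MS \
            and float(reg.pvalues[1]) < _SLOPE_ALPHA
        out.append(PaceEstimate(
            sid, "FORCED",
            pace_ms_per_deg=1.0 / slope if defined else float("nan"),
            slope_raw=slope, intercept=float(reg.params[0]),
            r=corr["pearson_r"], p=float(reg.pvalues[1]), defined=defined))
    return out


def _logistic(t, L, t50, tau):
    return L / (1.0 + np.exp(-(t - t50) / tau))


def fit_sigmoid_pace(trials: pd.DataFrame, critical_bin: int = 1,
                     binspec: BinSpec | None = None,
                     n_starts: int = 10, seed: int = 0) -> list:
    """Alternative FORCED pace readout from a logistic fit.

    Fits angle(t) = L / (1 + exp(-(t - t50)/tau)) per subject by bounded
    least squares from multiple seeded starts; the pace is the reciprocal of
    the maximal slope, 4 tau / L (ms/deg). Degenerate data (no angle spread)
    are flagged.
    """
    binspec = binspec or BinSpec()
    edge = binspec.lower_edge(critical_bin)
    usable = trials[(trials["on_time"]) & (~trials["is_catch"])
                    & (trials["rt_ms"] >= edge)]
    rng = np.random.default_rng(seed)
    out = []
    for sid, sub in usable.groupby("subject_id", sort=True):
        t = sub["rt_ms"].to_numpy()
        y = sub["hand_angle_deg"].to_numpy()
        if len(sub) < _MIN_TRIALS or np.ptp(y) < 1.0:
            out.append(PaceEstimate(sid, "FORCED", float("nan"), float("nan"),
                                    float("nan"), float("nan"), float("nan"),
                                    method="sigmoid", defined=False))
            continue
        best = None
        bounds = ([1.0, 0.0, 1.0], [120.0, float(t.max()) + 500.0, 500.0])
        for _ in range(n_starts):
            x0 = [rng.uniform(30.0, 120.0),
                  rng.uniform(t.min(), t.max()),
                  rng.uniform(10.0, 200.0)]
            try:
                res = optimize.least_squares(
                    lambda th: _logistic(t, *th) - y, x0, bounds=bounds)
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            out.append(PaceEstimate(sid, "FORCED", float("nan"), float("nan"),
                                    float("nan"), float("nan"), float("nan"),
                                    method="sigmoid", defined=False))
            continue
        L, t50, tau = best.x
        pace = 4.0 * tau / L
        out.append(PaceEstimate(
            sid, "FORCED", pace_ms_per_deg=float(pace),
            slope_raw=float(L / (4.0 * tau)), intercept=float(t50),
            r=float("nan"), p=float("nan"), method="sigmoid",
            extra={"L": float(L), "t50": float(t50), "tau": float(tau)}))
    return out


def compare_paces(free: list, forced: list, prior_scale_r: float = 1.0
                  ) -> dict:
    """Paired comparison of per-subject paces across tasks.

    Pairs estimates by subject_id (both defined), then reports the paired t
    on the differences, the JZS Bayes factor in favor of the null on that t,
    and Pearson/Spearman correlations.
    """
    f = {e.subject_id: e for e in free if e.defined}
    g = {e.subject_id: e for e in forced if e.defined}
    shared = sorted(set(f) & set(g))
    if len(shared) < 3:
        raise ValueError("need at least three subjects with defined paces "
                         "in both tasks")
    a = np.array([f[s].pace_ms_per_deg for s in shared])
    b = np.array([g[s].pace_ms_per_deg for s in shared])
    ttest = st.paired_t(a, b)
    bf = st.jzs_bf01(ttest.t, len(shared), prior_scale_r)
    corr = st.correlations(a, b)
    return {"n": len(shared), "t": ttest.t, "df": ttest.df,
            "p": ttest.p_two_sided, "mean_diff": ttest.mean_diff,
            "bf01": bf.bf01, **corr,
            "free_mean": float(a.mean()), "forced_mean": float(b.mean())}
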