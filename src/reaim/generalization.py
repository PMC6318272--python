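"""Generalization of learned re-aiming to untrained target directions.

Subjects first learn to counter a 45-deg rotation on a restricted set of
training targets; no-feedback probe trials then test how far the learned
compensation transfers. The analysis has three stages: (1) a learning
criterion retaining only subjects whose asymptotic training angles differ
reliably from zero; (2) a per-subject trial-by-trial regression of probe
movement angles on four z-scored regressors — trial number, circular
distance to the nearest training target, RT, and the RT x distance
interaction — with group-level tests on the betas; (3) an optional Gaussian
generalization fit, whose instability on flat (global) transfer profiles is
flagged rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import stats as st
from .circular import wrap_deg

__all__ = [
    "GenRegressionResult",
    "GaussianGenFit",
    "learning_criterion_filter",
    "nearest_training_distance",
    "fit_generalization_regression",
    "group_contrast",
    "fit_gaussian_generalization",
]

REGRESSORS = ["trial_number", "distance", "rt", "rt_x_distance"]


@dataclass
class GenRegressionResult:
    subject_id: str
    betas: dict
    ses: dict
    tvalues: dict
    pvalues: dict
    n_trials: int


@dataclass
class GaussianGenFit:
    height: float
    width: float
    offset: float
    sse: float
    stable: bool


def learning_criterion_filter(training_trials: pd.DataFrame,
                              cycle_length: int,
                              n_cycles: int = 4,
                              alpha: float = 0.05):
    """Retain subjects with reliable asymptotic learning.

    For each subject, a one-sample t against 0 deg on movement angles over
    the last ``n_cycles`` training cycles (one cycle = one pass through the
    group's targets); retained iff p < alpha. Returns (retained_ids, stats
    table).
    """
    rows, retained = [], []
    for sid, sub in training_trials.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial_index")
        n_tail = cycle_length * n_cycles
        if len(sub) < n_tail:
            raise ValueError(
                f"subject {sid}: fewer than {n_cycles} training cycles")
        angles = sub["hand_angle_deg"].to_numpy()[-n_tail:]
        if np.ptp(angles) == 0:
            # noise-free performance: infinite t when off zero
            t = float("inf") if angles[0] != 0 else 0.0
            p = 0.0 if angles[0] != 0 else 1.0
            res = st.TTestResult(t=t, df=len(angles) - 1, p_two_sided=p,
                                 mean_diff=float(angles[0]),
                                 kind="one_sample")
        else:
            res = st.one_sample_t(angles, 0.0)
        keep = res.p_two_sided < alpha
        if keep:
            retained.append(sid)
        rows.append({"subject_id": sid, "t": res.t, "df": res.df,
                     "p": res.p_two_sided, "mean_angle": res.mean_diff,
                     "retained": keep})
    return retained, pd.DataFrame(rows)


def nearest_training_distance(probe_angle_deg, training_angles_deg):
    """Minimal absolute circular distance (deg) to any training target."""
    training = np.asarray(training_angles_deg, dtype=float)
    if training.size == 0:
        raise ValueError("empty training target set")
    probe = np.asarray(probe_angle_deg, dtype=float)
    d = np.abs(wrap_deg(probe[..., None] - training))
    out = d.min(axis=-1)
    return float(out) if out.ndim == 0 else out


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def fit_generalization_regression(probe_trials: pd.DataFrame,
                                  training_angles_deg) -> list:
    """Per-subject OLS of probe movement angles on four z-scored regressors.

    Regressors (z-scored within subject): trial number, circular distance of
    the probe target to the nearest training target, RT, and the
    interaction — the product of z-scored RT and z-scored distance, itself
    re-z-scored. Constant regressors are flagged (beta = NaN).
    """
    results = []
    for sid, sub in probe_trials.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial_index")
        dist = nearest_training_distance(
            sub["target_angle_deg"].to_numpy(), training_angles_deg)
        raw = {
            "trial_number": sub["trial_index"].to_numpy(dtype=float),
            "distance": dist,
            "rt": sub["rt_ms"].to_numpy(dtype=float),
        }
        cols, names, degenerate = [], [], []
        z = {k: _zscore(v) for k, v in raw.items()}
        inter = None
        if z["rt"] is not None and z["distance"] is not None:
            inter = _zscore(z["rt"] * z["distance"])
        z["rt_x_distance"] = inter
        for name in REGRESSORS:
            if z[name] is None:
                degenerate.append(name)
            else:
                cols.append(z[name])
                names.append(name)
        y = sub["hand_angle_deg"].to_numpy(dtype=float)
        nan = float("nan")
        betas = {k: nan for k in REGRESSORS}
        ses = dict(betas)
        ts = dict(betas)
        ps = dict(betas)
        if names and len(y) > len(names) + 1 and np.ptp(y) > 0:
            reg = st.linear_regression(y, np.column_stack(cols), names=names)
            for i, name in enumerate(names, start=1):
                betas[name] = float(reg.params[i])
                ses[name] = float(reg.bse[i])
                ts[name] = float(reg.tvalues[i])
                ps[name] = float(reg.pvalues[i])
        elif np.ptp(y) == 0:
            betas = {k: 0.0 for k in REGRESSORS}
        results.append(GenRegressionResult(
            subject_id=sid, betas=betas, ses=ses, tvalues=ts, pvalues=ps,
            n_trials=len(sub)))
    return results


def group_contrast(results_a: list, results_b: list,
                   regressor: str = "distance") -> dict:
    """Group-level inference on a regression beta.

    One-sample t against 0 within each group plus a two-sample t between
    groups on the chosen beta (default: the distance effect, the locality
    signature).
    """
    if regressor not in REGRESSORS:
        raise ValueError(f"unknown regressor {regressor!r}")
    a = np.array([r.betas[regressor] for r in results_a])
    b = np.array([r.betas[regressor] for r in results_b])
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    ta, tb = st.one_sample_t(a, 0.0), st.one_sample_t(b, 0.0)
    between = st.two_sample_t(a, b)
    return {
        "regressor": regressor,
        "group_a": {"n": a.size, "mean_beta": float(a.mean()), "t": ta.t,
                    "df": ta.df, "p": ta.p_two_sided},
        "group_b": {"n": b.size, "mean_beta": float(b.mean()), "t": tb.t,
                    "df": tb.df, "p": tb.p_two_sided},
        "between": {"t": between.t, "df": between.df,
                    "p": between.p_two_sided},
    }


def fit_gaussian_generalization(distances_deg, mean_angles_deg,
                                max_width_deg: float = 360.0
                                ) -> GaussianGenFit:
    """Least-squares Gaussian generalization curve.

    Fits angle(d) = offset + height * exp(-d^2 / (2 width^2)) over per-
    target mean re-aim changes. Flat profiles make height/width/offset
    interchangeable; the fit is flagged unstable when the parameter
    covariance is near-singular or a bound is hit.
    """
    d = np.asarray(distances_deg, dtype=float)
    y = np.asarray(mean_angles_deg, dtype=float)
    if np.unique(d).size < 4:
        raise ValueError("need at least four distinct probe distances")

    def model(dd, height, width, offset):
        return offset + height * np.exp(-dd * dd / (2.0 * width * width))

    lo = [-90.0, 1.0, -90.0]
    hi = [90.0, max_width_deg, 90.0]
    p0 = [max(min(float(y[np.argmin(d)] - y[np.argmax(d)]), 89.0), -89.0),
          30.0, float(y[np.argmax(d)])]
    stable = True
    try:
        popt, pcov = optimize.curve_fit(model, d, y, p0=p0,
                                        bounds=(lo, hi), maxfev=20_000)
    except RuntimeError:
        return GaussianGenFit(height=float("nan"), width=float("nan"),
                              offset=float("nan"), sse=float("nan"),
                              stable=False)
    resid = y - model(d, *popt)
    sse = float(np.sum(resid ** 2))
    if not np.all(np.isfinite(pcov)) or \
            np.linalg.cond(pcov) > 1e10:
        stable = False
    at_bound = np.any(np.isclose(popt, lo, atol=1e-6)
                      | np.isclose(popt, hi, atol=1e-6))
    if at_bound:
        stable = False
    return GaussianGenFit(height=float(popt[0]), width=float(popt[1]),
                          offset=float(popt[2]), sse=sse, stable=stable)
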