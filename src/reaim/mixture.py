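"""Uniform + two-von-Mises mixture model of reach directions.

Reach angles within an RT bin are modeled as

    P(x) = w1 * VM(x; mu1, kappa) + w2 * VM(x; mu2, kappa)
           + (1 - w1 - w2) * U(-pi, pi),

with a shared concentration kappa, a positively signed mean mu1 in (0, 180]
(correctly signed re-aims), a non-positive mean mu2 in [-180, 0] (sign
flips), and a uniform component absorbing random reaches. Two variants are
fit by multi-start maximum likelihood per RT bin and compared by AIC:

* Free-mu  — both means free (k = 5 parameters), the mental-rotation
  hypothesis, under which the means migrate across bins;
* Fixed-mu — means pinned at +90 / -90 degrees (k = 3), the response-caching
  hypothesis, under which only the weights evolve.

Angles are degrees at the interface; the likelihood works in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special

from .circular import AngleSample, BinSpec, wrap_deg

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "FitConfig",
    "FREE_MU",
    "FIXED_MU",
    "mixture_pdf",
    "negative_log_likelihood",
    "fit_bin",
    "fit_all_bins",
    "compare_models",
    "sample_from_mixture",
]

FREE_MU = "FREE_MU"
FIXED_MU = "FIXED_MU"
_TWO_PI = 2.0 * np.pi
_N_PARAMS = {FREE_MU: 5, FIXED_MU: 3}
_LOW_N = 20  # below this pooled count a fit is flagged


@dataclass
class MixtureParams:
    w1: float
    w2: float
    kappa: float
    mu1_deg: float
    mu2_deg: float

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 > 1.0 + 1e-9:
            raise ValueError("weights must be non-negative with w1 + w2 <= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not (0.0 < self.mu1_deg <= 180.0):
            raise ValueError("mu1 must lie in (0, 180] degrees")
        if not (-180.0 <= self.mu2_deg <= 0.0):
            raise ValueError("mu2 must lie in [-180, 0] degrees")

    @property
    def w_uniform(self) -> float:
        return max(0.0, 1.0 - self.w1 - self.w2)


@dataclass
class MixtureFit:
    params: MixtureParams | None
    nll: float
    aic: float
    n: int
    bin_index: int
    variant: str
    n_starts_used: int
    converged: bool
    low_n: bool = False

    def to_record(self) -> dict:
        p = self.params
        return {
            "bin": self.bin_index, "variant": self.variant,
            "w1": None if p is None else p.w1,
            "w2": None if p is None else p.w2,
            "kappa": None if p is None else p.kappa,
            "mu1_deg": None if p is None else p.mu1_deg,
            "mu2_deg": None if p is None else p.mu2_deg,
            "nll": self.nll, "aic": self.aic, "n": self.n,
            "converged": self.converged,
        }


@dataclass
class FitConfig:
    """Multi-start MLE settings.

    Starts are drawn uniformly inside the bounds from ``seed``; ties among
    local optima are broken by lowest NLL, then lowest start index.
    """

    n_starts: int = 50
    seed: int = 0
    variant: str = FREE_MU
    kappa_bounds: tuple = (0.1, 200.0)
    tol: float = 1e-9

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.variant not in _N_PARAMS:
            raise ValueError(f"unknown variant {self.variant!r}")


def _vm_kernel(cos_dev: np.ndarray, kappa: float) -> np.ndarray:
    # exp(kappa*cos)/(2 pi I0(kappa)) computed with the scaled Bessel i0e
    # so large kappa never overflows
    return np.exp(kappa * (cos_dev - 1.0)) / (_TWO_PI * special.i0e(kappa))


def mixture_pdf(x_deg, params: MixtureParams) -> np.ndarray:
    """Mixture density per radian at target-relative angle(s) in degrees."""
    x = np.deg2rad(np.asarray(x_deg, dtype=float))
    mu1, mu2 = np.deg2rad(params.mu1_deg), np.deg2rad(params.mu2_deg)
    dens = (params.w1 * _vm_kernel(np.cos(x - mu1), params.kappa)
            + params.w2 * _vm_kernel(np.cos(x - mu2), params.kappa)
            + params.w_uniform / _TWO_PI)
    return dens if dens.ndim else float(dens)


def negative_log_likelihood(sample, params: MixtureParams) -> float:
    angles = np.asarray(sample.angles_deg if isinstance(sample, AngleSample)
                        else sample, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    dens = np.asarray(mixture_pdf(angles, params))
    return float(-np.sum(np.log(dens)))


def _nll_and_grad(theta, cosx, sinx, variant):
    """NLL and analytic gradient in the optimizer parameterization.

    theta = (w1, w2, kappa, mu1, mu2) for Free-mu (mus in radians) or
    (w1, w2, kappa) for Fixed-mu.
    """
    w1, w2, kappa = theta[0], theta[1], theta[2]
    if variant == FREE_MU:
        mu1, mu2 = theta[3], theta[4]
    else:
        mu1, mu2 = np.pi / 2.0, -np.pi / 2.0
    c1, s1 = np.cos(mu1), np.sin(mu1)
    c2, s2 = np.cos(mu2), np.sin(mu2)
    cd1 = cosx * c1 + sinx * s1          # cos(x - mu1)
    cd2 = cosx * c2 + sinx * s2
    vm1 = _vm_kernel(cd1, kappa)
    vm2 = _vm_kernel(cd2, kappa)
    u = 1.0 / _TWO_PI
    p = w1 * vm1 + w2 * vm2 + (1.0 - w1 - w2) * u
    p = np.maximum(p, 1e-300)
    nll = -np.sum(np.log(p))
    inv_p = 1.0 / p
    bessel_ratio = special.i1e(kappa) / special.i0e(kappa)
    d_k = w1 * vm1 * (cd1 - bessel_ratio) + w2 * vm2 * (cd2 - bessel_ratio)
    grad = np.empty(len(theta))
    grad[0] = -np.sum((vm1 - u) * inv_p)
    grad[1] = -np.sum((vm2 - u) * inv_p)
    grad[2] = -np.sum(d_k * inv_p)
    if variant == FREE_MU:
        sd1 = sinx * c1 - cosx * s1      # sin(x - mu1)
        sd2 = sinx * c2 - cosx * s2
        grad[3] = -np.sum(w1 * vm1 * kappa * sd1 * inv_p)
        grad[4] = -np.sum(w2 * vm2 * kappa * sd2 * inv_p)
    return nll, grad


def _bounds(config: FitConfig):
    b = [(0.0, 1.0), (0.0, 1.0), config.kappa_bounds]
    if config.variant == FREE_MU:
        b += [(1e-4, np.pi), (-np.pi, 0.0)]
    return b


def _draw_start(rng, config: FitConfig):
    # uniform on the weight triangle, then uniform within remaining bounds
    u1, u2 = rng.uniform(size=2)
    if u1 + u2 > 1.0:
        u1, u2 = 1.0 - u1, 1.0 - u2
    lo_k, hi_k = config.kappa_bounds
    start = [u1, u2, rng.uniform(lo_k, min(hi_k, 32.0))]
    if config.variant == FREE_MU:
        start += [rng.uniform(1e-3, np.pi), rng.uniform(-np.pi, -1e-3)]
    return np.array(start)


def _theta_to_params(theta, variant) -> MixtureParams:
    w1 = float(np.clip(theta[0], 0.0, 1.0))
    w2 = float(np.clip(theta[1], 0.0, 1.0 - w1))
    if variant == FREE_MU:
        mu1 = float(np.clip(np.rad2deg(theta[3]), 1e-9, 180.0))
        mu2 = float(np.clip(np.rad2deg(theta[4]), -180.0, 0.0))
    else:
        mu1, mu2 = 90.0, -90.0
    return MixtureParams(w1=w1, w2=w2, kappa=float(theta[2]),
                         mu1_deg=mu1, mu2_deg=mu2)


def fit_bin(sample, config: FitConfig, bin_index: int = 0) -> MixtureFit:
    """Maximum-likelihood mixture fit for one RT bin's pooled angles.

    Runs ``config.n_starts`` local optimizations (SLSQP under the simplex
    constraint w1 + w2 <= 1) from seeded random starts and keeps the best
    by NLL. Fixed-mu pins the means at +90 / -90 degrees, leaving k = 3 free
    parameters. Bins with fewer than 20 pooled angles are fit but flagged.
    """
    angles = np.asarray(sample.angles_deg if isinstance(sample, AngleSample)
                        else sample, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    x = np.deg2rad(angles)
    cosx, sinx = np.cos(x), np.sin(x)
    rng = np.random.default_rng(config.seed)
    bounds = _bounds(config)
    constraint = {"type": "ineq",
                  "fun": lambda th: 1.0 - th[0] - th[1],
                  "jac": lambda th: np.array([-1.0, -1.0]
                                             + [0.0] * (len(th) - 2))}
    best = None
    any_converged = False
    messages = []
    for start_idx in range(config.n_starts):
        theta0 = _draw_start(rng, config)
        res = optimize.minimize(
            _nll_and_grad, theta0, args=(cosx, sinx, config.variant),
            jac=True, method="SLSQP", bounds=bounds, constraints=[constraint],
            options={"maxiter": 300, "ftol": config.tol})
        if not np.isfinite(res.fun):
            messages.append(f"start {start_idx}: non-finite objective")
            continue
        any_converged = any_converged or res.success
        if best is None or res.fun < best[0] - 1e-12:
            best = (float(res.fun), start_idx, res)
    if best is None or not any_converged:
        raise RuntimeError(
            "no multi-start optimization converged: " + "; ".join(messages[:5]))
    nll, _, res = best
    params = _theta_to_params(res.x, config.variant)
    k = _N_PARAMS[config.variant]
    return MixtureFit(params=params, nll=nll, aic=2.0 * k + 2.0 * nll,
                      n=int(angles.size), bin_index=int(bin_index),
                      variant=config.variant,
                      n_starts_used=config.n_starts, converged=True,
                      low_n=angles.size < _LOW_N)


def default_start_bin(binspec: BinSpec | None = None,
                      lower_edge_ms: float = 150.0) -> int:
    """Bin whose lower edge is 150 ms — the default first analyzed bin."""
    spec = binspec or BinSpec()
    return int(lower_edge_ms / spec.width_ms) + 1


def fit_all_bins(trials, binspec: BinSpec | None = None,
                 config: FitConfig | None = None,
                 start_bin: int | None = None) -> dict:
    """Fit both mixture variants to every RT bin from ``start_bin`` onward.

    ``trials`` must carry ``rt_bin`` (see circular.assign_rt_bins) and
    ``hand_angle_deg``; angles are pooled across subjects within each bin.
    Per-bin failures are recorded as non-converged fits without aborting the
    remaining bins. Returns {variant: [MixtureFit, ...]}.
    """
    binspec = binspec or BinSpec()
    config = config or FitConfig()
    if start_bin is None:
        start_bin = default_start_bin(binspec)
    bins = sorted(b for b in trials["rt_bin"].unique() if b >= start_bin)
    out = {FREE_MU: [], FIXED_MU: []}
    for b in bins:
        angles = trials.loc[trials["rt_bin"] == b, "hand_angle_deg"].to_numpy()
        for variant in (FREE_MU, FIXED_MU):
            cfg = replace(config, variant=variant,
                          seed=config.seed + 1000 * int(b)
                          + (0 if variant == FREE_MU else 1))
            try:
                fit = fit_bin(angles, cfg, bin_index=int(b))
            except (RuntimeError, ValueError):
                fit = MixtureFit(params=None, nll=float("nan"),
                                 aic=float("nan"), n=int(angles.size),
                                 bin_index=int(b), variant=variant,
                                 n_starts_used=cfg.n_starts, converged=False)
            out[variant].append(fit)
    return out


def compare_models(fits_free, fits_fixed) -> dict:
    """Summed and per-bin AIC comparison between the Free-mu and Fixed-mu
    variants.

    delta_aic = AIC(rejected) - AIC(preferred) over the shared bins, so it
    is always non-negative and quantifies how decisively the preferred
    variant wins.
    """
    bins_free = [f.bin_index for f in fits_free]
    bins_fixed = [f.bin_index for f in fits_fixed]
    if bins_free != bins_fixed:
        raise ValueError("variants were fit on different bins")
    rows = []
    for ff, fx in zip(fits_free, fits_fixed):
        rows.append({"bin": ff.bin_index, "aic_free": ff.aic,
                     "aic_fixed": fx.aic, "n": ff.n,
                     "delta": fx.aic - ff.aic})
    aic_free = float(sum(r["aic_free"] for r in rows))
    aic_fixed = float(sum(r["aic_fixed"] for r in rows))
    preferred = FREE_MU if aic_free < aic_fixed else FIXED_MU
    return {"preferred": preferred,
            "delta_aic": abs(aic_fixed - aic_free),
            "aic_free": aic_free, "aic_fixed": aic_fixed,
            "per_bin": rows}


def sample_from_mixture(params: MixtureParams, n: int, seed) -> AngleSample:
    """Draw n angles (degrees) from the mixture; seeded and reproducible."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n,
                      p=[params.w1, params.w2, params.w_uniform])
    out = np.empty(n)
    for idx, mu in ((0, params.mu1_deg), (1, params.mu2_deg)):
        mask = comp == idx
        if mask.any():
            out[mask] = np.rad2deg(
                rng.vonmises(np.deg2rad(mu), params.kappa, size=mask.sum()))
    mask = comp == 2
    if mask.any():
        out[mask] = rng.uniform(-180.0, 180.0, size=mask.sum())
    return AngleSample(wrap_deg(out))
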