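"""Inferential primitives: t-tests, OLS, correlations, the JZS (Jeffreys-
Zellner-Siow) default Bayes factor for a one-sample t, and noncentral-t
power / sample-size computation.

The t-tests, correlations and OLS wrap scipy.stats / statsmodels. The JZS
Bayes factor and the power search are implemented here on top of scipy's
distributions and quadrature: BF01 is the ratio of the null marginal
likelihood of the t statistic to its marginal under a Cauchy(0, r) prior on
the standardized effect size, integrated over the JZS inverse-chi-square
scale mixture (Rouder et al., 2009).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import integrate, stats

__all__ = [
    "TTestResult",
    "BFResult",
    "PowerSpec",
    "RegressionResult",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "jzs_bf01",
    "one_sample_power",
    "required_sample_size",
    "linear_regression",
    "correlations",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    mean_diff: float
    kind: str


@dataclass
class BFResult:
    bf01: float
    t_input: float
    n: int
    prior_scale_r: float


@dataclass
class PowerSpec:
    d: float
    alpha_two_sided: float = 0.05
    power_target: float = 0.95
    test_kind: str = "one_sample"

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("effect size d must be positive")
        if not (0 < self.alpha_two_sided < 1 and 0 < self.power_target < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


@dataclass
class RegressionResult:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    names: list


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t needs n >= 2")
    mean_diff = float(x.mean() - mu0)
    sd = x.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean_diff == 0.0 else float(np.inf) * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        res = stats.ttest_1samp(x, mu0)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t=t, df=x.size - 1, p_two_sided=p,
                       mean_diff=mean_diff, kind="one_sample")


def paired_t(x, y) -> TTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(x - y, 0.0)
    return TTestResult(t=res.t, df=res.df, p_two_sided=res.p_two_sided,
                       mean_diff=res.mean_diff, kind="paired")


def two_sample_t(x, y) -> TTestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("two-sample t needs n >= 2 per group")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=x.size + y.size - 2,
                       p_two_sided=float(res.pvalue),
                       mean_diff=float(x.mean() - y.mean()), kind="two_sample")


def jzs_bf01(t: float, n: int, prior_scale_r: float) -> BFResult:
    """JZS Bayes factor in favor of the null for a one-sample t statistic.

    BF01 = f(t | delta = 0) / integral f(t | g) pi(g) dg, where the
    alternative places a Cauchy(0, r) prior on the standardized effect,
    expressed as the usual scale mixture: delta | g ~ N(0, g r^2),
    g ~ InverseGamma(1/2, 1/2). The g-integral is evaluated by adaptive
    quadrature; the prior scale must be passed explicitly.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    r = float(prior_scale_r)
    if r <= 0:
        raise ValueError("prior scale must be positive")
    v = n - 1
    t2 = float(t) * float(t)

    def integrand(g):
        a = 1.0 + n * g * r * r
        return (a ** -0.5
                * (1.0 + t2 / (a * v)) ** (-(v + 1) / 2.0)
                * (2.0 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1.0 / (2.0 * g)))

    alt, err = integrate.quad(integrand, 0.0, np.inf, limit=400,
                              epsabs=0.0, epsrel=1e-10)
    if not np.isfinite(alt) or alt <= 0 or err > 1e-6 * alt:
        raise ArithmeticError("JZS marginal likelihood integration failed")
    null = (1.0 + t2 / v) ** (-(v + 1) / 2.0)
    return BFResult(bf01=float(null / alt), t_input=float(t), n=int(n),
                    prior_scale_r=r)


def _nct_cdf(t: float, df: int, ncp: float) -> float:
    """Noncentral-t CDF, with a quadrature fallback where scipy's
    implementation loses accuracy (very large noncentrality)."""
    val = stats.nct.cdf(t, df, ncp)
    if np.isfinite(val):
        return float(val)
    # P(T' <= t) = E_W[ Phi(t sqrt(W/df) - ncp) ], W ~ chi^2_df
    out, _ = integrate.quad(
        lambda w: stats.norm.cdf(t * np.sqrt(w / df) - ncp)
        * stats.chi2.pdf(w, df), 0.0, np.inf, limit=200)
    return float(out)


def one_sample_power(n: int, d: float, alpha_two_sided: float = 0.05) -> float:
    """Power of a two-tailed one-sample t-test via the noncentral t."""
    if n < 2:
        raise ValueError("n must be at least 2")
    df = n - 1
    crit = float(stats.t.ppf(1.0 - alpha_two_sided / 2.0, df))
    ncp = d * np.sqrt(n)
    return float(1.0 - _nct_cdf(crit, df, ncp) + _nct_cdf(-crit, df, ncp))


def required_sample_size(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n >= 2 whose two-tailed one-sample t power meets the target."""
    if spec.test_kind != "one_sample":
        raise ValueError("only one-sample power is implemented")
    for n in range(2, n_max + 1):
        if one_sample_power(n, spec.d, spec.alpha_two_sided) >= spec.power_target:
            return n
    raise ValueError("requested power not reachable within n_max")


def linear_regression(y, X, names=None, add_intercept: bool = True
                      ) -> RegressionResult:
    """OLS with per-coefficient two-sided t-tests (statsmodels backend)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["intercept"] + names
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(params=np.asarray(fit.params),
                            bse=np.asarray(fit.bse),
                            tvalues=np.asarray(fit.tvalues),
                            pvalues=np.asarray(fit.pvalues),
                            resid=np.asarray(fit.resid), names=names)


def correlations(x, y) -> dict:
    """Pearson r and Spearman rho with two-sided p-values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlations need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": float("nan"), "pearson_p": float("nan"),
                "spearman_rho": float("nan"), "spearman_p": float("nan"),
                "defined": False, "n": int(x.size)}
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(x, y)
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sp.statistic), "spearman_p": float(sp.pvalue),
            "defined": True, "n": int(x.size)}
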