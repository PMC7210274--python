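"""Inference layer: JZS Bayes-factor t-tests, pooled correlations,
Cook's-d bivariate outlier screening, and Greenhouse-Geisser rmANOVA.

The Bayes factors follow the default JZS formulation: a Cauchy(0, r=0.707)
prior on the standardized effect size under H1 and a point null, with the
marginal likelihood obtained by numerical integration of the noncentral-t
density against the Cauchy prior.  Correlation grids are pooled on the
Fisher-z scale with n-3 weights (the inverse asymptotic variance of z) and
back-transformed with tanh.  The repeated-measures ANOVA layer delegates the
F table to statsmodels' AnovaRM and computes Mauchly's W, the
Greenhouse-Geisser epsilon, and epsilon-corrected degrees of freedom and
p-values from the covariance of orthonormal within-subject contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, linalg
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "DEFAULT_CAUCHY_SCALE",
    "pearson_r",
    "cooks_distances",
    "remove_bivariate_outliers",
    "bf10_from_t",
    "jzs_bf_one_sample",
    "jzs_bf_paired",
    "OneSampleBF",
    "pool_correlations",
    "PooledCorrelation",
    "gg_epsilon",
    "mauchly_w",
    "gg_corrected_df",
    "rm_anova_gg",
    "TestResult",
]

DEFAULT_CAUCHY_SCALE = 0.707


# --------------------------------------------------------------------------
# correlations and influence
# --------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


def cooks_distances(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Cook's distance of each point under the simple regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0:
        raise ValueError("degenerate predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return model.get_influence().cooks_distance[0]


def remove_bivariate_outliers(
    x: Sequence[float], y: Sequence[float], threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass influential-point removal: drop points with Cook's d > 1.

    The first-named variable of a measure pair serves as the regression
    predictor.  Returns (kept indices, removed indices); more than ceil(n/10)
    removals on one pair triggers a warning, as that pattern suggests the
    regression itself is misspecified rather than a few stray points.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    d = cooks_distances(x, y)
    removed = np.flatnonzero(d > threshold)
    kept = np.flatnonzero(d <= threshold)
    if removed.size > math.ceil(x.size / 10):
        warnings.warn(
            f"Cook's-d screen removed {removed.size} of {x.size} points",
            stacklevel=2,
        )
    return kept, removed


# --------------------------------------------------------------------------
# JZS Bayes-factor t-tests
# --------------------------------------------------------------------------

def bf10_from_t(t: float, n: int, cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> float:
    """JZS BF10 for a one-sample t statistic with n observations.

    The Cauchy(0, r) prior on the standardized effect size is expressed as a
    scale mixture of normals with an InvGamma(1/2, 1/2) mixing density on g,
    so BF10 reduces to a one-dimensional integral over g.  It is evaluated
    in log space (each factor is exponentiated only after the central-t
    kernel is divided out, keeping the integrand on the scale of the Bayes
    factor itself) with adaptive quadrature on the compactified variable
    u = g/(1+g).  Values below 1 support the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    nu = n - 1
    r2 = cauchy_scale * cauchy_scale
    log_h0_kernel = -(nu + 1) / 2.0 * math.log1p(t * t / nu)
    log_prior_const = -0.5 * math.log(2.0 * math.pi)

    def integrand(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        g = u / (1.0 - u)
        a = 1.0 + n * g * r2
        log_kernel = (
            -0.5 * math.log(a)
            - (nu + 1) / 2.0 * math.log1p(t * t / (a * nu))
            - log_h0_kernel
        )
        log_prior = log_prior_const - 1.5 * math.log(g) - 0.5 / g
        log_jac = -2.0 * math.log1p(-u)
        return math.exp(log_kernel + log_prior + log_jac)

    bf, err = integrate.quad(
        integrand, 0.0, 1.0, limit=300, epsabs=0.0, epsrel=1e-10, points=[0.5]
    )
    if not np.isfinite(bf) or bf <= 0 or err > 1e-6 * bf:
        raise RuntimeError("Bayes-factor quadrature did not converge")
    return float(bf)


@dataclass(frozen=True)
class OneSampleBF:
    t: float
    df: int
    p: float
    bf10: float
    n: int


def jzs_bf_one_sample(
    values: Sequence[float],
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    mu0: float = 0.0,
) -> OneSampleBF:
    """Classical one-sample t-test plus the default JZS Bayes factor."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance")
    t = float((x.mean() - mu0) / (sd / math.sqrt(x.size)))
    df = x.size - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return OneSampleBF(t=t, df=df, p=p, bf10=bf10_from_t(t, x.size, cauchy_scale), n=x.size)


def jzs_bf_paired(
    x: Sequence[float],
    y: Sequence[float],
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
) -> OneSampleBF:
    """Paired JZS t-test: the one-sample test on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return jzs_bf_one_sample(x - y, cauchy_scale)


# --------------------------------------------------------------------------
# Fisher-z pooling of correlation grids
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledCorrelation:
    m_r: float
    ci95: tuple[float, float]
    bf10: float
    t: float
    z_values: np.ndarray = field(repr=False)
    n_values: np.ndarray = field(repr=False)
    ci_method: str = "posterior"


def _posterior_mean_interval(
    values: np.ndarray,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    level: float = 0.95,
) -> tuple[float, float]:
    """Central credible interval for the population mean of ``values`` under
    the JZS model (Cauchy(0, r*sigma) prior on the mean, Jeffreys on sigma),
    by 2-D grid integration over (mu, log sigma)."""
    y = np.asarray(values, dtype=float)
    n = y.size
    m, s = y.mean(), y.std(ddof=1)
    se = s / math.sqrt(n)
    mu = np.linspace(m - 10 * se, m + 10 * se, 801)
    logsig = np.linspace(math.log(s) - 3.0, math.log(s) + 3.0, 241)
    sig = np.exp(logsig)[None, :]  # prior on log sigma is flat (Jeffreys)
    ss = ((y[:, None, None] - mu[None, :, None]) ** 2).sum(axis=0)
    logpost = (
        -n * logsig[None, :]
        - ss / (2.0 * sig**2)
        + sps.cauchy.logpdf(mu[:, None], 0.0, cauchy_scale * sig)
    )
    logpost -= logpost.max()
    dens_mu = np.trapezoid(np.exp(logpost), logsig, axis=1)
    cdf = integrate.cumulative_trapezoid(dens_mu, mu, initial=0.0)
    cdf /= cdf[-1]
    alpha = (1.0 - level) / 2.0
    lo = float(np.interp(alpha, cdf, mu))
    hi = float(np.interp(1.0 - alpha, cdf, mu))
    return lo, hi


def pool_correlations(
    cells: Sequence[tuple[float, int]],
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    ci_method: str = "posterior",
) -> PooledCorrelation:
    """Pool per-cell Pearson r values into a single M_r with interval and BF.

    Each cell is (r, n).  r values are Fisher-z transformed, averaged with
    weights n-3, and the weighted mean is back-transformed with tanh.  The
    Bayes factor is the one-sample JZS test of the (unweighted) z values
    against zero, and the interval is the central 95% interval on the mean z
    - posterior under the JZS model by default, a frequentist t-interval
    with ``ci_method="t"`` - mapped through tanh.
    """
    rs = np.array([c[0] for c in cells], dtype=float)
    ns = np.array([c[1] for c in cells], dtype=int)
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher-z transform")
    if np.any(ns <= 3):
        raise ValueError("cells need n > 3 for n-3 weighting")
    z = np.arctanh(rs)
    w = ns - 3.0
    zbar = float(np.sum(w * z) / np.sum(w))
    if z.std(ddof=1) == 0.0:
        # identical cells: the pooled value is exact, the t-test degenerate
        return PooledCorrelation(
            m_r=float(np.tanh(zbar)),
            ci95=(float(np.tanh(zbar)), float(np.tanh(zbar))),
            bf10=float("nan"),
            t=float("nan"),
            z_values=z,
            n_values=ns,
            ci_method=ci_method,
        )
    test = jzs_bf_one_sample(z, cauchy_scale)
    if ci_method == "posterior":
        lo, hi = _posterior_mean_interval(z, cauchy_scale)
    elif ci_method == "t":
        se = z.std(ddof=1) / math.sqrt(z.size)
        tcrit = sps.t.ppf(0.975, z.size - 1)
        lo, hi = z.mean() - tcrit * se, z.mean() + tcrit * se
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return PooledCorrelation(
        m_r=float(np.tanh(zbar)),
        ci95=(float(np.tanh(lo)), float(np.tanh(hi))),
        bf10=test.bf10,
        t=test.t,
        z_values=z,
        n_values=ns,
        ci_method=ci_method,
    )


# --------------------------------------------------------------------------
# repeated-measures ANOVA with sphericity diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """Container for one inferential test (t, F or W)."""

    kind: str
    value: float
    df: tuple[float, ...]
    p: float
    bf10: Optional[float] = None
    epsilon: Optional[float] = None
    mauchly_w: Optional[float] = None
    mauchly_p: Optional[float] = None
    df_gg: Optional[tuple[float, float]] = None
    p_gg: Optional[float] = None
    notes: str = ""


def _contrast_cov(scores: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    sigma = np.cov(scores, rowvar=False, ddof=1)
    return contrast @ sigma @ contrast.T


def gg_epsilon(scores: np.ndarray, contrast: Optional[np.ndarray] = None) -> float:
    """Greenhouse-Geisser epsilon from a subjects x cells score matrix.

    epsilon = tr(S)^2 / (d * tr(S^2)) with S the covariance of the
    orthonormal within-subject contrasts (d = cells - 1 by default);
    bounded in [1/d, 1].
    """
    scores = np.asarray(scores, dtype=float)
    k = scores.shape[1]
    if contrast is None:
        contrast = linalg.helmert(k, full=False)
    s = _contrast_cov(scores, contrast)
    d = s.shape[0]
    tr = np.trace(s)
    eps = tr**2 / (d * np.sum(s * s))
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_w(
    scores: np.ndarray, contrast: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Mauchly's sphericity test: (W, p) via the chi-square approximation."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if contrast is None:
        contrast = linalg.helmert(k, full=False)
    s = _contrast_cov(scores, contrast)
    d = s.shape[0]
    if d < 2:
        return 1.0, 1.0
    det = linalg.det(s)
    w = float(det / (np.trace(s) / d) ** d) if det > 0 else 0.0
    if w <= 0:
        return 0.0, 0.0
    f_corr = (2.0 * d**2 + d + 2.0) / (6.0 * d)
    chi2 = -(n - 1 - f_corr) * math.log(w)
    df = d * (d + 1) / 2.0 - 1.0
    return w, float(sps.chi2.sf(chi2, df))


def gg_corrected_df(
    epsilon: float, df1: float, df2: float
) -> tuple[float, float]:
    """Degrees of freedom after Greenhouse-Geisser correction."""
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    return epsilon * df1, epsilon * df2


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    within: tuple[str, str] = ("time", "condition"),
) -> dict[str, TestResult]:
    """Two-way within-subject ANOVA with sphericity diagnostics.

    ``data`` is a complete balanced long table.  Returns a result per effect
    ("time", "condition", "time x condition" in the factor names given),
    each carrying the uncorrected F test, Mauchly's W, Greenhouse-Geisser
    epsilon and the epsilon-corrected df and p.
    """
    w1, w2 = within
    cells = data.groupby([subject, w1, w2], observed=True)[dv].count()
    if cells.min() != 1 or cells.max() != 1:
        raise ValueError("table must be balanced with one value per cell (no imputation)")
    table = AnovaRM(data, depvar=dv, subject=subject, within=list(within)).fit().anova_table

    wide = data.pivot_table(index=subject, columns=[w1, w2], values=dv, observed=True)
    levels1 = sorted(data[w1].unique())
    levels2 = sorted(data[w2].unique())
    wide = wide.reindex(columns=pd.MultiIndex.from_product([levels1, levels2]))
    a, b = len(levels1), len(levels2)
    n = wide.shape[0]
    if n < max(a, b):
        raise ValueError("need at least as many subjects as factor levels")
    y = wide.to_numpy()

    effect_scores = {
        w1: (y.reshape(n, a, b).mean(axis=2), linalg.helmert(a, full=False)),
        w2: (y.reshape(n, a, b).mean(axis=1), linalg.helmert(b, full=False)),
        f"{w1} x {w2}": (
            y,
            np.kron(linalg.helmert(a, full=False), linalg.helmert(b, full=False)),
        ),
    }
    name_map = {w1: w1, w2: w2, f"{w1}:{w2}": f"{w1} x {w2}"}

    out: dict[str, TestResult] = {}
    for sm_name, name in name_map.items():
        row = table.loc[sm_name]
        f_val, df1, df2, p = (
            float(row["F Value"]),
            float(row["Num DF"]),
            float(row["Den DF"]),
            float(row["Pr > F"]),
        )
        scores, contrast = effect_scores[name]
        eps = gg_epsilon(scores, contrast)
        w, w_p = mauchly_w(scores, contrast)
        df_gg = gg_corrected_df(eps, df1, df2)
        out[name] = TestResult(
            kind="F",
            value=f_val,
            df=(df1, df2),
            p=p,
            epsilon=eps,
            mauchly_w=w,
            mauchly_p=w_p,
            df_gg=df_gg,
            p_gg=float(sps.f.sf(f_val, *df_gg)),
        )
    return out
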