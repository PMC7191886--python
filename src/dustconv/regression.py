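"""Per-group log-log regression with fit statistics and diagnostics.

Because workplace dust concentrations are well described as lognormal,
the respirable concentration is modelled on the inhalable one in log
space,

    ln(c_R) = k · ln(c_I) + C0,

fitted by ordinary least squares within a group of measurement pairs.
Back-transformed this is a power law, c_R = c_I**k · exp(C0).  Besides
the coefficients and their standard errors, each fit reports the
Pearson correlation R, the sample-size adjusted R², the standard error
of the fitted regression mean s_Fit(ln c_R) — smallest at the predictor
mean, largest at the observed extremes — plus the Durbin–Watson
statistic (residual autocorrelation in time order) and a Monte-Carlo
Lilliefors test of residual normality.

The OLS solution is computed from the closed-form normal equations;
tests cross-check it against an independent library implementation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .records import MeasurementPair

__all__ = [
    "RegressionResult",
    "fit_loglog",
    "fit_xy",
    "adjusted_r2",
    "s_fit",
    "confidence_band",
    "durbin_watson",
    "lilliefors_normality",
]


@dataclasses.dataclass
class RegressionResult:
    """Fitted coefficients and diagnostics for one group."""

    group_id: object | None
    n: int
    k: float
    C0: float
    se_k: float
    se_C0: float
    R: float
    R2: float
    adj_R2: float
    s_resid: float
    x_mean: float
    Sxx: float
    s_fit_min: float
    s_fit_max: float
    dw: float | None = None
    lilliefors_p: float | None = None


def adjusted_r2(R2: float, n: int, m: int = 1) -> float:
    """Coefficient of determination adjusted for sample size.

    ``adj R² = R² − m/(n − m − 1) · (1 − R²)`` with ``m`` predictors and
    ``n`` observations; for n >> m it approaches R².
    """
    if not 0.0 <= R2 <= 1.0:
        raise ValueError("R2 must be in [0, 1]")
    if n <= m + 1:
        raise ValueError("need n > m + 1 observations")
    return R2 - (m / (n - m - 1)) * (1.0 - R2)


def fit_xy(
    x: np.ndarray, y: np.ndarray, group_id: object | None = None
) -> RegressionResult:
    """OLS fit of ``y = k·x + C0`` via the normal equations.

    ``x`` and ``y`` are log concentrations in fit order.  Requires at
    least 3 points and non-degenerate ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 (x, y) points")
    x_mean = float(x.mean())
    y_mean = float(y.mean())
    dx = x - x_mean
    Sxx = float(dx @ dx)
    if Sxx <= 0.0:
        raise ValueError("degenerate predictor: zero variance in ln c_I")
    Sxy = float(dx @ (y - y_mean))
    k = Sxy / Sxx
    C0 = y_mean - k * x_mean

    resid = y - (k * x + C0)
    sse = float(resid @ resid)
    syy = float((y - y_mean) @ (y - y_mean))
    s_resid = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
    se_k = s_resid / math.sqrt(Sxx)
    se_C0 = s_resid * math.sqrt(1.0 / n + x_mean**2 / Sxx)
    R = Sxy / math.sqrt(Sxx * syy) if syy > 0 else 1.0
    R2 = R * R
    leverage = 1.0 / n + (x - x_mean) ** 2 / Sxx
    return RegressionResult(
        group_id=group_id,
        n=n,
        k=k,
        C0=C0,
        se_k=se_k,
        se_C0=se_C0,
        R=R,
        R2=R2,
        adj_R2=adjusted_r2(R2, n),
        s_resid=s_resid,
        x_mean=x_mean,
        Sxx=Sxx,
        s_fit_min=s_resid * math.sqrt(1.0 / n),
        s_fit_max=s_resid * math.sqrt(float(leverage.max())),
    )


def fit_loglog(
    pairs: Sequence[MeasurementPair],
    group_id: object | None = None,
    *,
    seed: int | None = None,
    n_mc: int = 2000,
) -> RegressionResult:
    """Fit ln(c_R) on ln(c_I) for a group of measurement pairs.

    Pairs are put in time order (inhalable start time, ties by
    record_id) before fitting so the Durbin–Watson statistic measures
    autocorrelation along the natural time axis.  If ``seed`` is given
    and the group has at least 5 pairs, a Monte-Carlo Lilliefors
    normality p-value for the residuals is attached.
    """
    ordered = sorted(pairs, key=lambda p: (p.inhalable.start, p.inhalable.record_id))
    x = np.array([p.ln_ci for p in ordered])
    y = np.array([p.ln_cr for p in ordered])
    result = fit_xy(x, y, group_id=group_id)
    resid = y - (result.k * x + result.C0)
    if np.any(resid != 0.0):
        result.dw = durbin_watson(resid)
    if seed is not None and x.size >= 5 and result.s_resid > 0:
        result.lilliefors_p = lilliefors_normality(resid, n_mc=n_mc, seed=seed)
    return result


def s_fit(result: RegressionResult, ln_ci: float) -> float:
    """Standard error of the fitted regression mean at ``ln_ci``."""
    return result.s_resid * math.sqrt(
        1.0 / result.n + (ln_ci - result.x_mean) ** 2 / result.Sxx
    )


def confidence_band(
    result: RegressionResult, ln_ci: float, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for the regression mean at ``ln_ci`` (log space).

    The half-width is z(level) · s_Fit(ln_ci); it is minimal at the
    predictor mean.  Normal quantiles are used throughout (1.96 at the
    default 95% level), not t quantiles: group sizes are large.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be inside (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    center = result.k * ln_ci + result.C0
    half = z * s_fit(result, ln_ci)
    return center - half, center + half


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin–Watson statistic of residuals in fit order.

    Sum of squared successive differences over the sum of squares; lies
    in [0, 4], with 2 for uncorrelated residuals.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("undefined for all-zero residuals")
    d = np.diff(e)
    return float(d @ d) / denom


def _lilliefors_distance(z: np.ndarray) -> float:
    """KS distance of standardised, sorted values against the normal cdf."""
    n = z.shape[-1]
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = grid - cdf
    d_minus = cdf - (grid - 1.0 / n)
    return float(np.max(np.maximum(d_plus, d_minus)))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_distances(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    table = _NULL_CACHE.get(key)
    if table is None:
        rng = np.random.default_rng(seed)
        out = np.empty(n_mc)
        # chunked so large n·n_mc products stay within modest memory
        block = max(1, int(2_000_000 // n))
        grid = np.arange(1, n + 1) / n
        done = 0
        while done < n_mc:
            m = min(block, n_mc - done)
            sims = rng.standard_normal((m, n))
            sims -= sims.mean(axis=1, keepdims=True)
            sims /= sims.std(axis=1, ddof=1, keepdims=True)
            sims.sort(axis=1)
            cdf = stats.norm.cdf(sims)
            d = np.maximum(grid - cdf, cdf - (grid - 1.0 / n)).max(axis=1)
            out[done : done + m] = d
            done += m
        table = np.sort(out)
        _NULL_CACHE[key] = table
    return table


def lilliefors_normality(
    residuals: Sequence[float], n_mc: int = 10000, *, seed: int
) -> float:
    """Lilliefors-corrected Kolmogorov–Smirnov normality test, MC p-value.

    The sample is standardised with its own estimated mean and standard
    deviation, and the KS distance against the standard normal cdf is
    compared with a Monte-Carlo null distribution built from ``n_mc``
    standard-normal samples of the same size run through the same
    estimation step.  Reproducible given ``seed``; the null table is
    cached per (n, n_mc, seed).
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 residuals")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant sample has no normality p-value")
    z = np.sort((x - x.mean()) / sd)
    d_obs = _lilliefors_distance(z)
    null = _null_distances(n, n_mc, seed)
    n_ge = int(null.size - np.searchsorted(null, d_obs, side="left"))
    return (1.0 + n_ge) / (n_mc + 1.0)
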