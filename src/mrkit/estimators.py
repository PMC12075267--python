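"""Causal-effect estimators for two-sample MR summary data.

Three estimators operate on a :class:`~mrkit.harmonize.HarmonizedSet` of J
per-SNP effect pairs (beta_xj, se_xj, beta_yj, se_yj):

* **IVW** — inverse-variance-weighted regression of outcome on exposure
  effects through the origin; equivalently the inverse-variance meta-analysis
  of the per-SNP Wald ratios.  The multiplicative random-effects variant
  (default) inflates the fixed-effect standard error by
  max(1, sqrt(Q/(J-1))) to absorb balanced heterogeneity.
* **MR-Egger** — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy, the slope the causal
  effect.  Inference uses the t reference with J-2 df, which matters at the
  small instrument counts typical of single-trait exposures.
* **Weighted median** — the weight-0.5 quantile of the ordered Wald ratios;
  consistent when at least half the weight comes from valid instruments.
  Its standard error comes from a seeded parametric bootstrap.

All log-scale estimates convert to odds ratios via exp().
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import EstimationImpossibleError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with odds-ratio conversion and CI."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    alpha: float = DEFAULT_ALPHA


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger slope (causal effect) and intercept (directional pleiotropy)."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def to_odds_ratio(
    beta: float, se: float, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, float]:
    """exp-transform a log-scale estimate: (OR, CI low, CI high)."""
    if not se >= 0:
        raise ValueError("negative se")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _finish(
    method: str,
    n_snp: int,
    beta: float,
    se: float,
    alpha: float,
    pval: float | None = None,
) -> MREstimate:
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
    or_, lo, hi = to_odds_ratio(beta, se, alpha)
    return MREstimate(
        method=method, n_snp=n_snp, beta=float(beta), se=float(se),
        pval=pval, or_=or_, ci_low=lo, ci_high=hi, alpha=alpha,
    )


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    alpha: float = DEFAULT_ALPHA,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate beta_y/beta_x.

    The default first-order standard error se_y/|beta_x| ignores the exposure
    sampling error; ``second_order=True`` adds the delta-method term in se_x.
    """
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    if second_order:
        se = np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        se = abs(se_y / beta_x)
    return _finish("wald", 1, beta, se, alpha)


def _ivw_fixed_core(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[float, float, float]:
    """(beta, se_fixed, Q) of the fixed-effect IVW fit."""
    w = 1.0 / se_y**2
    denom = float(np.sum(w * beta_x**2))
    beta = float(np.sum(w * beta_x * beta_y)) / denom
    se = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (beta_y - beta * beta_x) ** 2))
    return beta, se, q


def ivw(
    hset: HarmonizedSet,
    model: str = "multiplicative_random",
    alpha: float = DEFAULT_ALPHA,
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    ``model="fixed"`` is the plain weighted regression through the origin;
    ``model="multiplicative_random"`` (default) inflates its standard error
    by max(1, sqrt(Q/(J-1))).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = hset.j
    if j == 0:
        raise EstimationImpossibleError("IVW with zero instruments")
    if j == 1:
        if model == "fixed":
            logger.info("IVW with a single instrument degenerates to the Wald ratio")
            est = wald_ratio(
                hset.beta_x[0], hset.se_x[0], hset.beta_y[0], hset.se_y[0], alpha
            )
            return _finish("ivw_fixed", 1, est.beta, est.se, alpha, est.pval)
        raise EstimationImpossibleError(
            "multiplicative random-effects IVW needs at least 2 instruments"
        )
    beta, se, q = _ivw_fixed_core(hset.beta_x, hset.beta_y, hset.se_y)
    if model == "multiplicative_random":
        se *= max(1.0, float(np.sqrt(q / (j - 1))))
        method = "ivw_mre"
    else:
        method = "ivw_fixed"
    return _finish(method, j, beta, se, alpha)


def batch_ivw_fixed(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixed-effect IVW over replicate rows.

    ``beta_x`` and ``beta_y`` are (R, J) arrays of replicate summary effects
    sharing the (J,) outcome standard errors ``se_y``; returns (R,) arrays of
    point estimates and standard errors.  Used for power validation and
    calibration studies.
    """
    w = 1.0 / se_y**2
    denom = np.sum(w * beta_x**2, axis=-1)
    beta = np.sum(w * beta_x * beta_y, axis=-1) / denom
    return beta, np.sqrt(1.0 / denom)


def _oriented(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP sign convention for Egger: exposure effects non-negative."""
    sign = np.where(hset.beta_x < 0, -1.0, 1.0)
    return hset.beta_x * sign, hset.beta_y * sign


def egger(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> EggerFit:
    """MR-Egger weighted regression with a free intercept.

    SNPs are first oriented so every exposure effect is non-negative (the fit
    is invariant to per-SNP sign flips of the pair).  Both standard errors
    use multiplicative residual inflation max(1, sqrt(Q'/(J-2))) and t-based
    p-values with J-2 df.
    """
    j = hset.j
    if j < 3:
        raise EstimationImpossibleError(
            "MR-Egger needs at least 3 instruments for a residual df"
        )
    bx, by = _oriented(hset)
    w = 1.0 / hset.se_y**2
    res = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # res.scale = Q'/(J-2) with Q' the weighted residual sum of squares
    inflate = max(1.0, float(np.sqrt(res.scale)))
    cov_unscaled = np.asarray(res.normalized_cov_params)
    se_a = float(np.sqrt(cov_unscaled[0, 0])) * inflate
    se_b = float(np.sqrt(cov_unscaled[1, 1])) * inflate
    a, b = (float(v) for v in res.params)
    df = j - 2
    p_a = float(2.0 * stats.t.sf(abs(a) / se_a, df))
    p_b = float(2.0 * stats.t.sf(abs(b) / se_b, df))
    slope = _finish("egger_slope", j, b, se_b, alpha, p_b)
    return EggerFit(slope=slope, intercept=a, intercept_se=se_a, intercept_pval=p_a)


def _weighted_median_rows(
    theta: np.ndarray, weight: np.ndarray
) -> np.ndarray:
    """Row-wise weighted median by linear interpolation of cumulative midpoints.

    ``theta`` and ``weight`` are (R, J); weights are normalized per row.  The
    estimate interpolates theta across the two cumulative-midpoint positions
    bracketing 0.5, clamping to the extreme theta at the boundaries.
    """
    theta = np.atleast_2d(theta)
    weight = np.atleast_2d(weight)
    w = weight / np.sum(weight, axis=1, keepdims=True)
    order = np.argsort(theta, axis=1)
    theta_s = np.take_along_axis(theta, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    cum = np.cumsum(w_s, axis=1)
    mid = cum - w_s / 2.0
    idx = np.sum(mid < 0.5, axis=1)  # first midpoint >= 0.5
    j = theta.shape[1]
    rows = np.arange(theta.shape[0])
    out = np.empty(theta.shape[0])
    low = idx == 0
    high = idx == j
    out[low] = theta_s[low, 0]
    out[high] = theta_s[high, -1]
    inner = ~(low | high)
    if np.any(inner):
        i1 = idx[inner]
        i0 = i1 - 1
        r = rows[inner]
        p0, p1 = mid[r, i0], mid[r, i1]
        t0, t1 = theta_s[r, i0], theta_s[r, i1]
        frac = np.where(p1 > p0, (0.5 - p0) / np.where(p1 > p0, p1 - p0, 1.0), 0.0)
        out[inner] = t0 + (t1 - t0) * frac
    return out


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap se.

    Per-SNP ratios are weighted by beta_x^2/se_y^2 (the inverse Wald-ratio
    variances).  The bootstrap redraws summary effects from their sampling
    distributions ``n_boot`` times with a caller-supplied seed; instruments
    with beta_x = 0 are excluded with a warning.
    """
    keep = hset.beta_x != 0
    if not np.all(keep):
        logger.warning(
            "weighted median: excluding %d SNP(s) with beta_x = 0",
            int(np.sum(~keep)),
        )
        hset = hset.subset(keep)
    if hset.j < 3:
        raise EstimationImpossibleError("weighted median needs at least 3 instruments")
    bx, by, sx, sy = hset.beta_x, hset.beta_y, hset.se_x, hset.se_y
    theta = by / bx
    weight = bx**2 / sy**2
    point = float(_weighted_median_rows(theta, weight)[0])

    rng = np.random.default_rng(seed)
    bxs = bx + sx * rng.standard_normal((n_boot, hset.j))
    bys = by + sy * rng.standard_normal((n_boot, hset.j))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = _weighted_median_rows(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", hset.j, point, se, alpha)
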