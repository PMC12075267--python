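"""Heterogeneity, pleiotropy, and outlier diagnostics for an MR instrument set.

Cochran's Q (at the fixed-effect IVW estimate) and Ruecker's Q' (around the
Egger fit) measure residual heterogeneity; the Egger intercept tests average
directional pleiotropy; leave-one-out estimation flags single influential
SNPs; and MR-PRESSO resamples the leave-one-out residual sum of squares to
give a global pleiotropy test, per-SNP outlier tests (Bonferroni-adjusted),
and a distortion test for the outlier-corrected estimate.

All stochastic routines take an explicit seed and consume random draws in
snp_id-sorted order, so results do not depend on the input row order.
Functions return ``None`` (with a log message) when the instrument count is
below the statistic's minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import DEFAULT_ALPHA, EggerFit, MREstimate, _ivw_fixed_core, _oriented, egger, ivw
from .exceptions import EstimationImpossibleError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

DEFAULT_N_SIM = 1000
PRESSO_MIN_J = 4


@dataclass(frozen=True)
class QTest:
    """A heterogeneity statistic with its degrees of freedom and p-value."""

    q: float
    df: int
    p: float


@dataclass(frozen=True)
class LeaveOneOut:
    full: MREstimate
    entries: list[tuple[str, MREstimate | None]]


@dataclass(frozen=True)
class PressoResult:
    global_rss_obs: float
    global_p: float
    n_sim: int
    outlier_p: dict[str, float]
    outliers: frozenset[str]
    corrected_estimate: MREstimate | None
    distortion_p: float | None
    seed: int


@dataclass
class DiagnosticsReport:
    """Everything a sensitivity table needs for one exposure-outcome pair."""

    q_ivw: QTest | None
    q_egger: QTest | None
    egger_intercept: tuple[float, float, float] | None  # (value, se, p)
    presso: PressoResult | None
    loo: LeaveOneOut | None


def cochran_q(hset: HarmonizedSet, beta_hat: float) -> QTest | None:
    """Cochran's Q around the fixed-effect IVW fit: sum of squared weighted residuals."""
    j = hset.j
    if j < 2:
        logger.info("Cochran's Q needs at least 2 instruments (J=%d)", j)
        return None
    q = float(np.sum((hset.beta_y - beta_hat * hset.beta_x) ** 2 / hset.se_y**2))
    df = j - 1
    return QTest(q=q, df=df, p=float(stats.chi2.sf(q, df)))


def rucker_q(hset: HarmonizedSet, fit: EggerFit) -> QTest | None:
    """Ruecker's Q' around the Egger fit (orientation-fixed data); Q' <= Q always."""
    j = hset.j
    if j < 3:
        logger.info("Ruecker's Q' needs at least 3 instruments (J=%d)", j)
        return None
    bx, by = _oriented(hset)
    resid = by - fit.intercept - fit.slope.beta * bx
    q = float(np.sum(resid**2 / hset.se_y**2))
    df = j - 2
    return QTest(q=q, df=df, p=float(stats.chi2.sf(q, df)))


def leave_one_out(
    hset: HarmonizedSet,
    model: str = "multiplicative_random",
    alpha: float = DEFAULT_ALPHA,
) -> LeaveOneOut:
    """Default-IVW estimate with each SNP removed in turn.

    Entries whose reduced set cannot support the model (e.g. a single
    remaining instrument under the random-effects model) are marked with
    ``None``.
    """
    full = ivw(hset, model=model, alpha=alpha)
    entries: list[tuple[str, MREstimate | None]] = []
    for k in range(hset.j):
        mask = np.ones(hset.j, dtype=bool)
        mask[k] = False
        try:
            est = ivw(hset.subset(mask), model=model, alpha=alpha)
        except EstimationImpossibleError:
            est = None
        entries.append((str(hset.snp_id[k]), est))
    return LeaveOneOut(full=full, entries=entries)


def _loo_theta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP.

    Works on trailing axis; ``bx``/``by`` may be (J,) or (R, J).
    """
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx**2, axis=-1, keepdims=True) - w * bx**2
    return num / den


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    outlier_alpha: float = DEFAULT_ALPHA,
) -> PressoResult | None:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed residual sum of squares compares each SNP's outcome effect
    with its leave-one-out fixed-effect IVW prediction.  ``n_sim`` synthetic
    datasets are drawn from the no-pleiotropy sampling model and fully
    re-analysed (leave-one-out predictions recomputed per dataset); empirical
    p-values use the add-one correction so they are never exactly zero.
    Per-SNP outlier p-values are Bonferroni-multiplied by J.  When outliers
    are flagged, the corrected estimate is the fixed-effect IVW on the
    non-outlier set and the distortion p compares its displacement from the
    full-set estimate with displacements under random removal of equally many
    SNPs.
    """
    if hset.j < PRESSO_MIN_J:
        logger.info("MR-PRESSO needs at least %d instruments (J=%d)", PRESSO_MIN_J, hset.j)
        return None
    h = hset.sorted_by_id()
    bx, by, sx, sy = h.beta_x, h.beta_y, h.se_x, h.se_y
    j = h.j
    w = 1.0 / sy**2

    theta_loo = _loo_theta(bx, by, w)
    resid = by - theta_loo * bx
    rss_obs = float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed)
    bxs = bx + sx * rng.standard_normal((n_sim, j))
    bys = theta_loo * bx + sy * rng.standard_normal((n_sim, j))
    theta_loo_sim = _loo_theta(bxs, bys, w)
    resid_sim = bys - theta_loo_sim * bxs
    rss_sim = np.sum(w * resid_sim**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_snp = (1 + np.sum(resid_sim**2 >= resid**2, axis=0)) / (1 + n_sim)
    p_adj = np.minimum(p_snp * j, 1.0)
    outlier_mask = p_adj < outlier_alpha
    outliers = frozenset(str(s) for s in h.snp_id[outlier_mask])
    outlier_p = {str(s): float(p) for s, p in zip(h.snp_id, p_adj)}

    corrected: MREstimate | None = None
    distortion_p: float | None = None
    if outliers:
        keep = ~outlier_mask
        if np.sum(keep) >= 2:
            corrected = ivw(h.subset(keep), model="fixed")
            beta_full, _, _ = _ivw_fixed_core(bx, by, sy)
            d_obs = corrected.beta - beta_full
            m = int(np.sum(outlier_mask))
            # random removal of m SNPs: displacement null distribution
            drop_idx = np.argsort(rng.random((n_sim, j)), axis=1)[:, :m]
            drop_mask = np.zeros((n_sim, j), dtype=bool)
            np.put_along_axis(drop_mask, drop_idx, True, axis=1)
            wk = np.where(drop_mask, 0.0, w)
            beta_sub = np.sum(wk * bx * by, axis=1) / np.sum(wk * bx**2, axis=1)
            d_sim = beta_sub - beta_full
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_sim))
        else:
            logger.warning("MR-PRESSO flagged all but <2 SNPs; no corrected estimate")

    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_p=outlier_p,
        outliers=outliers,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        seed=seed,
    )


def diagnostics_report(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> DiagnosticsReport:
    """Assemble the full sensitivity panel for one harmonized pair."""
    beta_fixed = ivw(hset, model="fixed", alpha=alpha).beta if hset.j >= 1 else None
    q_ivw = cochran_q(hset, beta_fixed) if beta_fixed is not None else None
    q_egger = None
    intercept = None
    if hset.j >= 3:
        fit = egger(hset, alpha=alpha)
        q_egger = rucker_q(hset, fit)
        intercept = (fit.intercept, fit.intercept_se, fit.intercept_pval)
    loo = leave_one_out(hset, alpha=alpha) if hset.j >= 3 else None
    presso = mr_presso(hset, n_sim=n_sim, seed=seed, outlier_alpha=alpha)
    return DiagnosticsReport(
        q_ivw=q_ivw,
        q_egger=q_egger,
        egger_intercept=intercept,
        presso=presso,
        loo=loo,
    )
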