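"""Genetic risk score construction and association testing.

The individual-level score of person i is GRS_i = sum_j beta_j * G_ij, with
G_ij the 0/1/2 effect-allele dose and beta_j the exposure effect of SNP j.
Its association with the outcome is tested by linear regression (continuous
outcome) or logistic regression (binary outcome).

With only summary statistics, weighting each SNP's outcome effect by its
exposure effect collapses algebraically to fixed-effect inverse-variance
weighting; :func:`grs_summary` implements that summary-level score
association together with the score heterogeneity statistic Q_rs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimators import DEFAULT_ALPHA, MREstimate, _finish
from .exceptions import ConvergenceError, EstimationImpossibleError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GRSResult:
    """Summary-level GRS association with its heterogeneity statistic."""

    estimate: MREstimate
    q_rs: float
    q_df: int
    p_het: float


def grs_individual(
    doses: np.ndarray,
    betas: np.ndarray,
    eaf: np.ndarray | None = None,
) -> np.ndarray:
    """Per-individual weighted allele-dose scores.

    ``doses`` is an (n, J) matrix with entries in {0, 1, 2} (NaN = missing);
    missing doses are imputed to 2*eaf when frequencies are supplied,
    otherwise the affected individuals get a NaN score (logged).
    """
    doses = np.asarray(doses, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if doses.ndim != 2 or doses.shape[1] != betas.shape[0]:
        raise ValueError(
            f"dose matrix with {doses.shape} columns does not match {betas.shape[0]} weights"
        )
    finite = np.isnan(doses) | np.isin(doses, (0.0, 1.0, 2.0))
    if not np.all(finite):
        raise ValueError("dose entries must be 0, 1, 2 or missing")
    if np.any(np.isnan(doses)):
        if eaf is not None:
            fill = np.broadcast_to(2.0 * np.asarray(eaf, dtype=float), doses.shape)
            doses = np.where(np.isnan(doses), fill, doses)
            logger.info("imputed missing doses to 2*eaf")
        else:
            n_bad = int(np.sum(np.any(np.isnan(doses), axis=1)))
            logger.warning(
                "%d individual(s) with missing doses and no eaf: scores set to NaN", n_bad
            )
    return doses @ betas


def grs_association(
    scores: np.ndarray,
    outcome: np.ndarray,
    outcome_type: str = "continuous",
    alpha: float = DEFAULT_ALPHA,
) -> MREstimate:
    """Regression of the outcome on the score.

    Continuous outcomes use ordinary least squares; binary outcomes (0/1,
    both classes required) use a maximum-likelihood logistic fit.  The
    reported ``or_`` is exp(slope) in both cases; for a continuous outcome it
    is exp(beta) reported only for table-shape compatibility.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome have different lengths")
    keep = ~np.isnan(scores)
    scores, outcome = scores[keep], outcome[keep]
    if scores.size < 3:
        raise EstimationImpossibleError("fewer than 3 usable individuals")
    if np.ptp(scores) == 0:
        raise ValueError("constant score carries no association information")
    x = sm.add_constant(scores)
    if outcome_type == "continuous":
        res = sm.OLS(outcome, x).fit()
        method = "grs_linear"
    elif outcome_type == "binary":
        classes = np.unique(outcome)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("binary outcome must contain both classes coded 0/1")
        try:
            res = sm.Logit(outcome, x).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation raises inside statsmodels
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError("logistic fit did not converge (possible separation)")
        method = "grs_logistic"
    else:
        raise ValueError(f"unknown outcome_type {outcome_type!r}")
    slope = float(res.params[1])
    se = float(res.bse[1])
    pval = float(res.pvalues[1])
    return _finish(method, scores.size, slope, se, alpha, pval)


def grs_summary(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> GRSResult:
    """Summary-level GRS association from harmonized effect pairs.

    With weights w_j = beta_xj, the score-association estimate is
    alpha_hat = sum(w_j beta_yj / se_yj^2) / sum(w_j^2 / se_yj^2) with
    standard error 1/sqrt(sum(w_j^2 / se_yj^2)) — identical to the
    fixed-effect IVW estimate.  Q_rs is the weighted residual sum of squares
    around the fit (df = J-1).
    """
    j = hset.j
    if j < 2:
        raise EstimationImpossibleError("summary GRS needs at least 2 SNPs")
    w = hset.beta_x
    inv_var = 1.0 / hset.se_y**2
    denom = float(np.sum(w**2 * inv_var))
    alpha_hat = float(np.sum(w * hset.beta_y * inv_var)) / denom
    se = float(np.sqrt(1.0 / denom))
    q_rs = float(np.sum((hset.beta_y - alpha_hat * w) ** 2 * inv_var))
    df = j - 1
    p_het = float(stats.chi2.sf(q_rs, df))
    est = _finish("grs_summary", j, alpha_hat, se, alpha)
    return GRSResult(estimate=est, q_rs=q_rs, q_df=df, p_het=p_het)
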