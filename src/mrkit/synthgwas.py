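"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a two-sample MR analysis
assumes: J independent biallelic instruments with true per-allele exposure
effects gamma_j (oriented so the effect allele increases the exposure, the
usual GWAS instrument convention), optional horizontal-pleiotropy effects
alpha_j on the outcome (balanced around zero or directional around a mean
mu, confined to a configurable invalid fraction), optional gross outliers,
and observed effects drawn from the standardized-trait sampling model

    se_xj = 1/sqrt(2 n_x p_j (1-p_j)),   se_yj = 1/sqrt(2 n_y v p_j (1-p_j))

with v = k(1-k) for a binary outcome with case fraction k.  File-format
artifacts (allele swaps, strand flips, palindromic allele pairs) and
compound-symmetric LD blocks exercise the harmonization and clumping logic.

Default parameters mirror a serum-biomarker exposure GWAS (n = 39,883) and a
binary neurodegenerative-disease outcome GWAS (17,008 cases / 37,154
controls) with ~10 instruments and no true causal effect.

Each seed yields bit-identical output; the truth, the sampling noise, the
allele assignment and the reporting artifacts use separate child streams of
the seed, so e.g. switching artifacts on does not change the underlying
effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .sumstats import LDTable, SumStatRecord, SumStatTable

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)

P_FLOOR = 1e-300  # p-values are reported in (0, 1]


@dataclass
class SimConfig:
    """Generating parameters for a two-sample summary-statistics experiment."""

    J: int = 10
    theta: float = 0.0
    n_x: int = 39_883
    n_y: int = 54_162
    outcome_type: str = "binary"
    case_fraction: float = 0.314
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.15
    pleiotropy: str = "none"  # none | balanced | directional
    tau: float = 0.0
    mu: float = 0.0
    frac_invalid: float = 1.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    frac_palindromic: float = 0.15
    frac_strand_flipped: float = 0.0
    frac_allele_swapped: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be at least 1")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.gamma_sd < 0 or self.tau < 0:
            raise ValueError("gamma_sd and tau must be non-negative")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        for name in ("frac_invalid", "frac_palindromic", "frac_strand_flipped",
                     "frac_allele_swapped"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.n_outliers <= self.J:
            raise ValueError("n_outliers must be between 0 and J")
        if self.ld_blocks is not None:
            if sum(size for size, _ in self.ld_blocks) > self.J:
                raise ValueError("ld_blocks cover more SNPs than J")
            if any(not 0 <= r2 <= 1 for _, r2 in self.ld_blocks):
                raise ValueError("block r2 must be in [0, 1]")


@dataclass
class SimTruth:
    """The generating parameters against which recovery is tested."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    snp_id: list[str]
    outlier_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta,
            "gamma": list(map(float, self.gamma)),
            "alpha": list(map(float, self.alpha)),
            "maf": list(map(float, self.maf)),
            "se_x": list(map(float, self.se_x)),
            "se_y": list(map(float, self.se_y)),
            "snp_id": self.snp_id,
            "outlier_ids": self.outlier_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class SimBatch:
    """Replicate observed effects sharing one truth (vectorized draws)."""

    beta_x: np.ndarray  # (R, J)
    beta_y: np.ndarray  # (R, J)
    se_x: np.ndarray  # (J,)
    se_y: np.ndarray  # (J,)
    truth: SimTruth


def _variance_factor(config: SimConfig) -> float:
    if config.outcome_type == "binary":
        return config.case_fraction * (1.0 - config.case_fraction)
    return 1.0


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    j = config.J
    maf = rng.uniform(*config.maf_range, size=j)
    se_x = 1.0 / np.sqrt(2.0 * config.n_x * maf * (1.0 - maf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_y * _variance_factor(config) * maf * (1.0 - maf))
    # effect alleles oriented to increase the exposure
    gamma = np.abs(rng.normal(0.0, config.gamma_sd, size=j))
    alpha = np.zeros(j)
    if config.pleiotropy != "none":
        invalid = rng.random(j) < config.frac_invalid
        center = config.mu if config.pleiotropy == "directional" else 0.0
        draws = rng.normal(center, config.tau, size=j)
        alpha = np.where(invalid, draws, 0.0)
    snp_id = [f"rs{i + 1:06d}" for i in range(j)]
    outlier_ids: list[str] = []
    if config.n_outliers > 0:
        idx = rng.choice(j, size=config.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_outliers)
        alpha[idx] = config.outlier_scale * se_y[idx] * signs
        outlier_ids = sorted(snp_id[i] for i in idx)
    return SimTruth(
        theta=config.theta, gamma=gamma, alpha=alpha, maf=maf,
        se_x=se_x, se_y=se_y, snp_id=snp_id, outlier_ids=outlier_ids,
    )


def _positions(config: SimConfig) -> tuple[list[str], list[int]]:
    """Chromosome/position layout: LD-block members adjacent, others far apart."""
    chroms: list[str] = []
    positions: list[int] = []
    cursor = 1_000_000
    i = 0
    for size, _ in config.ld_blocks or []:
        for k in range(size):
            chroms.append("1")
            positions.append(cursor + k * 5_000)
            i += 1
        cursor += 50_000_000
    while i < config.J:
        chroms.append("1")
        positions.append(cursor)
        cursor += 50_000_000
        i += 1
    return chroms, positions


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), P_FLOOR)


def simulate_two_sample(
    config: SimConfig,
) -> tuple[SumStatTable, SumStatTable, SimTruth, LDTable]:
    """One exposure table, one outcome table, the generating truth, and LD.

    Deterministic given ``config.seed``.  The exposure is continuous; the
    outcome trait type follows the config.  The LD table contains the
    configured within-block r2 entries (0 between blocks by omission).
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(5)]
    rng_truth, rng_x, rng_y, rng_alleles, rng_artifacts = streams

    truth = _draw_truth(config, rng_truth)
    j = config.J
    beta_x = rng_x.normal(truth.gamma, truth.se_x)
    beta_y = rng_y.normal(config.theta * truth.gamma + truth.alpha, truth.se_y)

    pal_mask = rng_alleles.random(j) < config.frac_palindromic
    pal_choice = rng_alleles.integers(0, 4, size=j)
    non_choice = rng_alleles.integers(0, 8, size=j)
    pairs = [
        _PALINDROMIC_PAIRS[pal_choice[i]] if pal_mask[i] else _NONPALINDROMIC_PAIRS[non_choice[i]]
        for i in range(j)
    ]

    swap_mask = rng_artifacts.random(j) < config.frac_allele_swapped
    flip_mask = rng_artifacts.random(j) < config.frac_strand_flipped

    chroms, positions = _positions(config)
    px = _pvals(beta_x, truth.se_x)
    py = _pvals(beta_y, truth.se_y)

    from .harmonize import complement_allele  # local import avoids a cycle

    exp_records = []
    out_records = []
    for i in range(j):
        ea, oa = pairs[i]
        exp_records.append(
            SumStatRecord(
                snp_id=truth.snp_id[i], chrom=chroms[i], pos=positions[i],
                effect_allele=ea, other_allele=oa, eaf=float(truth.maf[i]),
                beta=float(beta_x[i]), se=float(truth.se_x[i]),
                pval=float(px[i]), n=config.n_x,
            )
        )
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(beta_y[i]), float(truth.maf[i])
        if swap_mask[i]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if flip_mask[i]:
            o_ea, o_oa = complement_allele(o_ea), complement_allele(o_oa)
        out_records.append(
            SumStatRecord(
                snp_id=truth.snp_id[i], chrom=chroms[i], pos=positions[i],
                effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
                beta=o_beta, se=float(truth.se_y[i]),
                pval=float(py[i]), n=config.n_y,
            )
        )

    n_cases = n_controls = None
    if config.outcome_type == "binary":
        n_cases = int(round(config.n_y * config.case_fraction))
        n_controls = config.n_y - n_cases
    exposure = SumStatTable(exp_records, trait_label="exposure", trait_type="continuous")
    outcome = SumStatTable(
        out_records, trait_label="outcome", trait_type=config.outcome_type,
        n_cases=n_cases, n_controls=n_controls,
    )

    ld = LDTable()
    start = 0
    for size, r2 in config.ld_blocks or []:
        for a in range(start, start + size):
            for b in range(a + 1, start + size):
                ld.set(truth.snp_id[a], truth.snp_id[b], r2)
        start += size
    return exposure, outcome, truth, ld


def replicate_summary_stats(
    config: SimConfig, n_reps: int, seed: int | None = None
) -> SimBatch:
    """Truth drawn once, ``n_reps`` independent observation layers (vectorized).

    The truth stream is the same one :func:`simulate_two_sample` uses for the
    same config, so batch studies and single-table runs share conditions.
    """
    truth_stream, default_obs_stream = np.random.SeedSequence(config.seed).spawn(5)[:2]
    rng_truth = np.random.default_rng(truth_stream)
    obs_stream = default_obs_stream if seed is None else np.random.SeedSequence(seed)
    rng_obs = np.random.default_rng(obs_stream)
    truth = _draw_truth(config, rng_truth)
    beta_x = truth.gamma + truth.se_x * rng_obs.standard_normal((n_reps, config.J))
    mean_y = config.theta * truth.gamma + truth.alpha
    beta_y = mean_y + truth.se_y * rng_obs.standard_normal((n_reps, config.J))
    return SimBatch(beta_x=beta_x, beta_y=beta_y, se_x=truth.se_x, se_y=truth.se_y, truth=truth)


def realized_r2_xz(truth: SimTruth) -> float:
    """Exposure variance explained by the instruments under the generating model."""
    return float(np.sum(2.0 * truth.maf * (1.0 - truth.maf) * truth.gamma**2))


def simulate_individual(
    config: SimConfig, n_individuals: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SimTruth]:
    """Individual-level doses, exposure and outcome consistent with the model.

    Doses are Binomial(2, maf); the exposure is the genetic value plus noise
    scaled so the trait has roughly unit variance; the outcome is linear in
    the exposure plus direct pleiotropic paths (continuous), or Bernoulli
    through the logit of the same predictor with the intercept placed to hit
    the configured case fraction.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)]
    rng_truth, rng_geno, rng_noise = streams
    truth = _draw_truth(config, rng_truth)
    doses = rng_geno.binomial(2, truth.maf, size=(n_individuals, config.J)).astype(float)
    genetic = doses @ truth.gamma
    var_explained = realized_r2_xz(truth)
    sd_e = np.sqrt(max(1.0 - var_explained, 0.1))
    exposure = genetic + rng_noise.normal(0.0, sd_e, size=n_individuals)
    predictor = config.theta * exposure + doses @ truth.alpha
    if config.outcome_type == "continuous":
        outcome = predictor + rng_noise.normal(0.0, 1.0, size=n_individuals)
    else:
        k = config.case_fraction
        intercept = np.log(k / (1.0 - k)) - float(np.mean(predictor))
        prob = 1.0 / (1.0 + np.exp(-(intercept + predictor)))
        outcome = rng_noise.binomial(1, prob).astype(float)
    return doses, exposure, outcome, truth
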