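"""Config-driven orchestration of the full bidirectional MR analysis.

``run`` executes, per direction and outcome: genome-wide instrument
selection, LD clumping, exclusion-list screening, an optional proxy pass for
instruments missing from the outcome, harmonization, the three causal
estimators, the sensitivity panel (Cochran/Ruecker Q, Egger intercept,
leave-one-out, MR-PRESSO), and the summary-level GRS association.  The
reverse direction re-selects instruments from the former outcome's own
summary statistics; forward instruments are never reused.

Outputs are tab-separated report tables (estimates, diagnostics, GRS,
forest-plot-ready rows, selection and harmonization audits) plus one JSON
report holding every number at full precision.  Everything stochastic is
seeded from the run seed, so a rerun with the same config is byte-identical.

Significance is flagged at p < 0.05 throughout; no multiple-testing
correction is applied across outcomes (stated in the report header as a
caveat).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import DiagnosticsReport, diagnostics_report
from .estimators import MREstimate, egger, ivw, weighted_median
from .exceptions import ConfigError, EstimationImpossibleError
from .grs import grs_summary
from .harmonize import harmonize
from .instruments import (
    clump,
    exclude_listed,
    find_proxy,
    instrument_strength,
    read_exclusion_list,
    select_genomewide,
)
from .sumstats import LDTable, SumStatTable, read_ld, read_sumstats

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class DatasetSpec:
    path: str
    trait_label: str
    trait_type: str = "continuous"
    column_map: dict[str, str] | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def load(self) -> SumStatTable:
        return read_sumstats(
            self.path,
            column_map=self.column_map,
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


@dataclass
class RunConfig:
    exposure: DatasetSpec
    outcomes: list[DatasetSpec]
    ld_path: str | None = None
    exclusion_path: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_min_r2: float = 0.9
    palindrome_policy: str = "drop"
    n_boot: int = 1000
    n_sim: int = 1000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    direction: str = "forward"  # forward | reverse | both

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        for name, lo, hi in (
            ("p_threshold", 0, 1), ("clump_r2", 0, 1),
            ("proxy_min_r2", 0, 1), ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigError(f"{name} must be in ({lo}, {hi}], got {v}")
        for spec in (self.exposure, *self.outcomes):
            if not Path(spec.path).exists():
                raise ConfigError(f"summary-statistics file not found: {spec.path}")
        for p in (self.ld_path, self.exclusion_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        exposure = DatasetSpec(**raw.pop("exposure"))
        outcomes = [DatasetSpec(**o) for o in raw.pop("outcomes")]
        return cls(exposure=exposure, outcomes=outcomes, **raw)


@dataclass
class RunReport:
    """All results of one run, JSON-serializable via ``to_dict``."""

    config_summary: dict[str, Any]
    pairs: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {"config": self.config_summary, "pairs": self.pairs}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            for est in pair.get("estimates", []):
                rows.append(
                    {
                        "exposure": pair["exposure"],
                        "outcome": pair["outcome"],
                        "n_snp": est["n_snp"],
                        "method": est["method"],
                        "or": est["or"],
                        "ci_low": est["ci_low"],
                        "ci_high": est["ci_high"],
                        "pval": est["pval"],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["exposure", "outcome", "n_snp", "method", "or", "ci_low", "ci_high", "pval"],
        )

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            diag = pair.get("diagnostics")
            if not diag:
                continue
            rows.append(
                {
                    "exposure": pair["exposure"],
                    "outcome": pair["outcome"],
                    "presso_global_p": (diag.get("presso") or {}).get("global_p"),
                    "q_ivw": (diag.get("q_ivw") or {}).get("q"),
                    "q_ivw_p": (diag.get("q_ivw") or {}).get("p"),
                    "q_egger": (diag.get("q_egger") or {}).get("q"),
                    "q_egger_p": (diag.get("q_egger") or {}).get("p"),
                    "egger_intercept": (diag.get("egger_intercept") or {}).get("value"),
                    "egger_intercept_se": (diag.get("egger_intercept") or {}).get("se"),
                    "egger_intercept_p": (diag.get("egger_intercept") or {}).get("p"),
                }
            )
        return pd.DataFrame(rows)

    def grs_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            g = pair.get("grs")
            if not g:
                continue
            rows.append(
                {
                    "exposure": pair["exposure"],
                    "outcome": pair["outcome"],
                    "or": g["or"],
                    "ci_low": g["ci_low"],
                    "ci_high": g["ci_high"],
                    "pval": g["pval"],
                    "q_rs": g["q_rs"],
                    "p_het": g["p_het"],
                }
            )
        return pd.DataFrame(rows)

    def forest_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            for est in pair.get("estimates", []):
                rows.append(
                    {
                        "trait": f"{pair['exposure']} -> {pair['outcome']}",
                        "method": est["method"],
                        "beta": est["beta"],
                        "ci_low": est["ci_low"],
                        "ci_high": est["ci_high"],
                        "pval": est["pval"],
                    }
                )
        return forest_table(rows)


def forest_table(rows: list[dict[str, Any]]) -> pd.DataFrame:
    """Plot-ready forest table with a strict p < 0.05 significance flag."""
    cols = ["trait", "method", "beta", "ci_low", "ci_high", "pval", "significant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["significant"] = df["pval"] < SIGNIFICANCE_LEVEL
    return df[cols]


def _est_dict(est: MREstimate) -> dict[str, Any]:
    return {
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "pval": est.pval,
        "or": est.or_,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }


def _diag_dict(diag: DiagnosticsReport) -> dict[str, Any]:
    out: dict[str, Any] = {}
    out["q_ivw"] = (
        None if diag.q_ivw is None
        else {"q": diag.q_ivw.q, "df": diag.q_ivw.df, "p": diag.q_ivw.p}
    )
    out["q_egger"] = (
        None if diag.q_egger is None
        else {"q": diag.q_egger.q, "df": diag.q_egger.df, "p": diag.q_egger.p}
    )
    out["egger_intercept"] = (
        None if diag.egger_intercept is None
        else dict(zip(("value", "se", "p"), diag.egger_intercept))
    )
    if diag.presso is None:
        out["presso"] = None
    else:
        p = diag.presso
        out["presso"] = {
            "global_rss_obs": p.global_rss_obs,
            "global_p": p.global_p,
            "n_sim": p.n_sim,
            "outlier_p": dict(sorted(p.outlier_p.items())),
            "outliers": sorted(p.outliers),
            "corrected_estimate": (
                None if p.corrected_estimate is None else _est_dict(p.corrected_estimate)
            ),
            "distortion_p": p.distortion_p,
            "seed": p.seed,
        }
    if diag.loo is None:
        out["leave_one_out"] = None
    else:
        out["leave_one_out"] = {
            "full": _est_dict(diag.loo.full),
            "entries": [
                {"left_out": snp, "estimate": None if est is None else _est_dict(est)}
                for snp, est in diag.loo.entries
            ],
        }
    return out


def _analyse_pair(
    exposure: SumStatTable,
    outcome: SumStatTable,
    ld: LDTable,
    exclusion: dict[str, str],
    cfg: RunConfig,
    seed: int,
) -> dict[str, Any]:
    result: dict[str, Any] = {
        "exposure": exposure.trait_label,
        "outcome": outcome.trait_label,
        "seed": seed,
    }
    selection: dict[str, Any] = {"input": len(exposure)}
    sel = select_genomewide(exposure, cfg.p_threshold)
    selection["post_threshold"] = len(sel)
    clumped, clog = clump(sel, ld, cfg.clump_r2, cfg.clump_window_kb)
    selection["post_clump"] = len(clumped)
    screened, elog = exclude_listed(clumped, exclusion)
    selection["post_exclusion"] = len(screened)
    selection["removals"] = [list(r) for r in (*clog.removals, *elog.removals)]

    # proxy pass for instruments absent from the outcome
    proxies: list[dict[str, str]] = []
    final_records = []
    chosen = set(screened.snp_ids)
    candidates = exposure.subset([s for s in exposure.snp_ids if s in outcome])
    for rec in screened:
        if rec.snp_id in outcome:
            final_records.append(rec)
            continue
        proxy_id = find_proxy(rec.snp_id, candidates, ld, cfg.proxy_min_r2)
        if proxy_id is not None and proxy_id not in chosen:
            final_records.append(exposure.get(proxy_id))
            chosen.add(proxy_id)
            proxies.append({"missing": rec.snp_id, "proxy": proxy_id})
            logger.info("proxy %s substituted for missing %s", proxy_id, rec.snp_id)
        else:
            logger.info("no proxy found for missing instrument %s", rec.snp_id)
    instruments_table = exposure.with_records(final_records)
    selection["post_proxy"] = len(instruments_table)
    result["selection"] = selection
    result["proxies"] = proxies
    result["instrument_strength"] = {
        rec.snp_id: dict(zip(("f_stat", "r2"), instrument_strength(rec, rec.n)))
        for rec in instruments_table
        if rec.n is not None and rec.n > 2
    }

    try:
        hset = harmonize(instruments_table, outcome, cfg.palindrome_policy)
    except EstimationImpossibleError as exc:
        result["error"] = str(exc)
        return result
    result["harmonization"] = [list(a) for a in hset.actions]
    result["n_snp"] = hset.j

    estimates: list[dict[str, Any]] = []
    try:
        estimates.append(_est_dict(ivw(hset, alpha=cfg.alpha)))
    except EstimationImpossibleError as exc:
        result.setdefault("estimator_errors", []).append(f"ivw: {exc}")
    try:
        estimates.append(
            _est_dict(weighted_median(hset, n_boot=cfg.n_boot, seed=seed, alpha=cfg.alpha))
        )
    except EstimationImpossibleError as exc:
        result.setdefault("estimator_errors", []).append(f"weighted_median: {exc}")
    try:
        fit = egger(hset, alpha=cfg.alpha)
        estimates.append(_est_dict(fit.slope))
    except EstimationImpossibleError as exc:
        result.setdefault("estimator_errors", []).append(f"egger: {exc}")
    result["estimates"] = estimates

    result["diagnostics"] = _diag_dict(
        diagnostics_report(hset, n_sim=cfg.n_sim, seed=seed, alpha=cfg.alpha)
    )
    try:
        g = grs_summary(hset, alpha=cfg.alpha)
        result["grs"] = {**_est_dict(g.estimate), "q_rs": g.q_rs, "q_df": g.q_df, "p_het": g.p_het}
    except EstimationImpossibleError as exc:
        result.setdefault("estimator_errors", []).append(f"grs_summary: {exc}")
    return result


def _round_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Human-readable rounding: 3 decimals, p-values to 3 significant figures."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if col.endswith(("pval", "_p", "p_het")) or col == "pval":
            out[col] = out[col].map(
                lambda v: float(f"{v:.3g}") if pd.notna(v) else v
            )
        else:
            out[col] = out[col].round(3)
    return out


def run(config: RunConfig) -> RunReport:
    """Execute the configured analysis and (optionally) write all reports."""
    exposure = config.exposure.load()
    outcomes = [spec.load() for spec in config.outcomes]
    ld = read_ld(config.ld_path) if config.ld_path else LDTable()
    exclusion = read_exclusion_list(config.exclusion_path) if config.exclusion_path else {}

    directions = {"forward": ["forward"], "reverse": ["reverse"], "both": ["forward", "reverse"]}[
        config.direction
    ]
    n_pairs = len(outcomes) * len(directions)
    pair_seeds = [
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(n_pairs) % (2**31)
    ]

    report = RunReport(
        config_summary={
            "version": __version__,
            "seed": config.seed,
            "direction": config.direction,
            "p_threshold": config.p_threshold,
            "clump_r2": config.clump_r2,
            "clump_window_kb": config.clump_window_kb,
            "proxy_min_r2": config.proxy_min_r2,
            "palindrome_policy": config.palindrome_policy,
            "n_boot": config.n_boot,
            "n_sim": config.n_sim,
            "alpha": config.alpha,
            "note": "p < 0.05 flagged significant; no multiple-testing correction across outcomes",
        }
    )

    k = 0
    for outcome in outcomes:
        for direction in directions:
            exp_t, out_t = (exposure, outcome) if direction == "forward" else (outcome, exposure)
            logger.info(
                "analysing %s -> %s (%s)", exp_t.trait_label, out_t.trait_label, direction
            )
            pair = _analyse_pair(exp_t, out_t, ld, exclusion, config, pair_seeds[k])
            pair["direction"] = direction
            report.pairs.append(pair)
            k += 1

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        _round_frame(report.estimates_frame()).to_csv(out / "estimates.tsv", sep="\t", index=False)
        _round_frame(report.diagnostics_frame()).to_csv(
            out / "diagnostics.tsv", sep="\t", index=False
        )
        _round_frame(report.grs_frame()).to_csv(out / "grs.tsv", sep="\t", index=False)
        _round_frame(report.forest_frame()).to_csv(out / "forest.tsv", sep="\t", index=False)
    return report
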