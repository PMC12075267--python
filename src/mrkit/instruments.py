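"""Selection of independent, strong, confounder-screened instrumental variables.

The pipeline is: genome-wide significance filter (p < 5e-8), greedy LD
clumping (PLINK-style: r-squared threshold 0.001 within a 10,000 kb window),
removal of SNPs on a user-supplied confounder/pleiotropy exclusion list, and
per-SNP instrument-strength measures (F-statistic and variance explained).
Confounder screening is an offline exclusion list rather than a live database
query, so runs are reproducible without network access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ConfigError
from .sumstats import LDTable, SumStatRecord, SumStatTable

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000.0
DEFAULT_PROXY_MIN_R2 = 0.9


@dataclass
class InstrumentSelectionLog:
    """Counts at each filter stage plus per-SNP removal reasons."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    removals: list[tuple[str, str]] = field(default_factory=list)

    def record_stage(self, stage: str, count: int) -> None:
        self.stage_counts[stage] = count

    def record_removal(self, snp_id: str, reason: str) -> None:
        self.removals.append((snp_id, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removals, columns=["snp_id", "reason"])


def select_genomewide(
    table: SumStatTable, p_threshold: float = DEFAULT_P_THRESHOLD
) -> SumStatTable:
    """Keep records with ``pval`` strictly below ``p_threshold`` (order preserved)."""
    out = table.with_records([r for r in table.records if r.pval < p_threshold])
    if len(out) == 0:
        logger.warning(
            "no SNP in %s passes p < %.3g", table.trait_label, p_threshold
        )
    return out


def _within_window(a: SumStatRecord, b: SumStatRecord, window_kb: float) -> bool:
    """Distance check for clumping; SNPs lacking chrom/pos count as independent."""
    if a.chrom is None or b.chrom is None or a.chrom != b.chrom:
        return False
    if a.pos is None or b.pos is None:
        logger.warning(
            "clump: missing position for %s or %s; treating pair as independent",
            a.snp_id,
            b.snp_id,
        )
        return False
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def clump(
    table: SumStatTable,
    ld: LDTable,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> tuple[SumStatTable, InstrumentSelectionLog]:
    """Greedy LD clumping of a summary-statistics table.

    Candidates are visited in (pval, snp_id) order; each accepted index SNP
    discards every remaining SNP on the same chromosome within ``window_kb``
    of it whose r-squared with it exceeds ``r2_threshold``.  The retained set
    is pairwise independent under this rule and invariant to input row order.
    """
    log = InstrumentSelectionLog()
    log.record_stage("input", len(table))
    remaining = sorted(table.records, key=lambda r: (r.pval, r.snp_id))
    kept: list[SumStatRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for rec in remaining:
            if (
                _within_window(index, rec, window_kb)
                and ld.r2(index.snp_id, rec.snp_id) > r2_threshold
            ):
                log.record_removal(
                    rec.snp_id,
                    f"clumped: r2={ld.r2(index.snp_id, rec.snp_id):g} with index {index.snp_id}",
                )
            else:
                survivors.append(rec)
        remaining = survivors
    log.record_stage("post-clump", len(kept))
    return table.with_records(kept), log


def find_proxy(
    snp_id: str,
    candidates: SumStatTable,
    ld: LDTable,
    min_r2: float = DEFAULT_PROXY_MIN_R2,
) -> str | None:
    """Best proxy for a missing SNP: the candidate with maximal r2, if r2 > min_r2.

    Ties on r2 break toward the lexicographically smallest id; the SNP itself
    is never its own proxy.  Returns ``None`` when no candidate qualifies.
    """
    best: tuple[float, str] | None = None
    for rec in candidates:
        if rec.snp_id == snp_id:
            continue
        r2 = ld.r2(snp_id, rec.snp_id)
        if r2 <= min_r2:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and rec.snp_id < best[1]):
            best = (r2, rec.snp_id)
    return None if best is None else best[1]


def instrument_strength(record: SumStatRecord, n: float) -> tuple[float, float]:
    """Per-SNP F-statistic and variance explained.

    F = (beta/se)^2; variance explained uses the F-based identity
    r2 = F/(F + n - 2), which needs no allele frequency.  When ``eaf`` is
    available the frequency-based 2*beta^2*p*(1-p) value is also logged for
    comparison (it assumes a variance-standardized trait).
    """
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    f_stat = (record.beta / record.se) ** 2
    r2 = f_stat / (f_stat + n - 2)
    if record.eaf is not None:
        r2_freq = 2.0 * record.beta**2 * record.eaf * (1.0 - record.eaf)
        logger.info(
            "%s: r2(F)=%.4g, r2(2b^2p(1-p))=%.4g", record.snp_id, r2, r2_freq
        )
    return f_stat, r2


def read_exclusion_list(path) -> dict[str, str]:
    """Read a tab-separated snp_id/reason exclusion file into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ConfigError(f"exclusion file {path} is empty")
    snp_col = df.columns[0]
    reason_col = df.columns[1] if df.shape[1] > 1 else None
    out: dict[str, str] = {}
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        out[str(rowd[snp_col])] = (
            str(rowd[reason_col]) if reason_col else "listed for exclusion"
        )
    return out


def exclude_listed(
    table: SumStatTable,
    exclusion: Mapping[str, str] | Iterable[str],
) -> tuple[SumStatTable, InstrumentSelectionLog]:
    """Remove listed SNPs (e.g. known pleiotropic loci), logging each reason."""
    if not isinstance(exclusion, Mapping):
        exclusion = {s: "listed for exclusion" for s in exclusion}
    log = InstrumentSelectionLog()
    log.record_stage("input", len(table))
    kept = []
    present = set(table.snp_ids)
    for snp_id in exclusion:
        if snp_id not in present:
            logger.warning("exclusion list names absent SNP %s", snp_id)
    for rec in table.records:
        if rec.snp_id in exclusion:
            log.record_removal(rec.snp_id, exclusion[rec.snp_id])
        else:
            kept.append(rec)
    log.record_stage("post-exclusion", len(kept))
    return table.with_records(kept), log
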