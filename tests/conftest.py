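"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats import LDTable, SumStatRecord, SumStatTable

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_hset(rng: np.random.Generator, j: int = 8, theta: float = 0.0) -> HarmonizedSet:
    """A random valid harmonized set with nonzero exposure effects."""
    beta_x = rng.normal(0.12, 0.04, j)
    beta_x = np.where(np.abs(beta_x) < 1e-3, 0.05, beta_x)
    se_x = rng.uniform(0.004, 0.02, j)
    se_y = rng.uniform(0.004, 0.02, j)
    beta_y = theta * beta_x + rng.normal(0.0, 0.02, j)
    return HarmonizedSet(
        snp_id=np.array([f"rs{i + 1:04d}" for i in range(j)], dtype=object),
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        eaf=rng.uniform(0.1, 0.9, j),
    )


def make_record(snp_id: str = "rs1", **kw) -> SumStatRecord:
    defaults = dict(
        snp_id=snp_id,
        effect_allele="A",
        other_allele="G",
        beta=0.1,
        se=0.01,
        pval=1e-9,
        chrom="1",
        pos=1_000_000,
        eaf=0.3,
        n=10_000,
    )
    defaults.update(kw)
    return SumStatRecord(**defaults)


def random_clump_instance(
    rng: np.random.Generator, j: int
) -> tuple[SumStatTable, LDTable]:
    """A random table + LD pattern exercising every branch of the clump rule."""
    records = []
    for i in range(j):
        records.append(
            make_record(
                snp_id=f"rs{i + 1:03d}",
                chrom=str(rng.integers(1, 3)),
                pos=int(rng.integers(0, 20_000_000)),
                pval=float(10.0 ** -rng.uniform(1, 12)),
            )
        )
    ld = LDTable()
    for a in range(j):
        for b in range(a + 1, j):
            if rng.random() < 0.5:
                ld.set(records[a].snp_id, records[b].snp_id, float(rng.random()))
    return SumStatTable(records), ld


def per_snp_gwas(doses, trait):
    """Marginal per-SNP regressions of a trait on each dose column.

    Returns (beta, se) arrays — the summary statistics an individual-level
    cohort would contribute.
    """
    import numpy as np

    n = len(trait)
    g_c = doses - doses.mean(axis=0)
    t_c = (trait - trait.mean())[:, None]
    var_g = np.sum(g_c**2, axis=0)
    beta = np.sum(g_c * t_c, axis=0) / var_g
    resid = t_c - g_c * beta
    se = np.sqrt(np.sum(resid**2, axis=0) / (n - 2) / var_g)
    return beta, se


def greedy_clump_reference(records, ld, r2_threshold: float, window_kb: float) -> list[str]:
    """Independent straight-line implementation of the greedy clump rule."""
    remaining = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept = []
    while remaining:
        index = remaining[0]
        kept.append(index.snp_id)
        survivors = []
        for rec in remaining[1:]:
            near = (
                index.chrom is not None
                and rec.chrom == index.chrom
                and index.pos is not None
                and rec.pos is not None
                and abs(index.pos - rec.pos) <= window_kb * 1000
            )
            if near and ld.r2(index.snp_id, rec.snp_id) > r2_threshold:
                continue
            survivors.append(rec)
        remaining = survivors
    return kept
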