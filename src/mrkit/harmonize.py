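"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS report the same SNP on arbitrary effect alleles and strands.  Before
any ratio estimate the outcome effects must be expressed per copy of the
exposure's effect allele: swapped allele pairs flip the sign of the outcome
beta, strand-complemented reports are complemented back, and palindromic
SNPs (A/T or C/G), whose strand cannot be resolved from the alleles alone,
are dropped by default.  An optional frequency rescue keeps palindromic SNPs
whose effect-allele frequencies are far enough from 0.5 on both sides to
orient the strand.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EstimationImpossibleError
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: action labels used in the harmonization audit log
KEPT = "kept"
SIGN_FLIPPED = "sign-flipped"
STRAND_COMPLEMENTED = "strand-complemented"
DROPPED_PALINDROMIC = "dropped:palindromic"
DROPPED_MISMATCH = "dropped:mismatch"
DROPPED_MISSING = "dropped:missing"

DEFAULT_EAF_RESCUE_THRESHOLD = 0.08


def complement_allele(a: str) -> str:
    """Watson-Crick complement of a single-base allele."""
    try:
        return COMPLEMENT[a]
    except KeyError:
        raise ValueError(f"not a valid allele: {a!r}") from None


def is_palindromic(ea: str, oa: str) -> bool:
    """True iff the unordered allele pair is A/T or C/G."""
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effect pairs consumed by all estimators."""

    snp_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray  # exposure effect-allele frequency; NaN where unknown
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    actions: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {
            len(v)
            for v in (self.snp_id, self.beta_x, self.se_x, self.beta_y, self.se_y, self.eaf)
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors have unequal lengths")
        if self.j and (np.any(self.se_x <= 0) or np.any(self.se_y <= 0)):
            raise ValueError("nonpositive standard error in harmonized set")

    @property
    def j(self) -> int:
        """Number of harmonized instruments."""
        return len(self.snp_id)

    def subset(self, index) -> "HarmonizedSet":
        index = np.asarray(index)
        return HarmonizedSet(
            snp_id=self.snp_id[index],
            beta_x=self.beta_x[index],
            se_x=self.se_x[index],
            beta_y=self.beta_y[index],
            se_y=self.se_y[index],
            eaf=self.eaf[index],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    def sorted_by_id(self) -> "HarmonizedSet":
        return self.subset(np.argsort(self.snp_id.astype(str)))

    def write_audit(self, path) -> None:
        """Tab-separated audit of per-SNP harmonization actions."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("snp_id\taction\tdetail\n")
            for snp_id, action, detail in self.actions:
                fh.write(f"{snp_id}\t{action}\t{detail}\n")


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindrome_policy: str = "drop",
    eaf_rescue_threshold: float = DEFAULT_EAF_RESCUE_THRESHOLD,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    For each exposure SNP: missing from the outcome -> dropped (proxy
    substitution is a caller-side pre-pass); same orientation -> kept; alleles
    swapped -> outcome beta negated; matching only after strand
    complementing -> complemented (and possibly also sign-flipped);
    palindromic -> dropped under the default policy, or frequency-oriented
    under ``palindrome_policy="frequency_rescue"``; anything else -> dropped
    as a mismatch.  Raises when no SNP survives.
    """
    if palindrome_policy not in ("drop", "frequency_rescue"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    actions: list[tuple[str, str, str]] = []
    kept_rows: list[tuple[str, float, float, float, float, float]] = []

    for exp in exposure:
        out = outcome.get(exp.snp_id)
        if out is None:
            actions.append((exp.snp_id, DROPPED_MISSING, "absent from outcome"))
            continue

        ea, oa = exp.effect_allele, exp.other_allele
        if is_palindromic(ea, oa):
            if {out.effect_allele, out.other_allele} != {ea, oa}:
                actions.append(
                    (exp.snp_id, DROPPED_MISMATCH,
                     f"{ea}/{oa} vs {out.effect_allele}/{out.other_allele}")
                )
                continue
            if palindrome_policy == "drop":
                actions.append((exp.snp_id, DROPPED_PALINDROMIC, f"{ea}/{oa}"))
                continue
            # frequency rescue: orient the strand from the allele frequencies
            beta_y = out.beta
            eaf_y = out.eaf
            if out.effect_allele != ea:  # textual swap first
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
            if (
                exp.eaf is None
                or eaf_y is None
                or abs(exp.eaf - 0.5) <= eaf_rescue_threshold
                or abs(eaf_y - 0.5) <= eaf_rescue_threshold
            ):
                actions.append(
                    (exp.snp_id, DROPPED_PALINDROMIC, "frequency too close to 0.5 or missing")
                )
                continue
            if (exp.eaf < 0.5) != (eaf_y < 0.5):
                beta_y = -beta_y
                actions.append(
                    (exp.snp_id, KEPT, "palindromic, frequency-oriented with strand flip")
                )
            else:
                actions.append((exp.snp_id, KEPT, "palindromic, frequency-oriented"))
            kept_rows.append(
                (exp.snp_id, exp.beta, exp.se, beta_y, out.se,
                 np.nan if exp.eaf is None else exp.eaf)
            )
            continue

        pair = (out.effect_allele, out.other_allele)
        cpair = (complement_allele(out.effect_allele), complement_allele(out.other_allele))
        if pair == (ea, oa):
            beta_y = out.beta
            actions.append((exp.snp_id, KEPT, "same orientation"))
        elif pair == (oa, ea):
            beta_y = -out.beta
            actions.append((exp.snp_id, SIGN_FLIPPED, "alleles swapped; outcome beta negated"))
        elif cpair == (ea, oa):
            beta_y = out.beta
            actions.append((exp.snp_id, STRAND_COMPLEMENTED, "opposite strand"))
        elif cpair == (oa, ea):
            beta_y = -out.beta
            actions.append(
                (exp.snp_id, STRAND_COMPLEMENTED, "opposite strand and swapped; beta negated")
            )
        else:
            actions.append(
                (exp.snp_id, DROPPED_MISMATCH,
                 f"{ea}/{oa} vs {out.effect_allele}/{out.other_allele}")
            )
            continue
        kept_rows.append(
            (exp.snp_id, exp.beta, exp.se, beta_y, out.se,
             np.nan if exp.eaf is None else exp.eaf)
        )

    if not kept_rows:
        drops = Counter(a for _, a, _ in actions)
        top, n_top = drops.most_common(1)[0] if drops else ("none", 0)
        raise EstimationImpossibleError(
            f"no SNP survived harmonization (largest drop category: {top}, n={n_top})"
        )

    ids, bx, sx, by, sy, eaf = zip(*kept_rows)
    hset = HarmonizedSet(
        snp_id=np.array(ids, dtype=object),
        beta_x=np.array(bx),
        se_x=np.array(sx),
        beta_y=np.array(by),
        se_y=np.array(sy),
        eaf=np.array(eaf),
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        actions=actions,
    )
    logger.info(
        "harmonized %d/%d SNPs (%s -> %s)",
        hset.j, len(exposure), exposure.trait_label, outcome.trait_label,
    )
    return hset
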