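"""Data model and file I/O for GWAS summary statistics and pairwise-LD tables.

The canonical internal column vocabulary is ``snp_id``, ``chrom``, ``pos``,
``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``.
GWAS files have no single standard header, so :func:`read_sumstats` takes a
``column_map`` translating the canonical names to whatever dialect the file
uses.  Files are tab-separated with a header row, one variant per line; missing
optional values are written as ``NA`` and accepted as ``NA``, ``""`` or ``.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import ConfigError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
NA_TOKENS = frozenset({"NA", "", ".", "nan", "NaN"})
NA_OUT = "NA"

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class SumStatRecord:
    """One GWAS association: per-allele effect of a biallelic SNP on a trait.

    ``beta`` is the per-effect-allele effect (log odds ratio for binary
    traits), ``se`` its standard error, ``pval`` the association p-value.
    ``eaf`` is the effect-allele frequency; ``chrom``/``pos``/``n`` are
    optional annotations.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele are identical")
        if not self.se > 0:
            raise ValueError("nonpositive se")
        if not 0 < self.pval <= 1:
            raise ValueError("pval outside (0, 1]")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError("eaf outside (0, 1)")
        if self.pos is not None:
            object.__setattr__(self, "pos", int(self.pos))

    def flipped(self) -> "SumStatRecord":
        """The same association reported on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


class SumStatTable:
    """An ordered collection of :class:`SumStatRecord` with unique SNP ids."""

    def __init__(
        self,
        records: Iterable[SumStatRecord],
        trait_label: str = "trait",
        trait_type: str = "continuous",
        n_cases: int | None = None,
        n_controls: int | None = None,
    ) -> None:
        if trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous or binary, got {trait_type!r}")
        self.records: list[SumStatRecord] = list(records)
        self.trait_label = trait_label
        self.trait_type = trait_type
        self.n_cases = n_cases
        self.n_controls = n_controls
        self._index: dict[str, SumStatRecord] = {}
        for rec in self.records:
            if rec.snp_id in self._index:
                raise ValueError(f"duplicate snp_id {rec.snp_id!r}")
            self._index[rec.snp_id] = rec
        #: row-level parse failures recorded by :func:`read_sumstats`
        self.rejected: list[tuple[int, str]] = []

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SumStatRecord]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SumStatTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.trait_label == other.trait_label
            and self.trait_type == other.trait_type
            and self.n_cases == other.n_cases
            and self.n_controls == other.n_controls
        )

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SumStatRecord | None:
        return self._index.get(snp_id)

    def subset(self, snp_ids: Iterable[str]) -> "SumStatTable":
        """Records with the given ids, in this table's order."""
        keep = set(snp_ids)
        return self.with_records([r for r in self.records if r.snp_id in keep])

    def with_records(self, records: Iterable[SumStatRecord]) -> "SumStatTable":
        return SumStatTable(
            records,
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_optional_float(token: str) -> float | None:
    if token in NA_TOKENS:
        return None
    return float(token)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "trait",
    trait_type: str = "continuous",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SumStatTable:
    """Read a tab-separated summary-statistics file into a :class:`SumStatTable`.

    ``column_map`` maps canonical names (keys) to the file's column names
    (values); canonical names already present in the header need not be
    mapped.  Rows violating record invariants are rejected (not fatal unless
    every row fails); each rejection is logged and recorded on the returned
    table's ``rejected`` attribute as ``(row_number, message)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS if c in df.columns}
    if column_map:
        colmap.update(column_map)
    missing = [c for c in MANDATORY_COLUMNS if colmap.get(c) not in df.columns]
    if missing:
        raise ConfigError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[SumStatRecord] = []
    rejected: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))

        def val(canon: str) -> str | None:
            col = colmap.get(canon)
            return rowd[col] if col in rowd else None

        snp_id = val("snp_id")
        try:
            if snp_id in seen:
                raise ValueError(f"duplicate snp_id {snp_id!r}")
            chrom = val("chrom")
            chrom = None if chrom in NA_TOKENS or chrom is None else str(chrom)
            pos_tok = val("pos")
            pos = None if pos_tok is None else _parse_optional_float(pos_tok)
            eaf_tok = val("eaf")
            eaf = None if eaf_tok is None else _parse_optional_float(eaf_tok)
            n_tok = val("n")
            n = None if n_tok is None else _parse_optional_float(n_tok)
            rec = SumStatRecord(
                snp_id=str(snp_id),
                effect_allele=val("effect_allele"),
                other_allele=val("other_allele"),
                beta=float(val("beta")),
                se=float(val("se")),
                pval=float(val("pval")),
                chrom=chrom,
                pos=None if pos is None else int(pos),
                eaf=eaf,
                n=n,
            )
        except (TypeError, ValueError) as exc:
            msg = f"row {i} ({snp_id!r}): {exc}"
            logger.warning("rejected %s", msg)
            rejected.append((i, str(exc)))
            continue
        seen.add(rec.snp_id)
        records.append(rec)

    if len(df) > 0 and not records:
        raise ConfigError(f"all {len(df)} rows of {path} failed validation")
    if rejected:
        logger.warning("%d of %d rows rejected from %s", len(rejected), len(df), path)
    table = SumStatTable(
        records,
        trait_label=trait_label,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    table.rejected = rejected
    return table


def _fmt(value) -> str:
    if value is None:
        return NA_OUT
    if isinstance(value, float) and float(value).is_integer() and abs(value) < 1e15:
        # sample sizes and positions print as integers
        return str(int(value))
    return repr(value) if isinstance(value, float) else str(value)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table so that :func:`read_sumstats` reproduces it field-for-field."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            fields = [
                r.snp_id,
                r.chrom if r.chrom is not None else NA_OUT,
                str(r.pos) if r.pos is not None else NA_OUT,
                r.effect_allele,
                r.other_allele,
                repr(float(r.eaf)) if r.eaf is not None else NA_OUT,
                repr(float(r.beta)),
                repr(float(r.se)),
                repr(float(r.pval)),
                _fmt(r.n),
            ]
            fh.write("\t".join(fields) + "\n")


class LDTable:
    """Symmetric lookup of pairwise r-squared; absent pairs count as 0."""

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        if a == b and r2 != 1.0:
            raise ValueError(f"r2({a}, {a}) must be 1, got {r2}")
        key = self._key(a, b)
        if key in self._r2 and self._r2[key] != r2:
            raise ValueError(f"conflicting r2 for pair ({a}, {b}): {self._r2[key]} vs {r2}")
        self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return self._r2.get(self._key(a, b), 1.0)
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), r2 in sorted(self._r2.items()):
            yield a, b, r2

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDTable":
        ld = cls()
        for a, b, r2 in pairs:
            ld.set(str(a), str(b), float(r2))
        return ld


def read_ld(path) -> LDTable:
    """Read a three-column long-format LD file (snp_a, snp_b, r2)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ConfigError(f"LD file {path} needs three columns (snp_a, snp_b, r2)")
    ld = LDTable()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        a, b, r2_tok = str(row[0]), str(row[1]), str(row[2])
        try:
            ld.set(a, b, float(r2_tok))
        except ValueError as exc:
            raise ValueError(f"LD row {i}: {exc}") from exc
    return ld


def write_ld(ld: LDTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in ld.pairs():
            fh.write(f"{a}\t{b}\t{r2!r}\n")
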