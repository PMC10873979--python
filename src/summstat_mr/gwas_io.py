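"""Reading, validating and writing GWAS summary statistics and companion tables.

The canonical on-disk dialect is tab-separated text with a header. Summary
statistics carry one row per SNP with the columns

    rsid  chrom  pos  effect_allele  other_allele  eaf  beta  se  pvalue  n

where ``beta`` is the additive effect of one copy of the effect allele (the
log odds ratio for binary traits), ``eaf`` the effect-allele frequency
(optionally missing), and positions are 1-based. Foreign headers (e.g.
FinnGen-style column names) are mapped through ``column_map``.

Pairwise linkage-disequilibrium lookups use a plink ``.ld``-style table
(``chr_a bp_a snp_a chr_b bp_b snp_b r2``); self-pairs are permitted so that
SNPs without any linked partner still carry a genomic position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _stats

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SummaryStats",
    "LDReference",
    "TraitAnnotation",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_reference",
    "write_ld_reference",
    "read_annotation",
    "write_annotation",
]

SUMMARY_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
MANDATORY_COLUMNS = [c for c in SUMMARY_COLUMNS if c != "eaf"]
MISSING_TOKEN = "NA"
VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TRAIT_TYPES = ("continuous", "binary")


class FormatError(ValueError):
    """Raised when an input table cannot be interpreted."""


def _as_upper_str(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.upper()


@dataclass
class SummaryStats:
    """Per-SNP association records for a single trait.

    ``table`` holds the canonical columns (see module docstring). ``beta`` is
    on the log-odds scale when ``trait_type == "binary"``.
    """

    trait_id: str
    trait_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics for {self.trait_id!r} lack columns {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> pd.Series:
        return self.table["rsid"]

    def get(self, rsid: str) -> pd.Series:
        rows = self.table[self.table["rsid"] == rsid]
        if rows.empty:
            raise KeyError(rsid)
        return rows.iloc[0]

    def subset(self, rsids: Iterable[str]) -> "SummaryStats":
        keep = self.table[self.table["rsid"].isin(set(rsids))]
        return replace(self, table=keep.reset_index(drop=True))

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("rsid", drop=False)

    def equals(self, other: "SummaryStats") -> bool:
        if (self.trait_id, self.trait_type) != (other.trait_id, other.trait_type):
            return False
        a, b = self.table, other.table
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind == "f":
                va, vb = a[c].to_numpy(), b[c].to_numpy()
                both_nan = np.isnan(va) & np.isnan(vb)
                if not np.all(both_nan | (va == vb)):
                    return False
            elif not a[c].equals(b[c]):
                return False
        return True


def validate_summary_table(
    df: pd.DataFrame,
    trait_id: str = "?",
    pvalue_tolerance: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Enforce record-level invariants, dropping offending rows.

    Rows are removed when the standard error is not strictly positive, when
    either allele is not a single A/C/G/T base, when the two alleles are
    identical (multi-allelic and indel records are thereby rejected), when
    eaf/pvalue fall outside their ranges, or when the rsid duplicates an
    earlier row. Disagreement between the reported p-value and the two-sided
    normal test of beta/se beyond ``pvalue_tolerance`` (relative, on the
    -log10 scale) is only warned about, never dropped.
    """
    report: dict[str, int] = {}
    df = df.copy()
    df["effect_allele"] = _as_upper_str(df["effect_allele"])
    df["other_allele"] = _as_upper_str(df["other_allele"])

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            report[reason] = report.get(reason, 0) + k
            log.warning("%s: dropping %d record(s): %s", trait_id, k, reason)
            df = df[~mask]

    drop(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES),
         "allele not a single A/C/G/T base")
    drop(df["effect_allele"] == df["other_allele"], "effect allele equals other allele")
    drop(~(df["se"] > 0) | ~np.isfinite(df["se"]), "non-positive or missing standard error")
    drop(~np.isfinite(df["beta"]), "missing beta")
    drop((df["pvalue"] <= 0) | (df["pvalue"] > 1) | ~np.isfinite(df["pvalue"]),
         "p-value outside (0, 1]")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    drop(eaf_bad, "eaf outside (0, 1)")
    drop(df["rsid"].duplicated(), "duplicate rsid")

    if len(df):
        expected = 2.0 * _stats.norm.sf(np.abs(df["beta"] / df["se"]))
        with np.errstate(divide="ignore"):
            lo, le = -np.log10(df["pvalue"]), -np.log10(np.clip(expected, 1e-300, None))
        off = np.abs(lo - le) > pvalue_tolerance * np.maximum(1.0, np.abs(le))
        n_off = int(np.sum(off))
        if n_off:
            report["pvalue_inconsistent_warning"] = n_off
            log.warning("%s: %d record(s) have p-values inconsistent with beta/se "
                        "(kept; validation warning only)", trait_id, n_off)
    return df.reset_index(drop=True), report


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read one trait's summary statistics from a delimited text table.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"rsid": "SNP", "pvalue": "pval"}``; unmapped canonical names are
    assumed to appear verbatim in the header. Invalid rows are dropped with a
    logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN, ""],
                          dtype={"chrom": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in SUMMARY_COLUMNS}
    raw = raw.rename(columns={src: dst for src, dst in rename.items() if src in raw.columns})
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path} lacks mandatory column(s) {missing}")
    if "eaf" not in raw.columns:
        raw["eaf"] = np.nan
    df = raw[SUMMARY_COLUMNS].copy()
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("eaf", "beta", "se", "pvalue"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").astype(np.int64)
    tid = trait_id if trait_id is not None else path.stem
    df, _ = validate_summary_table(df, trait_id=tid)
    return SummaryStats(trait_id=tid, trait_type=trait_type, table=df)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> Path:
    """Write summary statistics to TSV; ``read(write(x))`` is field-for-field identity."""
    path = Path(path)
    # %.17g guarantees binary64 round-trip through text
    stats.table.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
                       float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# LD reference


@dataclass
class LDReference:
    """Pairwise r-squared lookup with genomic positions.

    ``entries`` is keyed by lexicographically sorted rsid pairs; ``positions``
    maps rsid to ``(chrom, pos)``. ``r2(x, x)`` is implicitly 1.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must lie in [0, 1], got {r2}")
        if a != b:
            self.entries[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float | None:
        """Stored r² for a pair, 1.0 for identical rsids, None when unknown."""
        if a == b:
            return 1.0
        return self.entries.get(self._key(a, b))

    def partners(self, rsid: str) -> list[tuple[str, float]]:
        out = []
        for (a, b), r2 in self.entries.items():
            if a == rsid:
                out.append((b, r2))
            elif b == rsid:
                out.append((a, r2))
        return out

    def distance(self, a: str, b: str) -> float:
        """Base-pair distance; +inf across chromosomes or for unplaced SNPs."""
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is None or pb is None or pa[0] != pb[0]:
            return float("inf")
        return abs(pa[1] - pb[1])


LD_COLUMNS = ["chr_a", "bp_a", "snp_a", "chr_b", "bp_b", "snp_b", "r2"]


def write_ld_reference(ld: LDReference, path: str | Path) -> Path:
    rows = []
    paired = set()
    for (a, b), r2 in sorted(ld.entries.items()):
        ca, pa = ld.positions.get(a, ("NA", 0))
        cb, pb = ld.positions.get(b, ("NA", 0))
        rows.append((ca, pa, a, cb, pb, b, r2))
        paired.update((a, b))
    for rsid, (c, p) in sorted(ld.positions.items()):
        if rsid not in paired:  # self-pair carries the position
            rows.append((c, p, rsid, c, p, rsid, 1.0))
    pd.DataFrame(rows, columns=LD_COLUMNS).to_csv(path, sep="\t", index=False,
                                                  float_format="%.17g")
    return Path(path)


def read_ld_reference(path: str | Path) -> LDReference:
    df = pd.read_csv(path, sep="\t", dtype={"chr_a": str, "chr_b": str})
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks LD column(s) {missing}")
    ld = LDReference()
    for row in df.itertuples(index=False):
        ld.positions[row.snp_a] = (row.chr_a, int(row.bp_a))
        ld.positions[row.snp_b] = (row.chr_b, int(row.bp_b))
        if row.snp_a != row.snp_b:
            ld.set_r2(row.snp_a, row.snp_b, float(row.r2))
    return ld


# ---------------------------------------------------------------------------
# Trait annotation (local stand-in for a PhenoScanner-style lookup)


@dataclass
class TraitAnnotation:
    """Known SNP-trait associations: one row per (rsid, trait, pvalue)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("rsid", "trait", "pvalue"):
            if c not in self.table.columns:
                raise FormatError(f"annotation table lacks column {c!r}")
        bad = (self.table["pvalue"] <= 0) | (self.table["pvalue"] > 1)
        if bad.any():
            raise FormatError("annotation p-values must lie in (0, 1]")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def empty(cls) -> "TraitAnnotation":
        return cls(pd.DataFrame(columns=["rsid", "trait", "pvalue"]).astype(
            {"rsid": str, "trait": str, "pvalue": float}))

    def lookup(self, rsid: str) -> pd.DataFrame:
        return self.table[self.table["rsid"] == rsid]


def write_annotation(annotation: TraitAnnotation, path: str | Path) -> Path:
    annotation.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_annotation(path: str | Path) -> TraitAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "trait": str})
    if df.empty and "rsid" not in df.columns:
        return TraitAnnotation.empty()
    return TraitAnnotation(table=df)
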