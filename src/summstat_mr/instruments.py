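"""Instrument selection and qualification for two-sample MR.

Canonical order: genome-wide significance filter (p < 5e-8, strict), greedy
LD clumping (keep the lowest-p index SNP, remove linked SNPs with r² above
0.001 within a 10,000 kb window), exclusion of SNPs annotated to listed
confounder traits, exclusion of SNPs genome-wide associated with the outcome,
and proxy substitution (r² > 0.8, strict) for instruments absent from the
outcome panel. Instrument strength is summarized per SNP by the
standardized-trait approximation r² = 2·MAF·(1-MAF)·beta² and
F = r²·(n-2)/(1-r²), with F <= 10 flagged as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import LDReference, SummaryStats, TraitAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "SelectionResult",
    "filter_genome_wide",
    "clump",
    "exclude_confounder_snps",
    "exclude_outcome_associated",
    "find_proxies",
    "instrument_strength",
    "select_instruments",
]


def filter_genome_wide(stats: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Keep records with p strictly below the genome-wide threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    return stats.subset(stats.table.loc[stats.table["pvalue"] < p_threshold, "rsid"])


def clump(
    stats: SummaryStats,
    ld: LDReference,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryStats:
    """Greedy LD clumping: lowest-p index SNPs; linked neighbours removed.

    Repeatedly take the unprocessed SNP with the lowest p-value (ties broken
    by rsid) as an index SNP and remove every other SNP within ``window_kb``
    of it whose r² with it exceeds ``r2_threshold``. SNPs unknown to the LD
    reference are treated as unlinked (logged).
    """
    df = stats.table.sort_values(["pvalue", "rsid"], kind="mergesort")
    order = list(df["rsid"])
    unknown = [s for s in order if s not in ld.positions]
    if unknown:
        log.warning("clump: %d SNP(s) absent from the LD reference, treated as unlinked",
                    len(unknown))
    removed: set[str] = set()
    retained: list[str] = []
    window_bp = window_kb * 1_000.0
    for idx_snp in order:
        if idx_snp in removed:
            continue
        retained.append(idx_snp)
        for other in order:
            if other == idx_snp or other in removed:
                continue
            if ld.distance(idx_snp, other) > window_bp:
                continue
            r2 = ld.r2(idx_snp, other)
            if r2 is not None and r2 > r2_threshold:
                removed.add(other)
    return stats.subset(retained)


def exclude_confounder_snps(
    instr: SummaryStats,
    annotation: TraitAnnotation,
    confounder_traits: set[str] | list[str],
    p_threshold: float = 5e-8,
) -> SummaryStats:
    """Remove SNPs annotated to a listed confounder trait at p below threshold."""
    confounders = {t.lower() for t in confounder_traits}
    hits = annotation.table[
        annotation.table["trait"].str.lower().isin(confounders)
        & (annotation.table["pvalue"] < p_threshold)
    ]
    bad = set(hits["rsid"])
    for _, row in hits.iterrows():
        if row["rsid"] in set(instr.rsids):
            log.info("excluding %s: associated with confounder %r (p=%.2g)",
                     row["rsid"], row["trait"], row["pvalue"])
    keep = [s for s in instr.rsids if s not in bad]
    return instr.subset(keep)


def exclude_outcome_associated(
    instr: SummaryStats,
    outcome: SummaryStats,
    p_threshold: float = 5e-8,
) -> SummaryStats:
    """Remove instruments genome-wide associated with the outcome itself.

    Instruments absent from the outcome panel are retained here (proxy search
    handles them) and logged.
    """
    out = outcome.indexed()
    keep = []
    for s in instr.rsids:
        if s not in out.index:
            log.info("instrument %s missing from outcome panel (proxy search applies)", s)
            keep.append(s)
        elif out.loc[s, "pvalue"] >= p_threshold:
            keep.append(s)
        else:
            log.info("excluding %s: outcome association p=%.2g", s, out.loc[s, "pvalue"])
    return instr.subset(keep)


def find_proxies(
    missing_snps: list[str],
    ld: LDReference,
    outcome: SummaryStats,
    r2_min: float = 0.8,
) -> dict[str, tuple[str, float] | None]:
    """Best outcome-present proxy per missing SNP, requiring r² strictly > r2_min.

    Ties on r² break by smaller genomic distance, then lexicographic rsid.
    """
    present = set(outcome.rsids)
    out: dict[str, tuple[str, float] | None] = {}
    for s in missing_snps:
        candidates = [(r2, ld.distance(s, other), other)
                      for other, r2 in ld.partners(s)
                      if other in present and r2 > r2_min]
        if not candidates:
            out[s] = None
            continue
        best = min(candidates, key=lambda c: (-c[0], c[1], c[2]))
        out[s] = (best[2], best[0])
    return out


def instrument_strength(
    instr: SummaryStats,
    n: int | None = None,
    f_weak: float = 10.0,
    eaf_fallback: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-SNP variance explained and F statistic, plus a summary.

    r²_j = 2·MAF_j·(1-MAF_j)·beta_j² (standardized-trait approximation) and
    F_j = r²_j·(n-2)/(1-r²_j). SNPs lacking eaf are flagged and excluded from
    the summary unless ``eaf_fallback`` is set, in which case
    r² = beta²/(beta² + n·se²) is used for them.
    """
    tab = instr.table
    n_vec = tab["n"].to_numpy(dtype=float) if n is None else np.full(len(tab), float(n))
    if np.any(n_vec < 3):
        raise ValueError("sample size must be at least 3")
    eaf = tab["eaf"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    beta = tab["beta"].to_numpy(dtype=float)
    se = tab["se"].to_numpy(dtype=float)
    r2 = 2.0 * maf * (1.0 - maf) * beta**2
    missing = ~np.isfinite(maf)
    if eaf_fallback:
        fb = beta**2 / (beta**2 + n_vec * se**2)
        r2 = np.where(missing, fb, r2)
        missing = np.zeros_like(missing)
    elif missing.any():
        log.warning("instrument_strength: %d SNP(s) lack eaf; excluded from the summary",
                    int(missing.sum()))
    with np.errstate(invalid="ignore"):
        F = r2 * (n_vec - 2.0) / (1.0 - r2)
    per_snp = pd.DataFrame({
        "rsid": tab["rsid"], "r2": r2, "F": F,
        "weak": ~(F > f_weak), "missing_eaf": missing,
    })
    valid = per_snp[~per_snp["missing_eaf"]]
    summary = {
        "n_snp": int(len(valid)),
        "min_F": float(valid["F"].min()) if len(valid) else float("nan"),
        "mean_F": float(valid["F"].mean()) if len(valid) else float("nan"),
        "max_F": float(valid["F"].max()) if len(valid) else float("nan"),
        "total_r2": float(valid["r2"].sum()) if len(valid) else float("nan"),
        "n_weak": int(valid["weak"].sum()),
    }
    return per_snp, summary


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with per-SNP provenance."""

    exposure_id: str
    snps: list[str]
    provenance: pd.DataFrame   # per-candidate flags and exclusion reasons
    per_snp_strength: pd.DataFrame = field(default_factory=pd.DataFrame)
    strength_summary: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    instruments: InstrumentSet
    exposure_stats: SummaryStats   # retained instruments, exposure side
    outcome_stats: SummaryStats    # matching outcome records (proxies substituted)
    attrition: pd.DataFrame        # per-stage counts in/out


def select_instruments(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDReference,
    annotation: TraitAnnotation | None = None,
    confounder_traits: set[str] | list[str] = (),
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000.0,
    confounder_p: float = 5e-8,
    outcome_assoc_p: float = 5e-8,
    proxy_r2: float = 0.8,
) -> SelectionResult:
    """Full selection pipeline with a per-stage attrition table.

    A proxy replaces its instrument entirely (exposure and outcome records)
    and must itself be present in the exposure panel; instruments without a
    qualifying proxy are excluded.
    """
    annotation = annotation if annotation is not None else TraitAnnotation.empty()
    stages: list[tuple[str, int, int]] = []

    def record(stage: str, before: int, after: int) -> None:
        stages.append((stage, before, after))

    current = filter_genome_wide(exposure, p_threshold)
    record("genome_wide_filter", exposure.n_records, current.n_records)

    n0 = current.n_records
    current = clump(current, ld, clump_r2, clump_window_kb)
    record("ld_clumping", n0, current.n_records)

    n0 = current.n_records
    current = exclude_confounder_snps(current, annotation, confounder_traits, confounder_p)
    record("confounder_exclusion", n0, current.n_records)

    n0 = current.n_records
    current = exclude_outcome_associated(current, outcome, outcome_assoc_p)
    record("outcome_association_exclusion", n0, current.n_records)

    # proxy substitution for instruments absent from the outcome panel
    out_idx = outcome.indexed()
    exp_idx = exposure.indexed()
    missing = [s for s in current.rsids if s not in out_idx.index]
    proxies = find_proxies(missing, ld, outcome, proxy_r2) if missing else {}
    proxy_of: dict[str, tuple[str, float]] = {}
    final: list[str] = []
    for s in current.rsids:
        if s not in missing:
            final.append(s)
            continue
        hit = proxies.get(s)
        if hit is not None and hit[0] in exp_idx.index and hit[0] not in final:
            final.append(hit[0])
            proxy_of[hit[0]] = (s, hit[1])
            log.info("proxy %s (r2=%.3f) substitutes %s", hit[0], hit[1], s)
        else:
            log.info("instrument %s excluded: no qualifying proxy", s)
    record("proxy_substitution", current.n_records, len(final))

    exp_sel = exposure.subset(final)
    out_sel = outcome.subset([s for s in final if s in out_idx.index])
    per_snp, summary = instrument_strength(exp_sel)

    passed = set(filter_genome_wide(exposure, p_threshold).rsids)
    clumped = set(clump(filter_genome_wide(exposure, p_threshold), ld,
                        clump_r2, clump_window_kb).rsids)
    prov = pd.DataFrame({
        "rsid": list(exp_sel.rsids),
        "passed_pthreshold": [s in passed or s in proxy_of for s in exp_sel.rsids],
        "clump_retained": [s in clumped or s in proxy_of for s in exp_sel.rsids],
        "proxy_for": [proxy_of.get(s, (None,))[0] for s in exp_sel.rsids],
        "proxy_r2": [proxy_of.get(s, (None, np.nan))[1] for s in exp_sel.rsids],
    })
    attrition = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
    attrition["n_removed"] = attrition["n_in"] - attrition["n_out"]
    instruments = InstrumentSet(
        exposure_id=exposure.trait_id, snps=final, provenance=prov,
        per_snp_strength=per_snp, strength_summary=summary,
    )
    return SelectionResult(instruments=instruments, exposure_stats=exp_sel,
                           outcome_stats=out_sel, attrition=attrition)
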