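"""Study orchestration: univariable MR per exposure, outlier-corrected
reruns, multivariable MR across exposures, and multiple-testing calls.

A study is a set of exposures analysed against one outcome. For each
exposure the univariable arm runs the instrument-selection pipeline,
harmonization, the three estimators and the sensitivity battery; when the
outlier procedure flags SNPs they are removed and every estimator is rerun,
with both passes reported. The multivariable arm pools the exposures'
instruments (union, clumped jointly on the smallest p across exposures),
harmonizes all traits together and reports each exposure's direct effect;
indirect effects are reported descriptively as total (univariable) minus
direct (multivariable).

Family-wise error is controlled by Bonferroni across the exposures tested
(0.05/4 = 0.0125 for a four-exposure study); p-values between that threshold
and 0.05 are labelled suggestive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import MRModel
from .gwas_io import (LDReference, SummaryStats, TraitAnnotation,
                      read_annotation, read_ld_reference, read_summary_stats)
from .harmonization import harmonize
from .instruments import (clump, exclude_confounder_snps, exclude_outcome_associated,
                          filter_genome_wide, find_proxies, select_instruments)

log = logging.getLogger(__name__)

__all__ = [
    "Thresholds", "StudyConfig", "StudyData", "StudyReport",
    "bonferroni_threshold", "classify_significance",
    "run_univariable", "run_multivariable", "run_study",
]


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance level alpha/n (0.05 over 4 traits -> 0.0125)."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must lie in (0, 1)")
    return alpha_family / n_tests


def classify_significance(p: float, threshold: float,
                          suggestive_upper: float = 0.05) -> str:
    """'significant' below the corrected threshold, 'suggestive' up to the
    nominal level (strict upper bound), else 'null'."""
    if not 0.0 < threshold <= suggestive_upper:
        raise ValueError("require 0 < threshold <= suggestive_upper")
    if p < threshold:
        return "significant"
    if p < suggestive_upper:
        return "suggestive"
    return "null"


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs, defaulting to the conventional values."""

    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2: float = 0.8
    confounder_p: float = 5e-8
    outcome_assoc_p: float = 5e-8
    palindromic_band: float = 0.08
    presso_n_sim: int = 1000
    presso_significance: float = 0.05
    alpha_family: float = 0.05
    suggestive_upper: float = 0.05
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must lie in (0, 1)")


@dataclass
class StudyData:
    """In-memory study inputs."""

    exposures: list[SummaryStats]
    outcome: SummaryStats
    ld: LDReference
    annotation: TraitAnnotation
    confounder_traits: list[str] = field(default_factory=list)


@dataclass
class StudyConfig:
    """File-backed study description (YAML)."""

    exposures: list[dict]            # {trait_id, path, trait_type, [column_map]}
    outcome: dict
    ld_reference: str
    annotation: str | None = None
    confounder_traits: list[str] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(exposures=raw["exposures"], outcome=raw["outcome"],
                   ld_reference=raw["ld_reference"],
                   annotation=raw.get("annotation"),
                   confounder_traits=list(raw.get("confounder_traits", [])),
                   thresholds=thr, seed=int(raw.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> Path:
        payload = {
            "exposures": self.exposures, "outcome": self.outcome,
            "ld_reference": self.ld_reference, "annotation": self.annotation,
            "confounder_traits": self.confounder_traits,
            "thresholds": asdict(self.thresholds), "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
        return Path(path)

    def load(self) -> StudyData:
        exposures = [read_summary_stats(e["path"], e.get("column_map"),
                                        e.get("trait_type", "continuous"),
                                        trait_id=e["trait_id"])
                     for e in self.exposures]
        outcome = read_summary_stats(self.outcome["path"],
                                     self.outcome.get("column_map"),
                                     self.outcome.get("trait_type", "binary"),
                                     trait_id=self.outcome["trait_id"])
        ld = read_ld_reference(self.ld_reference)
        annotation = (read_annotation(self.annotation) if self.annotation
                      else TraitAnnotation.empty())
        return StudyData(exposures=exposures, outcome=outcome, ld=ld,
                         annotation=annotation,
                         confounder_traits=list(self.confounder_traits))


def _exposure_seed(seed: int, idx: int) -> int:
    return (seed * 1_000_003 + 7919 * (idx + 1)) % (2**31 - 1)


_METHOD_LABELS = ("ivw", "egger", "weighted_median")


def _fit_rows(model: MRModel, exposure_id: str, stage: str, seed: int,
              n_boot: int) -> list[dict]:
    rows = []
    for m in _METHOD_LABELS:
        kw = ({"seed": seed, "n_boot": n_boot} if m == "weighted_median" else {})
        res = model.fit(m, **kw)
        for e in res.estimates:
            row = e.as_row()
            row["exposure"] = e.exposure_id or exposure_id
            row["stage"] = stage
            if "intercept" in e.extras:
                row["egger_intercept"] = e.extras["intercept"]
                row["egger_intercept_p"] = e.extras["intercept_pvalue"]
            rows.append(row)
    return rows


@dataclass
class StudyReport:
    """Everything the study produced, reproducible from stored numbers."""

    results: pd.DataFrame                    # univariable estimates, both passes
    sensitivity: pd.DataFrame
    attrition: pd.DataFrame
    calls: pd.DataFrame                      # per-exposure significance calls (IVW)
    mvmr: pd.DataFrame | None = None
    indirect: pd.DataFrame | None = None
    skipped: list[dict] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha_bonferroni: float = float("nan")
    n_tests: int = 0
    seed: int = 0

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "forest_table.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity_table.tsv", sep="\t", index=False)
        self.attrition.to_csv(outdir / "attrition_table.tsv", sep="\t", index=False)
        self.calls.to_csv(outdir / "significance_calls.tsv", sep="\t", index=False)
        if self.mvmr is not None:
            self.mvmr.to_csv(outdir / "mvmr_table.tsv", sep="\t", index=False)
        if self.indirect is not None:
            self.indirect.to_csv(outdir / "indirect_effects.tsv", sep="\t", index=False)
        header = {"thresholds": asdict(self.thresholds), "seed": self.seed,
                  "alpha_bonferroni": self.alpha_bonferroni, "n_tests": self.n_tests,
                  "skipped": self.skipped}
        (outdir / "report_header.yaml").write_text(yaml.safe_dump(header, sort_keys=False))
        return outdir

    def summary(self) -> str:
        lines = [f"Univariable MR over {self.n_tests} exposure(s); "
                 f"Bonferroni threshold {self.alpha_bonferroni:.4g}"]
        for _, row in self.calls.iterrows():
            lines.append(f"  {row['exposure']:<16} IVW ({row['basis']}) "
                         f"OR {row['or']:.3f} ({row['or_low']:.3f}-{row['or_high']:.3f}) "
                         f"p={row['pvalue']:.3g} -> {row['call']}")
        return "\n".join(lines)


def run_univariable(data: StudyData, thresholds: Thresholds = Thresholds(),
                    seed: int = 0) -> StudyReport:
    """Univariable arm: per exposure, selection -> harmonization ->
    {IVW, Egger, weighted median} -> sensitivity battery -> outlier-corrected
    rerun when the outlier procedure flags SNPs."""
    thr = thresholds
    all_rows: list[dict] = []
    sens_rows: list[dict] = []
    attr_rows: list[pd.DataFrame] = []
    calls: list[dict] = []
    skipped: list[dict] = []

    for idx, exposure in enumerate(data.exposures):
        e_seed = _exposure_seed(seed, idx)
        sel = select_instruments(
            exposure, data.outcome, data.ld, data.annotation,
            data.confounder_traits,
            p_threshold=thr.p_instrument, clump_r2=thr.clump_r2,
            clump_window_kb=thr.clump_window_kb, confounder_p=thr.confounder_p,
            outcome_assoc_p=thr.outcome_assoc_p, proxy_r2=thr.proxy_r2)
        att = sel.attrition.copy()
        att.insert(0, "exposure", exposure.trait_id)
        attr_rows.append(att)
        if sel.exposure_stats.n_records < 2:
            skipped.append({"exposure": exposure.trait_id,
                            "reason": "fewer than 2 surviving instruments",
                            "n_instruments": sel.exposure_stats.n_records})
            continue
        frame = harmonize(sel.exposure_stats, sel.outcome_stats,
                          palindromic_eaf_band=thr.palindromic_band)
        model = MRModel(frame)
        all_rows.extend(_fit_rows(model, exposure.trait_id, "primary",
                                  e_seed, thr.n_boot))
        report = model.sensitivity(n_sim=thr.presso_n_sim, seed=e_seed,
                                   outlier_significance=thr.presso_significance)
        srow = report.as_row()
        srow["exposure"] = exposure.trait_id
        srow["F_min"] = sel.instruments.strength_summary.get("min_F")
        srow["F_max"] = sel.instruments.strength_summary.get("max_F")
        sens_rows.append(srow)

        basis = "primary"
        final_model = model
        if report.presso_outliers:
            corrected_frame = frame.exclude(report.presso_outliers)
            final_model = MRModel(corrected_frame)
            all_rows.extend(_fit_rows(final_model, exposure.trait_id,
                                      "outlier_corrected", e_seed, thr.n_boot))
            basis = "outlier_corrected"
        final_ivw = final_model.fit("ivw").estimate
        calls.append({"exposure": exposure.trait_id, "basis": basis,
                      "n_snp": final_ivw.n_snp, "beta": final_ivw.beta,
                      "se": final_ivw.se, "pvalue": final_ivw.pvalue,
                      "or": final_ivw.or_scale[0] if final_ivw.or_scale else np.nan,
                      "or_low": final_ivw.or_scale[1] if final_ivw.or_scale else np.nan,
                      "or_high": final_ivw.or_scale[2] if final_ivw.or_scale else np.nan})

    n_tests = len(calls)
    alpha = bonferroni_threshold(thr.alpha_family, max(1, n_tests))
    calls_df = pd.DataFrame(calls)
    if len(calls_df):
        calls_df["call"] = [classify_significance(p, alpha, thr.suggestive_upper)
                            for p in calls_df["pvalue"]]
    return StudyReport(
        results=pd.DataFrame(all_rows),
        sensitivity=pd.DataFrame(sens_rows),
        attrition=(pd.concat(attr_rows, ignore_index=True)
                   if attr_rows else pd.DataFrame()),
        calls=calls_df, skipped=skipped, thresholds=thr,
        alpha_bonferroni=alpha, n_tests=n_tests, seed=seed)


def _mv_select(data: StudyData, thr: Thresholds) -> list[str]:
    """Union of per-exposure significant SNPs, clumped jointly on min p."""
    sig_sets = [set(filter_genome_wide(e, thr.p_instrument).rsids)
                for e in data.exposures]
    union = sorted(set().union(*sig_sets))
    if not union:
        return []
    pmin: dict[str, float] = {}
    source: dict[str, pd.Series] = {}
    for e in data.exposures:
        ix = e.indexed()
        for s in union:
            if s in ix.index:
                p = float(ix.loc[s, "pvalue"])
                if s not in pmin or p < pmin[s]:
                    pmin[s] = p
                if s not in source:
                    source[s] = ix.loc[s]
    rows = []
    for s in union:
        row = source[s].copy()
        row["pvalue"] = pmin[s]
        rows.append(row)
    pooled = SummaryStats(trait_id="mv_union", trait_type="continuous",
                          table=pd.DataFrame(rows).reset_index(drop=True))
    pooled = clump(pooled, data.ld, thr.clump_r2, thr.clump_window_kb)
    pooled = exclude_confounder_snps(pooled, data.annotation,
                                     data.confounder_traits, thr.confounder_p)
    pooled = exclude_outcome_associated(pooled, data.outcome, thr.outcome_assoc_p)

    out_present = set(data.outcome.rsids)
    exp_indices = [e.indexed() for e in data.exposures]
    final: list[str] = []
    missing = [s for s in pooled.rsids if s not in out_present]
    proxies = find_proxies(missing, data.ld, data.outcome, thr.proxy_r2)
    for s in pooled.rsids:
        if s in out_present:
            if all(s in ix.index for ix in exp_indices):
                final.append(s)
            continue
        hit = proxies.get(s)
        if (hit is not None and all(hit[0] in ix.index for ix in exp_indices)
                and hit[0] not in final):
            final.append(hit[0])
            log.info("mv selection: proxy %s (r2=%.3f) substitutes %s",
                     hit[0], hit[1], s)
        else:
            log.info("mv selection: %s excluded (missing in a panel, no proxy)", s)
    return final


def run_multivariable(data: StudyData, thresholds: Thresholds = Thresholds(),
                      seed: int = 0,
                      univariable: StudyReport | None = None) -> StudyReport:
    """Multivariable arm: joint instrument set, multi-trait harmonization,
    direct effects by IVW/Egger/median, and descriptive indirect effects
    (total minus direct) when univariable totals are available."""
    thr = thresholds
    final = _mv_select(data, thr)
    if len(final) < len(data.exposures) + 1:
        raise ValueError(
            f"only {len(final)} joint instruments for {len(data.exposures)} exposures")
    exposures = [e.subset(final) for e in data.exposures]
    outcome = data.outcome.subset(final)
    frame = harmonize(exposures, outcome, palindromic_eaf_band=thr.palindromic_band)
    model = MRModel(frame)
    mv_seed = _exposure_seed(seed, 999)
    rows = _fit_rows(model, "multivariable", "direct", mv_seed, thr.n_boot)
    mv = pd.DataFrame(rows)

    indirect = None
    if univariable is not None and len(univariable.calls):
        total = univariable.calls.set_index("exposure")["beta"]
        direct = mv[mv["method"] == "mvmr_ivw"].set_index("exposure")["beta"]
        common = [t for t in direct.index if t in total.index]
        indirect = pd.DataFrame({
            "exposure": common,
            "total_beta": [total[t] for t in common],
            "direct_beta": [direct[t] for t in common],
        })
        indirect["indirect_beta"] = indirect["total_beta"] - indirect["direct_beta"]
    return StudyReport(results=mv, sensitivity=pd.DataFrame(),
                       attrition=pd.DataFrame({"stage": ["mv_joint_instruments"],
                                               "n_in": [len(final)],
                                               "n_out": [frame.n_snp],
                                               "n_removed": [len(final) - frame.n_snp]}),
                       calls=pd.DataFrame(), mvmr=mv, indirect=indirect,
                       thresholds=thr, seed=seed)


def run_study(data: StudyData, thresholds: Thresholds = Thresholds(),
              seed: int = 0) -> StudyReport:
    """Full design: univariable arm, then multivariable arm when >= 2 exposures."""
    report = run_univariable(data, thresholds, seed)
    if len(data.exposures) >= 2:
        try:
            mv = run_multivariable(data, thresholds, seed, univariable=report)
            report.mvmr = mv.mvmr
            report.indirect = mv.indirect
        except ValueError as exc:
            log.warning("multivariable arm skipped: %s", exc)
            report.skipped.append({"exposure": "multivariable", "reason": str(exc)})
    return report
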