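"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q with I², the simulation-based residual-sum-of-squares outlier
procedure (global, per-SNP outlier and distortion tests, with an
outlier-corrected re-estimate), leave-one-out influence analysis, and funnel
data (per-SNP ratio vs precision).

The RSS procedure follows the standard recipe: observed RSS uses
leave-one-out IVW slopes; the null distribution is built by redrawing the
per-SNP effects from normal distributions centred on fitted values with the
observed standard errors and recomputing the statistic. Its p-values have
resolution 1/n_sim — a reported 0.0 means "below resolution".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .estimators import InsufficientInstrumentsError, MREstimate, _ratios, ivw, mr_egger
from .harmonization import HarmonizedFrame

log = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport", "PressoResult",
    "cochran_q", "mr_presso", "leave_one_out", "funnel_data",
    "sensitivity_battery",
]


def cochran_q(frame: HarmonizedFrame, pooled_beta: float | None = None
              ) -> tuple[float, int, float, float]:
    """Cochran's Q across per-SNP ratio estimates, with I².

    Q = sum_j w_j (ratio_j - pooled)², w_j = 1/se_ratio_j², df = n-1;
    I² = max(0, (Q - df)/Q)·100. ``pooled_beta`` defaults to the IVW
    estimate on the frame.
    """
    if frame.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    ratios, se_ratio = _ratios(frame)
    if pooled_beta is None:
        pooled_beta = ivw(frame).beta
    w = 1.0 / se_ratio**2
    q = float(np.sum(w * (ratios - pooled_beta) ** 2))
    df = frame.n_snp - 1
    p = float(_stats.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, df, p, i2


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each SNP left out, vectorized (last axis = SNPs)."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list[str]
    outlier_pvalues: pd.Series
    distortion_p: float | None          # None when no outliers were found
    corrected: MREstimate | None        # IVW on the outlier-free frame
    n_sim: int
    seed: int


def mr_presso(
    frame: HarmonizedFrame,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> PressoResult:
    """Residual-sum-of-squares outlier procedure with corrected re-estimate.

    Global test: observed weighted RSS against leave-one-out IVW predictions,
    compared with ``n_sim`` simulated no-pleiotropy datasets. When the global
    p falls below ``outlier_significance``, per-SNP observed-vs-simulated
    squared residuals give per-SNP p-values, Bonferroni-corrected across
    SNPs; flagged SNPs are removed and IVW re-run. The distortion test
    compares the resulting estimate shift with shifts from removing random
    non-outlier subsets of the same size.
    """
    n = frame.n_snp
    if n < 4:
        raise InsufficientInstrumentsError("the outlier procedure needs at least 4 instruments")
    rng = np.random.default_rng(seed)
    bx, by = frame.bx, frame.beta_y
    sx, sy = frame.sx, frame.se_y
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    obs_res = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(obs_res))

    bx_sim = bx + rng.standard_normal((n_sim, n)) * sx
    by_sim = loo * bx + rng.standard_normal((n_sim, n)) * sy
    loo_sim = _loo_slopes(bx_sim, by_sim, w)
    sim_res = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = np.sum(sim_res, axis=1)
    global_p = float(np.mean(rss_sim >= rss_obs))

    outliers: list[str] = []
    outlier_p = pd.Series(np.nan, index=list(frame.snps), name="outlier_pvalue")
    if global_p < outlier_significance:
        per_snp_p = np.mean(sim_res >= obs_res[None, :], axis=0)
        outlier_p = pd.Series(per_snp_p, index=list(frame.snps), name="outlier_pvalue")
        flag = per_snp_p < outlier_significance / n
        outliers = [str(s) for s in frame.snps[flag]]

    distortion_p: float | None = None
    corrected: MREstimate | None = None
    if outliers:
        kept = frame.exclude(outliers)
        corrected = ivw(kept)
        full = ivw(frame)
        displacement = corrected.beta - full.beta
        k = len(outliers)
        non_outliers = np.flatnonzero(~np.isin(frame.snps, outliers))
        if len(non_outliers) > k:
            disp_sim = np.empty(n_sim)
            sxy_all = float(np.sum(w * bx * by))
            sxx_all = float(np.sum(w * bx * bx))
            for s in range(n_sim):
                drop = rng.choice(non_outliers, size=k, replace=False)
                slope = ((sxy_all - np.sum(w[drop] * bx[drop] * by[drop]))
                         / (sxx_all - np.sum(w[drop] * bx[drop] ** 2)))
                disp_sim[s] = slope - full.beta
            distortion_p = float(np.mean(np.abs(disp_sim) >= abs(displacement)))
        else:  # everything but the outliers would be removed
            distortion_p = None
    return PressoResult(global_rss=rss_obs, global_p=global_p, outliers=outliers,
                        outlier_pvalues=outlier_p, distortion_p=distortion_p,
                        corrected=corrected, n_sim=n_sim, seed=seed)


def leave_one_out(frame: HarmonizedFrame) -> pd.DataFrame:
    """IVW estimate with each SNP excluded in turn.

    The returned table carries the full-frame estimate in ``attrs["full"]``;
    ``flagged`` marks SNPs whose exclusion changes the estimate's sign or
    moves it outside the full-frame CI (a heuristic operationalization of
    "strong deviation").
    """
    if frame.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 instruments")
    full = ivw(frame)
    rows = []
    for j in range(frame.n_snp):
        mask = np.ones(frame.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(frame.subset(mask))
        flagged = (np.sign(est.beta) != np.sign(full.beta)
                   or not (full.ci_low <= est.beta <= full.ci_high))
        rows.append({"rsid": frame.snps[j], "beta": est.beta, "se": est.se,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "pvalue": est.pvalue, "flagged": bool(flagged)})
    table = pd.DataFrame(rows)
    table.attrs["full"] = full
    return table


def funnel_data(frame: HarmonizedFrame) -> pd.DataFrame:
    """Per-SNP Wald ratio and precision 1/se_ratio for funnel plotting.

    The pooled IVW value is carried in ``attrs["ivw_beta"]`` (the vertical
    reference line); a symmetric funnel suggests no directional pleiotropy.
    """
    if frame.n_snp < 1:
        raise ValueError("empty frame")
    ratios, se_ratio = _ratios(frame)
    table = pd.DataFrame({"rsid": frame.snps, "ratio": ratios,
                          "precision": 1.0 / se_ratio})
    table.attrs["ivw_beta"] = (ivw(frame).beta if frame.n_snp >= 2
                               else float(ratios[0]))
    return table


@dataclass
class SensitivityReport:
    """The full diagnostic battery for one univariable analysis."""

    q_value: float
    q_df: int
    q_p: float
    i2: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso_global_p: float
    presso_outliers: list[str]
    presso_outlier_pvalues: pd.Series
    presso_distortion_p: float | None
    corrected: MREstimate | None
    loo: pd.DataFrame
    funnel: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flat row shaped like a published sensitivity table."""
        return {
            "Q": self.q_value, "Q_df": self.q_df, "I2_pct": self.i2, "Q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
            "presso_global_p": self.presso_global_p,
            "presso_n_outliers": len(self.presso_outliers),
            "presso_distortion_p": (np.nan if self.presso_distortion_p is None
                                    else self.presso_distortion_p),
            "loo_n_flagged": int(self.loo["flagged"].sum()),
        }


def sensitivity_battery(
    frame: HarmonizedFrame,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_significance: float = 0.05,
) -> SensitivityReport:
    """Assemble Q/I², Egger intercept, outlier procedure, LOO and funnel data."""
    q, df, q_p, i2 = cochran_q(frame)
    egger = mr_egger(frame)
    presso = mr_presso(frame, n_sim=n_sim, seed=seed,
                       outlier_significance=outlier_significance)
    return SensitivityReport(
        q_value=q, q_df=df, q_p=q_p, i2=i2,
        egger_intercept=egger.extras["intercept"],
        egger_intercept_se=egger.extras["intercept_se"],
        egger_intercept_p=egger.extras["intercept_pvalue"],
        presso_global_p=presso.global_p,
        presso_outliers=presso.outliers,
        presso_outlier_pvalues=presso.outlier_pvalues,
        presso_distortion_p=presso.distortion_p,
        corrected=presso.corrected,
        loo=leave_one_out(frame),
        funnel=funnel_data(frame),
        extras={"presso_n_sim": n_sim, "seed": seed},
    )
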