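"""Causal-effect estimators for summary-data Mendelian randomization.

Per-SNP Wald ratios beta_Y/beta_X are pooled by:

* **IVW** — weighted regression of beta_Y on beta_X through the origin with
  weights 1/se_Y²; the default multiplicative random-effects model scales the
  fixed-effect SE by max(1, residual SD), so heterogeneity can widen but
  never narrow the interval.
* **MR-Egger** — the same regression with an intercept after orienting every
  SNP so beta_X >= 0; the slope is the causal estimate under InSIDE and the
  intercept estimates average directional pleiotropy (t test, n-2 df).
* **Weighted median** — the 0.5 point of the inverse-variance-weight-ordered
  ratio estimates (linear interpolation at cumulative weight s_j = S_j -
  w_j/2); consistent while at least half the weight comes from valid
  instruments. SE by parametric bootstrap.

Multivariable variants regress beta_Y on the matrix of exposure effects
jointly, giving each exposure's direct effect conditional on the others
(IVW/Egger by weighted least squares; the median variant by weighted
quantile regression at the 0.5 quantile).

All estimates carry an odds-ratio-scale view exp(beta) with normal-theory
95% limits when the outcome is binary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .harmonization import HarmonizedFrame

log = logging.getLogger(__name__)

__all__ = [
    "MREstimate", "MRResults", "MRModel",
    "wald_ratio", "ivw", "mr_egger", "weighted_median",
    "mvmr_ivw", "mvmr_egger", "mvmr_median", "to_odds_ratio",
]

Z95 = 1.959963984540054  # normal 97.5% point

_P_FLOOR = 1e-300


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


class CollinearityError(ValueError):
    """Exposure effect matrix is rank deficient."""


@dataclass
class MREstimate:
    """One method's causal-effect estimate.

    ``beta`` is on the log-odds scale for binary outcomes; ``or_scale`` is
    the exponentiated (OR, lower, upper) view when applicable. ``extras``
    carries method-specific quantities (Egger intercept and its test,
    residual scale factor, bootstrap replicate count).
    """

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    exposure_id: str | None = None
    or_scale: tuple[float, float, float] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def as_row(self) -> dict:
        row = {
            "method": self.method, "exposure": self.exposure_id, "n_snp": self.n_snp,
            "beta": self.beta, "se": self.se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pvalue": self.pvalue,
        }
        if self.or_scale is not None:
            row["or"], row["or_low"], row["or_high"] = self.or_scale
        return row


def _normal_p(z: float) -> float:
    return float(max(2.0 * _stats.norm.sf(abs(z)), _P_FLOOR))


def _make_estimate(method: str, n_snp: int, beta: float, se: float,
                   pvalue: float | None = None, exposure_id: str | None = None,
                   extras: dict | None = None) -> MREstimate:
    beta, se = float(beta), float(se)
    return MREstimate(
        method=method, n_snp=n_snp, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta / se) if pvalue is None else float(max(pvalue, _P_FLOOR)),
        exposure_id=exposure_id, extras=extras or {},
    )


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Exponentiated view: OR = exp(beta), 95% limits exp(beta -/+ 1.96 se)."""
    return replace(est, or_scale=(float(np.exp(est.beta)),
                                  float(np.exp(est.beta - Z95 * est.se)),
                                  float(np.exp(est.beta + Z95 * est.se))))


def _maybe_or(est: MREstimate, frame: HarmonizedFrame) -> MREstimate:
    return to_odds_ratio(est) if frame.outcome_trait_type == "binary" else est


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_Y/beta_X.

    First-order delta-method SE |se_Y/beta_X|; ``second_order`` adds the
    beta_X uncertainty term, never decreasing the SE.
    """
    if beta_x == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    var = (se_y / beta_x) ** 2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return _make_estimate("wald_ratio", 1, beta, np.sqrt(var))


def _ratios(frame: HarmonizedFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and first-order SEs (univariable frames)."""
    bx = frame.bx
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for beta_x = 0")
    return frame.beta_y / bx, frame.se_y / np.abs(bx)


def _wls_origin(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted regression through the origin: (slope, unscaled SE, residual scale)."""
    sxx = float(np.sum(w * bx * bx))
    slope = float(np.sum(w * bx * by)) / sxx
    resid = by - slope * bx
    n = len(bx)
    scale = np.sqrt(float(np.sum(w * resid**2)) / (n - 1)) if n > 1 else 1.0
    return slope, 1.0 / np.sqrt(sxx), scale


def ivw(frame: HarmonizedFrame, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted pooled estimate (the primary analysis).

    With fewer than two SNPs the single-SNP Wald ratio is returned with a
    logged notice.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError("effects_model must be 'fixed' or 'multiplicative_random'")
    if frame.n_exposures != 1:
        raise ValueError("ivw is univariable; use mvmr_ivw")
    if frame.n_snp < 2:
        log.info("ivw: single instrument; falling back to the Wald ratio")
        est = wald_ratio(frame.bx[0], frame.sx[0], frame.beta_y[0], frame.se_y[0])
        return _maybe_or(replace(est, method="ivw", extras={"fallback": "wald_ratio"}),
                         frame)
    w = 1.0 / frame.se_y**2
    slope, se_fixed, scale = _wls_origin(frame.bx, frame.beta_y, w)
    factor = 1.0 if effects_model == "fixed" else max(1.0, scale)
    est = _make_estimate("ivw", frame.n_snp, slope, se_fixed * factor,
                         extras={"effects_model": effects_model,
                                 "residual_scale": float(scale)})
    return _maybe_or(est, frame)


def mr_egger(frame: HarmonizedFrame) -> MREstimate:
    """MR-Egger regression: slope = causal estimate, intercept = average pleiotropy.

    SNPs are oriented so beta_X >= 0; the intercept test uses a t
    distribution with n-2 degrees of freedom. Intercept quantities live in
    ``extras``.
    """
    if frame.n_exposures != 1:
        raise ValueError("mr_egger is univariable; use mvmr_egger")
    n = frame.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    sign = np.where(frame.bx >= 0, 1.0, -1.0)
    bx, by = sign * frame.bx, sign * frame.beta_y
    w = 1.0 / frame.se_y**2
    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    scale = np.sqrt(float(np.sum(w * resid**2)) / (n - 2))
    factor = max(1.0, scale)
    se = np.sqrt(np.diag(cov_unscaled)) * factor
    intercept, slope = coef
    int_t = intercept / se[0]
    est = _make_estimate(
        "mr_egger", n, slope, se[1],
        extras={
            "intercept": float(intercept),
            "intercept_se": float(se[0]),
            "intercept_pvalue": float(max(2.0 * _stats.t.sf(abs(int_t), n - 2), _P_FLOOR)),
            "residual_scale": float(scale),
        })
    return _maybe_or(est, frame)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: 0.5 point of s_j = S_j - w_j/2."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(frame: HarmonizedFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Weights are inverse-variance weights of the per-SNP ratio estimates; the
    bootstrap redraws beta_X and beta_Y from their sampling distributions and
    recomputes the estimate.
    """
    if frame.n_exposures != 1:
        raise ValueError("weighted_median is univariable; use mvmr_median")
    n = frame.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    ratios, se_ratio = _ratios(frame)
    point = _weighted_median(ratios, 1.0 / se_ratio**2)
    rng = np.random.default_rng(seed)
    bx_star = frame.bx + rng.standard_normal((n_boot, n)) * frame.sx
    by_star = frame.beta_y + rng.standard_normal((n_boot, n)) * frame.se_y
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bx = bx_star[b]
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        reps[b] = _weighted_median(by_star[b] / bx, (bx / frame.se_y) ** 2)
    se = float(np.std(reps, ddof=1))
    est = _make_estimate("weighted_median", n, point, se,
                         extras={"n_boot": n_boot, "seed": seed})
    return _maybe_or(est, frame)


# ---------------------------------------------------------------------------
# multivariable


def _check_design(frame: HarmonizedFrame, min_extra: int) -> None:
    K = frame.n_exposures
    if frame.n_snp < K + min_extra:
        raise InsufficientInstrumentsError(
            f"need at least {K + min_extra} SNPs for {K} exposures, have {frame.n_snp}")
    rank = np.linalg.matrix_rank(frame.beta_x)
    if rank < K:
        sing = np.linalg.svd(frame.beta_x, compute_uv=False)
        raise CollinearityError(
            "exposure effect matrix is rank deficient "
            f"(rank {rank} < {K}; exposures {list(frame.exposure_ids)}; "
            f"smallest singular value {sing[-1]:.3g})")


def _mv_wls(frame: HarmonizedFrame, with_intercept: bool) -> tuple[np.ndarray, np.ndarray, float, int]:
    n, K = frame.n_snp, frame.n_exposures
    X = frame.beta_x
    by = frame.beta_y
    if with_intercept:
        sign = np.where(X[:, 0] >= 0, 1.0, -1.0)
        X = X * sign[:, None]
        by = by * sign
        X = np.column_stack([np.ones(n), X])
    w = 1.0 / frame.se_y**2
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    df = n - X.shape[1]
    scale = np.sqrt(float(np.sum(w * resid**2)) / df)
    se = np.sqrt(np.diag(cov_unscaled)) * max(1.0, scale)
    return coef, se, scale, df


def mvmr_ivw(frame: HarmonizedFrame) -> list[MREstimate]:
    """Multivariable IVW: per-exposure direct effects conditional on the others."""
    _check_design(frame, min_extra=1)
    coef, se, scale, _ = _mv_wls(frame, with_intercept=False)
    out = []
    for k, t in enumerate(frame.exposure_ids):
        est = _make_estimate("mvmr_ivw", frame.n_snp, coef[k], se[k], exposure_id=t,
                             extras={"residual_scale": float(scale)})
        out.append(_maybe_or(est, frame))
    return out


def mvmr_egger(frame: HarmonizedFrame) -> list[MREstimate]:
    """Multivariable MR-Egger; the shared intercept report rides in each extras."""
    _check_design(frame, min_extra=2)
    coef, se, scale, df = _mv_wls(frame, with_intercept=True)
    int_t = coef[0] / se[0]
    intercept = {
        "intercept": float(coef[0]),
        "intercept_se": float(se[0]),
        "intercept_pvalue": float(max(2.0 * _stats.t.sf(abs(int_t), df), _P_FLOOR)),
        "residual_scale": float(scale),
    }
    out = []
    for k, t in enumerate(frame.exposure_ids):
        est = _make_estimate("mvmr_egger", frame.n_snp, coef[k + 1], se[k + 1],
                             exposure_id=t, extras=dict(intercept))
        out.append(_maybe_or(est, frame))
    return out


def _wlad_origin(X: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted median (0.5-quantile) regression through the origin.

    Since the check loss is positively homogeneous, minimising
    sum_j w_j |by_j - x_j b| equals an unweighted quantile regression on the
    w-scaled data.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(w * by, X * w[:, None]).fit(q=0.5, max_iter=2000, p_tol=1e-8)
    return np.asarray(res.params, dtype=float)


def mvmr_median(frame: HarmonizedFrame, n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """Multivariable median regression; SE by seeded parametric bootstrap."""
    _check_design(frame, min_extra=1)
    n, K = frame.n_snp, frame.n_exposures
    w = 1.0 / frame.se_y**2
    coef = _wlad_origin(frame.beta_x, frame.beta_y, w)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, K))
    for b in range(n_boot):
        bx = frame.beta_x + rng.standard_normal((n, K)) * frame.se_x
        by = frame.beta_y + rng.standard_normal(n) * frame.se_y
        try:
            reps[b] = _wlad_origin(bx, by, w)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
            reps[b] = np.nan
    se = np.nanstd(reps, axis=0, ddof=1)
    out = []
    for k, t in enumerate(frame.exposure_ids):
        est = _make_estimate("mvmr_median", n, coef[k], se[k], exposure_id=t,
                             extras={"n_boot": n_boot, "seed": seed})
        out.append(_maybe_or(est, frame))
    return out


# ---------------------------------------------------------------------------
# model / results objects


class MRModel:
    """Two-sample MR model over a harmonized frame.

    ``fit`` dispatches on ``method`` ("ivw", "egger", "weighted_median") and,
    for frames with several exposures, to the multivariable variants.
    """

    UNIVARIABLE = {"ivw": ivw, "egger": mr_egger, "weighted_median": weighted_median}
    MULTIVARIABLE = {"ivw": mvmr_ivw, "egger": mvmr_egger, "weighted_median": mvmr_median}

    def __init__(self, frame: HarmonizedFrame):
        self.frame = frame

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta_x: str | Sequence[str] = "beta_x",
        se_x: str | Sequence[str] = "se_x",
        beta_y: str = "beta_y",
        se_y: str = "se_y",
        rsid: str | None = "rsid",
        outcome_binary: bool = True,
    ) -> "MRModel":
        """Build a model from an already-aligned effects table."""
        bx_cols = [beta_x] if isinstance(beta_x, str) else list(beta_x)
        sx_cols = [se_x] if isinstance(se_x, str) else list(se_x)
        n = len(df)
        snps = (df[rsid].astype(str).to_numpy() if rsid and rsid in df.columns
                else np.array([f"snp_{i}" for i in range(n)], dtype=object))
        frame = HarmonizedFrame(
            snps=snps,
            chrom=np.full(n, "NA", dtype=object), pos=np.zeros(n, dtype=np.int64),
            effect_allele=np.full(n, "A", dtype=object),
            other_allele=np.full(n, "G", dtype=object),
            beta_x=df[bx_cols].to_numpy(dtype=float),
            se_x=df[sx_cols].to_numpy(dtype=float),
            eaf_x=np.full((n, len(bx_cols)), np.nan),
            beta_y=df[beta_y].to_numpy(dtype=float),
            se_y=df[se_y].to_numpy(dtype=float),
            eaf_y=np.full(n, np.nan), n_x=np.full((n, len(bx_cols)), 0.0),
            n_y=np.zeros(n, dtype=np.int64),
            exposure_ids=tuple(bx_cols), outcome_id="outcome",
            outcome_trait_type="binary" if outcome_binary else "continuous",
            actions=pd.DataFrame({"rsid": snps, "action": ["kept_as_is"] * n}),
            dropped=pd.DataFrame(columns=["rsid", "action", "trait"]),
        )
        return cls(frame)

    def fit(self, method: str = "ivw", **kwargs) -> "MRResults":
        table = self.UNIVARIABLE if self.frame.n_exposures == 1 else self.MULTIVARIABLE
        if method not in table:
            raise ValueError(f"unknown method {method!r}; choose from {sorted(table)}")
        result = table[method](self.frame, **kwargs)
        estimates = [result] if isinstance(result, MREstimate) else list(result)
        if estimates[0].exposure_id is None:
            estimates = [replace(e, exposure_id=self.frame.exposure_ids[0])
                         for e in estimates]
        return MRResults(model=self, method=method, estimates=estimates)

    def fit_all(self, methods: Sequence[str] = ("ivw", "egger", "weighted_median"),
                seed: int = 0, n_boot: int = 1000) -> pd.DataFrame:
        rows = []
        for m in methods:
            kw = {"seed": seed, "n_boot": n_boot} if m == "weighted_median" else {}
            rows.append(self.fit(m, **kw).to_frame())
        return pd.concat(rows, ignore_index=True)

    def sensitivity(self, n_sim: int = 1000, seed: int = 0,
                    outlier_significance: float = 0.05):
        """Full heterogeneity/pleiotropy battery (univariable frames)."""
        from . import sensitivity as _sens

        return _sens.sensitivity_battery(self.frame, n_sim=n_sim, seed=seed,
                                         outlier_significance=outlier_significance)


@dataclass
class MRResults:
    """Fit results: per-exposure estimates plus method-specific diagnostics."""

    model: MRModel
    method: str
    estimates: list[MREstimate]

    @property
    def estimate(self) -> MREstimate:
        if len(self.estimates) != 1:
            raise ValueError("multiple exposures; use .estimates or .to_frame()")
        return self.estimates[0]

    # univariable conveniences
    @property
    def beta(self) -> float:
        return self.estimate.beta

    @property
    def se(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    @property
    def odds_ratio(self) -> tuple[float, float, float] | None:
        return self.estimate.or_scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.estimates])

    def summary(self) -> str:
        lines = [f"MR results: {self.method} "
                 f"({self.estimates[0].n_snp} SNPs, outcome "
                 f"{self.model.frame.outcome_id!r})"]
        for e in self.estimates:
            line = (f"  {e.exposure_id:<16} beta={e.beta:+.4f} se={e.se:.4f} "
                    f"95% CI [{e.ci_low:+.4f}, {e.ci_high:+.4f}] p={e.pvalue:.3g}")
            if e.or_scale is not None:
                o, lo, hi = e.or_scale
                line += f"  OR {o:.3f} ({lo:.3f}-{hi:.3f})"
            lines.append(line)
        ex = self.estimates[0].extras
        if "intercept" in ex:
            lines.append(f"  intercept={ex['intercept']:+.4f} "
                         f"se={ex['intercept_se']:.4f} p={ex['intercept_pvalue']:.3g}")
        return "\n".join(lines)
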