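"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the two-sample setting the estimators target: for each
SNP j a true effect on the exposure, gamma_j, a (possibly zero) direct
pleiotropic effect on the outcome, alpha_j, and the induced outcome effect

    Gamma_j = theta * gamma_j + alpha_j

with observed effects drawn around the truth using the standard
summary-statistic error model: se_X = 1/sqrt(2 N_X MAF (1-MAF)) for the
exposure and se_Y = 1/sqrt(2 N_Y cf (1-cf) * 2 MAF (1-MAF)) for a
case-control outcome with case fraction cf (effects directly on the log-odds
scale, no individual-level simulation). The effect allele is reported as the
exposure-increasing allele, as GWAS instrument tables conventionally are;
directional pleiotropy is therefore directional *relative to the exposure*.

Multiple exposures share one outcome: each instrument either loads on a
single exposure (disjoint panels, the univariable four-exposure design) or on
all of them (shared instruments, the multivariable design). Allele bookkeeping
challenges for harmonization — palindromic A/T / G/C pairs and outcome records
stored on the opposite allele — are planted at configurable rates.

Linkage disequilibrium is block-constant: r² = rho² within a block, zero
across blocks, the simplest structure that exercises clumping and proxy
search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .gwas_io import SUMMARY_COLUMNS, LDReference, SummaryStats, TraitAnnotation

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_ld_reference",
    "simulate_study",
    "exposure_se",
    "outcome_se",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                         ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_WITHIN_BLOCK_SPACING_BP = 5_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-sample MR dataset.

    Defaults mirror a well-powered consortium setting: a binary outcome of 211,023
    individuals with 5,668 cases, an exposure GWAS of 410,141, and ~50
    genome-wide-significant instruments whose strength puts the pooled IVW
    standard error near 0.03 and per-SNP F statistics in the tens-to-hundreds.
    """

    n_snps: int = 300
    n_instruments: int = 50
    theta: float = 0.11                    # causal log-odds per exposure unit
    exposure_effect_sd: float = 0.07       # SD of true instrument effects gamma_j
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0           # mean of alpha_j (directional mode)
    pleiotropy_sd: float = 0.01            # SD of alpha_j
    inside_kappa: float = 0.0              # alpha_j = kappa*gamma_j + noise (InSIDE-violating)
    invalid_fraction: float = 1.0          # fraction of instruments receiving pleiotropy
    n_exposure: int = 410_141
    n_outcome: int = 211_023
    outcome_case_fraction: float = 5_668 / 211_023
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.15
    allele_flip_fraction: float = 0.5      # outcome rows stored on the opposite allele
    outlier_indices: tuple[int, ...] = ()
    outlier_offset: float = 0.0            # fixed pleiotropic offset at outlier_indices
    ld_block_size: int = 5
    ld_rho: float = 0.9
    seed: int = 0
    # multi-exposure designs (single-exposure fields describe exposure 1)
    n_exposures: int = 1
    thetas: tuple[float, ...] | None = None
    shared_instruments: bool = False
    # planted confounder annotations
    confounder_indices: tuple[int, ...] = ()
    confounder_trait: str = "smoking"

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_instruments <= 0 or self.ld_block_size <= 0:
            raise ValueError("counts must be positive")
        if self.n_instruments > self.n_snps:
            raise ValueError("n_instruments cannot exceed n_snps")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        for name in ("invalid_fraction", "palindromic_fraction", "allele_flip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.outcome_case_fraction < 1.0:
            raise ValueError("outcome_case_fraction must lie strictly inside (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_exposures < 1:
            raise ValueError("n_exposures must be >= 1")
        if self.thetas is not None and len(self.thetas) != self.n_exposures:
            raise ValueError("thetas must have one entry per exposure")
        n_blocks = -(-self.n_snps // self.ld_block_size)
        if self.n_instruments > n_blocks:
            raise ValueError(
                "n_instruments exceeds the number of LD blocks; clumping could not "
                "retain independent instruments (increase n_snps or decrease ld_block_size)")
        bad = [i for i in self.outlier_indices if not 0 <= i < self.n_snps]
        if bad:
            raise ValueError(f"outlier_indices out of range: {bad}")

    @property
    def effective_thetas(self) -> np.ndarray:
        if self.thetas is not None:
            return np.asarray(self.thetas, dtype=float)
        return np.r_[self.theta, np.zeros(self.n_exposures - 1)]


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated study, for parameter-recovery tests."""

    theta: float | tuple[float, ...]
    gamma: np.ndarray              # (n_snps,) or (n_snps, K)
    alpha: np.ndarray              # (n_snps,)
    invalid_snps: frozenset[int]   # {j : alpha_j != 0}
    outlier_snps: frozenset[int]
    instrument_indices: tuple[int, ...] = ()
    instrument_exposure: tuple[int, ...] = ()  # which exposure each instrument loads on (-1 = all)

    def to_json_dict(self) -> dict:
        return {
            "theta": self.theta if np.isscalar(self.theta) else list(self.theta),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "invalid_snps": sorted(self.invalid_snps),
            "outlier_snps": sorted(self.outlier_snps),
            "instrument_indices": list(self.instrument_indices),
            "instrument_exposure": list(self.instrument_exposure),
        }


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`; iterates as the 4-tuple
    (exposures, outcome, annotation, truth); ``ld`` holds the matching
    LD reference."""

    exposures: list[SummaryStats]
    outcome: SummaryStats
    annotation: TraitAnnotation
    truth: SyntheticTruth
    ld: LDReference

    def __iter__(self) -> Iterator:
        return iter((self.exposures, self.outcome, self.annotation, self.truth))


def exposure_se(cfg: SimConfig, maf: np.ndarray | float) -> np.ndarray | float:
    """Expected exposure-effect standard error at a given MAF."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * cfg.n_exposure * maf * (1.0 - maf))


def outcome_se(cfg: SimConfig, maf: np.ndarray | float) -> np.ndarray | float:
    """Expected outcome-effect standard error at a given MAF (case-control)."""
    maf = np.asarray(maf, dtype=float)
    cf = cfg.outcome_case_fraction
    return 1.0 / np.sqrt(2.0 * cfg.n_outcome * cf * (1.0 - cf) * 2.0 * maf * (1.0 - maf))


def _block_positions(n_snps: int, block_size: int, gap_kb: float = 1_000.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Positions on one chromosome: tight blocks separated by ``gap_kb``."""
    idx = np.arange(n_snps)
    block = idx // block_size
    within = idx % block_size
    span = block_size * _WITHIN_BLOCK_SPACING_BP
    pos = 1 + block * (span + int(gap_kb * 1_000)) + within * _WITHIN_BLOCK_SPACING_BP
    return block, pos.astype(np.int64)


def simulate_ld_reference(
    n_blocks: int,
    block_size: int,
    rho: float,
    inter_block_gap_kb: float = 1_000.0,
    seed: int = 0,
    chrom: str = "1",
    rsid_offset: int = 0,
) -> LDReference:
    """Block-constant LD: r² = rho² within a block, 0 across blocks.

    rsids are ``rs{i+1+rsid_offset}`` in position order, matching the panel
    produced by :func:`simulate_study`. ``seed`` is accepted for interface
    symmetry; the construction is deterministic.
    """
    if n_blocks <= 0 or block_size <= 0:
        raise ValueError("n_blocks and block_size must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    n = n_blocks * block_size
    block, pos = _block_positions(n, block_size, inter_block_gap_kb)
    rsids = [f"rs{i + 1 + rsid_offset}" for i in range(n)]
    ld = LDReference()
    for i in range(n):
        ld.positions[rsids[i]] = (chrom, int(pos[i]))
    r2 = rho * rho
    for b in range(n_blocks):
        members = np.flatnonzero(block == b)
        for i_idx, i in enumerate(members):
            for j in members[i_idx + 1:]:
                ld.set_r2(rsids[i], rsids[int(j)], r2)
    return ld


def _draw_allele_pairs(rng: np.random.Generator, n: int, palindromic: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pick_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    pick_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    for i in range(n):
        pair = _PALINDROMIC_PAIRS[pick_p[i]] if palindromic[i] else _NONPALINDROMIC_PAIRS[pick_np[i]]
        ea[i], oa[i] = pair
    return ea, oa


def _summary_table(rsids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    pval = 2.0 * _stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": np.asarray(eaf, dtype=float), "beta": beta, "se": se,
        "pvalue": pval, "n": np.full(len(beta), n, dtype=np.int64),
    })
    return df[SUMMARY_COLUMNS]


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate exposures, outcome, annotation and ground truth for one study.

    Independent random streams are used for (effects, pleiotropy, allele
    assignment, sampling noise, outcome allele flips, annotation), so that
    e.g. changing ``allele_flip_fraction`` perturbs nothing but the flips.
    Identical config (including seed) gives byte-identical outputs.
    """
    K = cfg.n_exposures
    n = cfg.n_snps
    ss = np.random.SeedSequence(cfg.seed)
    (s_effects, s_pleio, s_maf, s_alleles, s_noise, s_flips, s_layout) = [
        np.random.default_rng(c) for c in ss.spawn(7)]

    # --- panel layout: one instrument per LD block, random slot within block
    block, pos = _block_positions(n, cfg.ld_block_size)
    n_blocks = int(block[-1]) + 1
    rsids = np.array([f"rs{i + 1}" for i in range(n)], dtype=object)
    chrom = np.full(n, "1", dtype=object)
    instr_blocks = np.sort(s_layout.choice(n_blocks, size=cfg.n_instruments, replace=False))
    instruments = np.empty(cfg.n_instruments, dtype=np.int64)
    for k, b in enumerate(instr_blocks):
        members = np.flatnonzero(block == b)
        instruments[k] = s_layout.choice(members)

    # --- true effects
    gamma = np.zeros((n, K))
    if cfg.shared_instruments:
        raw = s_effects.normal(0.0, cfg.exposure_effect_sd, size=(cfg.n_instruments, K))
        # report the exposure-1-increasing allele as the effect allele
        sign = np.where(raw[:, 0] >= 0, 1.0, -1.0)
        gamma[instruments, :] = raw * sign[:, None]
        instr_exposure = tuple([-1] * cfg.n_instruments)
    else:
        assign = np.arange(cfg.n_instruments) % K
        raw = s_effects.normal(0.0, cfg.exposure_effect_sd, size=cfg.n_instruments)
        gamma[instruments, assign] = np.abs(raw)
        instr_exposure = tuple(int(a) for a in assign)

    orienting = gamma[instruments, 0] if cfg.shared_instruments \
        else gamma[instruments, np.arange(cfg.n_instruments) % K]

    alpha = np.zeros(n)
    if cfg.pleiotropy_mode != "none":
        n_invalid = int(round(cfg.invalid_fraction * cfg.n_instruments))
        chosen = s_pleio.choice(cfg.n_instruments, size=n_invalid, replace=False)
        noise = s_pleio.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        if cfg.pleiotropy_mode == "balanced":
            a = noise
        elif cfg.pleiotropy_mode == "directional":
            a = cfg.pleiotropy_mean + noise
        else:  # inside_violating: alpha coupled to instrument strength
            a = cfg.inside_kappa * orienting[chosen] + noise
        alpha[instruments[chosen]] = a
    if cfg.outlier_indices:
        alpha[list(cfg.outlier_indices)] += cfg.outlier_offset

    thetas = cfg.effective_thetas
    big_gamma = gamma @ thetas + alpha

    # --- observed summary statistics
    maf = s_maf.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    eaf = np.where(s_maf.random(n) < 0.5, maf, 1.0 - maf)
    palindromic = s_alleles.random(n) < cfg.palindromic_fraction
    ea, oa = _draw_allele_pairs(s_alleles, n, palindromic)

    se_x = exposure_se(cfg, maf)
    se_y = outcome_se(cfg, maf)
    beta_x_hat = gamma + s_noise.normal(size=(n, K)) * se_x[:, None]
    beta_y_hat = big_gamma + s_noise.normal(size=n) * se_y

    exposures = []
    for k in range(K):
        tab = _summary_table(rsids, chrom, pos, ea, oa, eaf,
                             beta_x_hat[:, k], se_x, cfg.n_exposure)
        exposures.append(SummaryStats(trait_id=f"exposure_{k + 1}",
                                      trait_type="continuous", table=tab))

    flip = s_flips.random(n) < cfg.allele_flip_fraction
    out_ea = np.where(flip, oa, ea)
    out_oa = np.where(flip, ea, oa)
    out_eaf = np.where(flip, 1.0 - eaf, eaf)
    out_beta = np.where(flip, -beta_y_hat, beta_y_hat)
    out_tab = _summary_table(rsids, chrom, pos, out_ea, out_oa, out_eaf,
                             out_beta, se_y, cfg.n_outcome)
    outcome = SummaryStats(trait_id="outcome", trait_type="binary", table=out_tab)

    # --- annotation: planted confounder hits plus benign associations
    rows = []
    for i in cfg.confounder_indices:
        rows.append((rsids[i], cfg.confounder_trait, 1e-12))
    for i in instruments[: min(3, len(instruments))]:
        rows.append((rsids[i], "height", 1e-9))
    annotation = TraitAnnotation(pd.DataFrame(rows, columns=["rsid", "trait", "pvalue"])
                                 if rows else TraitAnnotation.empty().table)

    # --- LD reference matching the panel layout
    ld = simulate_ld_reference(n_blocks, cfg.ld_block_size, cfg.ld_rho)
    extra = n_blocks * cfg.ld_block_size - n
    if extra:  # drop SNP names beyond the panel
        for i in range(n, n_blocks * cfg.ld_block_size):
            name = f"rs{i + 1}"
            ld.positions.pop(name, None)
            ld.entries = {k: v for k, v in ld.entries.items() if name not in k}

    truth = SyntheticTruth(
        theta=float(thetas[0]) if K == 1 else tuple(float(t) for t in thetas),
        gamma=gamma[:, 0] if K == 1 else gamma,
        alpha=alpha,
        invalid_snps=frozenset(int(j) for j in np.flatnonzero(alpha != 0.0)),
        outlier_snps=frozenset(int(j) for j in cfg.outlier_indices
                               if alpha[j] != 0.0),
        instrument_indices=tuple(int(i) for i in instruments),
        instrument_exposure=instr_exposure,
    )
    return SimulatedStudy(exposures=exposures, outcome=outcome,
                          annotation=annotation, truth=truth, ld=ld)
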