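"""Align exposure and outcome effects to a common effect allele.

All traits are aligned to the first exposure's effect allele. Per SNP:

* identical allele pair            -> keep as is;
* swapped pair                     -> negate beta, eaf -> 1 - eaf ("flipped");
* complementary pair (strand
  representation differs)          -> complement, then the two rules above;
* palindromic pair (A/T or G/C)    -> strand cannot be resolved from labels;
  orientation is inferred from allele frequencies when both are available and
  both lie outside the ambiguity band around 0.5 (flip when the frequencies
  fall on opposite sides of 0.5), otherwise the SNP is dropped as ambiguous;
* irreconcilable allele sets       -> dropped as incompatible.

A stricter policy that drops every palindromic SNP is available via
``drop_palindromic=True``. Multivariable harmonization is complete-case: a
SNP missing, ambiguous or incompatible in any trait is dropped everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .gwas_io import COMPLEMENT, SUMMARY_COLUMNS, FormatError, SummaryStats

log = logging.getLogger(__name__)

__all__ = ["HarmonizedFrame", "harmonize", "ACTIONS"]

ACTIONS = (
    "kept_as_is",
    "flipped",
    "palindromic_inferred",
    "dropped_palindromic_ambiguous",
    "dropped_incompatible",
)


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _resolve(ref_ea: str, ref_oa: str, ea: str, oa: str,
             ref_eaf: float, eaf: float,
             band: float, drop_palindromic: bool) -> tuple[int, str]:
    """Orientation of one trait's record against the reference alleles.

    Returns ``(sign, action)``; sign 0 for dropped records.
    """
    if _is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return 0, "dropped_incompatible"
        if drop_palindromic:
            return 0, "dropped_palindromic_ambiguous"
        if np.isnan(ref_eaf) or np.isnan(eaf):
            return 0, "dropped_palindromic_ambiguous"
        if abs(ref_eaf - 0.5) <= band or abs(eaf - 0.5) <= band:
            return 0, "dropped_palindromic_ambiguous"
        # allele labels carry no strand information: orient by frequency side
        same_side = (ref_eaf < 0.5) == (eaf < 0.5)
        return (1 if same_side else -1), "palindromic_inferred"
    pair = (ea, oa)
    comp = (COMPLEMENT.get(ea, "?"), COMPLEMENT.get(oa, "?"))
    if pair == (ref_ea, ref_oa) or comp == (ref_ea, ref_oa):
        return 1, "kept_as_is"
    if pair == (ref_oa, ref_ea) or comp == (ref_oa, ref_ea):
        return -1, "flipped"
    return 0, "dropped_incompatible"


@dataclass
class HarmonizedFrame:
    """SNP-aligned effects: the input to every estimator.

    ``beta_x``/``se_x``/``eaf_x`` have one column per exposure; ``beta_y``,
    ``se_y`` are the outcome effects on the shared effect allele. ``actions``
    records, per retained SNP, how the outcome record was resolved;
    ``dropped`` records every discarded SNP with its reason.
    """

    snps: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    eaf_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_y: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray
    exposure_ids: tuple[str, ...]
    outcome_id: str
    outcome_trait_type: str
    actions: pd.DataFrame
    dropped: pd.DataFrame

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.snps) != 1:
            self.beta_x = self.beta_x.T
        for name in ("se_x", "eaf_x", "n_x"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 1:
                v = v[:, None]
            setattr(self, name, v)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    # 1-D views for the univariable case
    @property
    def bx(self) -> np.ndarray:
        return self.beta_x[:, 0]

    @property
    def sx(self) -> np.ndarray:
        return self.se_x[:, 0]

    @property
    def eaf(self) -> np.ndarray:
        return self.eaf_x[:, 0]

    def subset(self, mask: np.ndarray) -> "HarmonizedFrame":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            m = np.zeros(self.n_snp, dtype=bool)
            m[mask] = True
            mask = m
        return replace(
            self,
            snps=self.snps[mask], chrom=self.chrom[mask], pos=self.pos[mask],
            effect_allele=self.effect_allele[mask], other_allele=self.other_allele[mask],
            beta_x=self.beta_x[mask], se_x=self.se_x[mask], eaf_x=self.eaf_x[mask],
            beta_y=self.beta_y[mask], se_y=self.se_y[mask], eaf_y=self.eaf_y[mask],
            n_x=self.n_x[mask], n_y=self.n_y[mask],
            actions=self.actions[np.asarray(mask)].reset_index(drop=True),
        )

    def exclude(self, rsids: Sequence[str]) -> "HarmonizedFrame":
        bad = set(rsids)
        return self.subset(np.array([s not in bad for s in self.snps]))

    def to_frame(self) -> pd.DataFrame:
        """Audit table: aligned effects plus the per-SNP harmonization action."""
        out = pd.DataFrame({
            "rsid": self.snps, "chrom": self.chrom, "pos": self.pos,
            "effect_allele": self.effect_allele, "other_allele": self.other_allele,
        })
        for k, t in enumerate(self.exposure_ids):
            out[f"beta_{t}"] = self.beta_x[:, k]
            out[f"se_{t}"] = self.se_x[:, k]
        out["eaf"] = self.eaf_x[:, 0]
        out["beta_y"] = self.beta_y
        out["se_y"] = self.se_y
        out["action"] = self.actions["action"].to_numpy()
        return out

    def as_summary_stats(self) -> tuple[list[SummaryStats], SummaryStats]:
        """Rebuild aligned per-trait summary statistics (e.g. for re-harmonizing)."""
        exposures = []
        for k, t in enumerate(self.exposure_ids):
            exposures.append(SummaryStats(trait_id=t, trait_type="continuous",
                                          table=self._table(self.beta_x[:, k],
                                                            self.se_x[:, k],
                                                            self.eaf_x[:, k],
                                                            self.n_x[:, k])))
        outcome = SummaryStats(trait_id=self.outcome_id,
                               trait_type=self.outcome_trait_type,
                               table=self._table(self.beta_y, self.se_y,
                                                 self.eaf_y, self.n_y))
        return exposures, outcome

    def _table(self, beta, se, eaf, n) -> pd.DataFrame:
        pval = np.clip(2.0 * _stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
        df = pd.DataFrame({
            "rsid": self.snps, "chrom": self.chrom, "pos": self.pos,
            "effect_allele": self.effect_allele, "other_allele": self.other_allele,
            "eaf": eaf, "beta": beta, "se": se, "pvalue": pval,
            "n": np.asarray(n, dtype=np.int64),
        })
        return df[SUMMARY_COLUMNS]


def harmonize(
    exposure: SummaryStats | Sequence[SummaryStats],
    outcome: SummaryStats,
    palindromic_eaf_band: float = 0.08,
    drop_palindromic: bool = False,
) -> HarmonizedFrame:
    """Align one or several exposures and the outcome on shared SNPs.

    The first exposure's effect allele is the reference. Complete-case across
    traits; drop reasons are retained in ``HarmonizedFrame.dropped``.
    """
    exposures = [exposure] if isinstance(exposure, SummaryStats) else list(exposure)
    if not exposures:
        raise ValueError("at least one exposure is required")
    traits = exposures + [outcome]
    indexed = []
    for t in traits:
        if t.table["rsid"].duplicated().any():
            raise FormatError(f"duplicate rsids in trait {t.trait_id!r}")
        indexed.append(t.indexed())

    ref = indexed[0]
    shared = [s for s in ref.index if all(s in ix.index for ix in indexed[1:])]
    n_missing = len(ref) - len(shared)
    if n_missing:
        log.info("harmonize: %d SNP(s) of %s missing in another trait (complete-case)",
                 n_missing, exposures[0].trait_id)

    K = len(exposures)
    kept_rows, kept_actions = [], []
    dropped = []
    for s in shared:
        r = ref.loc[s]
        signs = np.ones(len(traits))
        actions = ["kept_as_is"]
        fail = None
        for t_idx in range(1, len(traits)):
            row = indexed[t_idx].loc[s]
            sign, action = _resolve(r["effect_allele"], r["other_allele"],
                                    row["effect_allele"], row["other_allele"],
                                    r["eaf"], row["eaf"],
                                    palindromic_eaf_band, drop_palindromic)
            actions.append(action)
            signs[t_idx] = sign
            if sign == 0:
                fail = (action, traits[t_idx].trait_id)
                break
        if fail is not None:
            dropped.append((s, fail[0], fail[1]))
            continue
        bx = np.empty(K); sx = np.empty(K); fx = np.empty(K); nx = np.empty(K)
        for k in range(K):
            row = indexed[k].loc[s]
            sign = signs[k]
            bx[k] = sign * row["beta"]
            sx[k] = row["se"]
            fx[k] = row["eaf"] if sign > 0 else 1.0 - row["eaf"]
            nx[k] = row["n"]
        orow = indexed[-1].loc[s]
        osign = signs[-1]
        kept_rows.append((s, r["chrom"], r["pos"], r["effect_allele"], r["other_allele"],
                          bx, sx, fx, nx,
                          osign * orow["beta"], orow["se"],
                          orow["eaf"] if osign > 0 else 1.0 - orow["eaf"], orow["n"]))
        kept_actions.append(actions[-1])

    if not kept_rows:
        raise ValueError("no SNP survived harmonization")

    cols = list(zip(*kept_rows))
    frame = HarmonizedFrame(
        snps=np.array(cols[0], dtype=object),
        chrom=np.array(cols[1], dtype=object),
        pos=np.array(cols[2], dtype=np.int64),
        effect_allele=np.array(cols[3], dtype=object),
        other_allele=np.array(cols[4], dtype=object),
        beta_x=np.vstack(cols[5]), se_x=np.vstack(cols[6]), eaf_x=np.vstack(cols[7]),
        n_x=np.vstack(cols[8]),
        beta_y=np.array(cols[9], dtype=float), se_y=np.array(cols[10], dtype=float),
        eaf_y=np.array(cols[11], dtype=float), n_y=np.array(cols[12], dtype=np.int64),
        exposure_ids=tuple(e.trait_id for e in exposures),
        outcome_id=outcome.trait_id,
        outcome_trait_type=outcome.trait_type,
        actions=pd.DataFrame({"rsid": list(cols[0]), "action": kept_actions}),
        dropped=pd.DataFrame(dropped, columns=["rsid", "action", "trait"]),
    )
    if len(frame.dropped):
        log.info("harmonize: dropped %d SNP(s): %s", len(frame.dropped),
                 frame.dropped["action"].value_counts().to_dict())
    return frame
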