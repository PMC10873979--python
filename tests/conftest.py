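"""Shared fixtures: synthetic frames with known truth and hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from summstat_mr.estimators import MRModel
from summstat_mr.harmonization import harmonize
from summstat_mr.synthetic_data import SimConfig, simulate_study


def _instrument_frame(cfg: SimConfig):
    """Harmonized frame over the true instruments of a simulated study."""
    study = simulate_study(cfg)
    inst = [f"rs{i + 1}" for i in study.truth.instrument_indices]
    exposures = [e.subset(inst) for e in study.exposures]
    exp = exposures if len(exposures) > 1 else exposures[0]
    return harmonize(exp, study.outcome.subset(inst)), study


@pytest.fixture
def instrument_frame():
    """Factory: SimConfig -> (HarmonizedFrame, SimulatedStudy)."""
    return _instrument_frame


def _random_frame(rng: np.random.Generator, n: int, K: int = 1,
                  theta: float = 0.1) -> MRModel:
    """Aligned-effects model with heterogeneous weights, for oracle checks."""
    bx = rng.normal(0.06, 0.03, size=(n, K))
    bx[np.abs(bx) < 1e-3] = 1e-3
    se_x = rng.uniform(0.002, 0.01, size=(n, K))
    se_y = rng.uniform(0.01, 0.05, size=n)
    by = bx @ np.full(K, theta) + rng.normal(size=n) * se_y
    df = pd.DataFrame({f"bx{k}": bx[:, k] for k in range(K)}
                      | {f"sx{k}": se_x[:, k] for k in range(K)}
                      | {"beta_y": by, "se_y": se_y})
    return MRModel.from_dataframe(
        df, beta_x=[f"bx{k}" for k in range(K)],
        se_x=[f"sx{k}" for k in range(K)])


@pytest.fixture
def random_frame():
    """Factory: (rng, n, K) -> MRModel over a random aligned frame."""
    return _random_frame


@pytest.fixture
def frame_from_arrays():
    """Factory building a univariable MRModel from explicit arrays."""

    def build(bx, se_x, by, se_y, outcome_binary=True) -> MRModel:
        df = pd.DataFrame({"beta_x": bx, "se_x": se_x,
                           "beta_y": by, "se_y": se_y})
        return MRModel.from_dataframe(df, outcome_binary=outcome_binary)

    return build


def summary_table(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-statistics table from terse row dicts."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.05, "se": 0.005,
                "pvalue": 1e-20, "n": 100_000}
    columns = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "beta", "se", "pvalue", "n"]
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, pos=1000 + 10_000 * i, rsid=f"rs{i + 1}")
        r.update(row)
        full.append(r)
    if not full:
        return pd.DataFrame(columns=columns).astype(
            {"pos": np.int64, "eaf": float, "beta": float, "se": float,
             "pvalue": float, "n": np.int64})
    return pd.DataFrame(full)[columns]


@pytest.fixture
def make_summary():
    """Factory: row dicts -> SummaryStats."""
    from summstat_mr.gwas_io import SummaryStats

    def build(rows, trait_id="exp", trait_type="continuous"):
        return SummaryStats(trait_id=trait_id, trait_type=trait_type,
                            table=summary_table(rows))

    return build
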