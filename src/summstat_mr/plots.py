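"""Quick-look plots (optional; requires matplotlib).

The package's primary outputs are the data tables; these helpers render the
conventional diagnostic views from them.
"""

from __future__ import annotations

import pandas as pd

from .harmonization import HarmonizedFrame
from .sensitivity import funnel_data


def funnel_plot(frame: HarmonizedFrame, ax=None):
    """Per-SNP ratio vs precision with the pooled IVW reference line."""
    import matplotlib.pyplot as plt

    data = funnel_data(frame)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(data["ratio"], data["precision"], s=12, alpha=0.7)
    ax.axvline(data.attrs["ivw_beta"], color="crimson", lw=1, label="IVW")
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.set_ylabel("precision (1/SE)")
    ax.legend(frameon=False)
    return ax


def forest_plot(results: pd.DataFrame, ax=None):
    """Forest view of a results table (columns: exposure, method, or, or_low, or_high)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(results) + 1))
    labels = [f"{r.exposure} [{r.method}]" for r in results.itertuples()]
    y = range(len(results))[::-1]
    ax.errorbar(results["or"], list(y),
                xerr=[results["or"] - results["or_low"],
                      results["or_high"] - results["or"]],
                fmt="o", ms=4, capsize=2)
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    ax.set_yticks(list(y), labels)
    ax.set_xlabel("odds ratio (95% CI)")
    return ax
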