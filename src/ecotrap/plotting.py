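"""Convenience plots of sweep output (abundance vs proportion controlled).

These render figure analogues from the sweep CSVs; they are a viewing
aid, not part of the tested surface.  matplotlib is imported lazily so
the core package works without it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_abundance_vs_prop"]


def plot_abundance_vs_prop(df: pd.DataFrame, ax=None, patch: str = "controlled"):
    """Mean patch abundance against proportion of area controlled.

    One line per (control level, gamma) combination.  ``patch`` selects
    the controlled ("Nc") or uncontrolled ("Nu") series.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    col = {"controlled": "mean_Nc", "uncontrolled": "mean_Nu"}[patch]
    if ax is None:
        _, ax = plt.subplots()
    for (ctrl, gamma), sub in df.groupby(["control", "gamma"]):
        sub = sub.sort_values("prop_controlled")
        ax.plot(sub.prop_controlled * 100, sub[col], marker="o",
                label=f"control={ctrl}, gamma={gamma}")
    ax.set_xlabel("Proportion of area controlled (%)")
    ax.set_ylabel(f"Mean abundance, {patch} patch")
    ax.legend(fontsize=8)
    return ax
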