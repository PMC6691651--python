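"""Plotting helpers for longitudinal lesion-volume data."""

from __future__ import annotations

import pandas as pd

from .stats import summarize_longitudinal

__all__ = ["plot_longitudinal"]


def plot_longitudinal(records: pd.DataFrame, modality: str, ax=None):
    """Mean +/- SD lesion volume over weeks, one errorbar series per scheme."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summary = summarize_longitudinal(records)
    summary = summary[summary["modality"] == modality]
    for scheme, sub in summary.groupby("scheme_label"):
        sub = sub.sort_values("week")
        ax.errorbar(
            sub["week"], sub["mean"], yerr=sub["sd"].fillna(0.0),
            marker="o", capsize=3, label=str(scheme),
        )
    ax.set_xlabel("weeks post-irradiation")
    ax.set_ylabel("lesion volume (mm$^3$)")
    ax.set_title(f"{modality} lesion progression")
    ax.legend(fontsize="small")
    return ax
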