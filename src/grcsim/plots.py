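"""Optional figure analogues (requires the ``plot`` extra: matplotlib).

Thin helpers over the experiment tables; nothing here is needed for the
simulations themselves.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_beam_trials(summary: pd.DataFrame, path: str | Path) -> None:
    """Scatter of per-trial middle-beam totals: unregulated, regulated, full-input."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(summary["trial"], summary["unregulated_total"], s=12, c="k", marker="s",
               label="meet threshold (no Golgi regulation)")
    ax.scatter(summary["trial"], summary["regulated_total"], s=12, c="tab:blue",
               label="fire under Golgi regulation")
    ax.scatter(summary["trial"], summary["full_input_total"], s=12, c="tab:pink",
               label="input to all dendrites")
    ax.set_xlabel("trial")
    ax.set_ylabel("granule cells per beam")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rate_recoding(rates: np.ndarray, sample_means: np.ndarray,
                       top_slice: np.ndarray, path: str | Path) -> None:
    """Histograms of mossy-fiber rates, granule sample means, and the top slice."""
    plt = _plt()
    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharex=True)
    for ax, data, title in zip(
        axes,
        (rates, sample_means, top_slice),
        ("mossy-fiber rates", "sample means", "top slice"),
    ):
        ax.hist(data, bins=30, color="tab:blue")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("Hz")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlap_spectra(table: pd.DataFrame, path: str | Path) -> None:
    """Analytic overlap proportions against the number of other stored patterns."""
    plt = _plt()
    p_values = sorted(table["p_active"].unique(), reverse=True)
    fig, axes = plt.subplots(1, len(p_values), figsize=(3 * len(p_values), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, p in zip(axes, p_values):
        sub = table[table["p_active"] == p]
        for k in sorted(sub["k"].unique()):
            line = sub[sub["k"] == k]
            ax.plot(line["n_other"], line["analytic_proportion"], label=f"k={k}", lw=1)
        ax.set_title(f"p = {p:g}", fontsize=9)
        ax.set_xlabel("other stored patterns")
    axes[0].set_ylabel("proportion of synapses")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
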