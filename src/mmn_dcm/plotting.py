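"""Figure helpers for group results and evoked summaries."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_bma_effects", "plot_repetition_profile"]


def plot_bma_effects(bma, regressor: str = "group", path=None,
                     pp_threshold: float = 0.95):
    """Bar plot of BMA effect sizes with posterior-probability annotations.

    Bars show the averaged effect per parameter for one regressor; filled
    bars exceed the ``Pp`` threshold.  Returns the figure.
    """
    t = bma.table()
    t = t[t.regressor == regressor]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(t)), 3.2))
    colors = ["C0" if pp > pp_threshold else "lightgray" for pp in t.pp]
    ax.bar(range(len(t)), t.effect, yerr=t["sd"], color=colors, capsize=2)
    for i, (e, pp) in enumerate(zip(t.effect, t.pp)):
        ax.annotate(f"{pp:.2f}", (i, e), textcoords="offset points",
                    xytext=(0, 6 if e >= 0 else -12), ha="center",
                    fontsize=7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(range(len(t)))
    ax.set_xticklabels(t.parameter, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel(f"{regressor} effect (log scale)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_repetition_profile(window_gfp: np.ndarray, labels, path=None):
    """Per-condition mismatch-window amplitudes (deviant .. rep5)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(range(len(window_gfp)), window_gfp, "o-")
    ax.set_xticks(range(len(window_gfp)))
    ax.set_xticklabels(labels, rotation=45)
    ax.set_ylabel("mean window GFP")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
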