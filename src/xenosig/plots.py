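"""Basic figure output: Kaplan-Meier step curves and volcano plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import SurvivalCurve

__all__ = ["km_plot", "volcano_plot"]


def km_plot(curves: dict[str, SurvivalCurve], path, title: str = "") -> None:
    """Step plot of one KM curve per named group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.surv])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(
    results: pd.DataFrame,
    path,
    effect_col: str = "log2fc",
    p_col: str = "adj_p",
    effect_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    title: str = "",
) -> None:
    """Effect size vs -log10 adjusted p, with threshold guides."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = results[effect_col].to_numpy()
    y = -np.log10(np.maximum(results[p_col].to_numpy(), 1e-300))
    sig = (np.abs(x) >= effect_cutoff) & (results[p_col].to_numpy() < p_cutoff)
    ax.scatter(x[~sig], y[~sig], s=4, c="grey", alpha=0.5)
    ax.scatter(x[sig], y[sig], s=6, c="crimson")
    ax.axhline(-np.log10(p_cutoff), ls="--", lw=0.8, c="k")
    for v in (-effect_cutoff, effect_cutoff):
        ax.axvline(v, ls="--", lw=0.8, c="k")
    ax.set_xlabel(effect_col)
    ax.set_ylabel(f"-log10({p_col})")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
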