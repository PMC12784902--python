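"""Report figures: MAD barplot, per-fly strip plots with group medians.

Because the headline quantity is a dispersion estimate with a bootstrap
standard error (not a full raw distribution), group variability is shown as
a barplot with error bars; the per-fly bias and activity panels show every
individual as a dot with a horizontal group-median line and compact
letter display from the BH-adjusted pairwise tests (groups sharing a letter
do not differ significantly).
"""

from __future__ import annotations

from itertools import combinations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["significance_letters", "mad_barplot", "strip_plot"]


def significance_letters(
    labels: list[str], pairwise: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from a table of adjusted pairwise p-values.

    ``pairwise`` needs columns ``group_a``, ``group_b`` and ``p_adjusted``.
    Standard insert-and-absorb sweep: groups sharing a letter are not
    significantly different at ``alpha``.
    """
    sig = set()
    for _, row in pairwise.iterrows():
        if row["p_adjusted"] < alpha:
            sig.add(frozenset((row["group_a"], row["group_b"])))

    # letter sets: start with one set holding everything, split on conflicts
    sets: list[set[str]] = [set(labels)]
    for a, b in (tuple(s) for s in sig):
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: sorted(labels).index(min(s)))
    letters = {lab: "" for lab in labels}
    for i, s in enumerate(sets):
        for lab in sorted(s):
            letters[lab] += chr(ord("a") + i)
    return letters


def mad_barplot(group_variability: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Barplot of group MADs with bootstrap-SE error bars."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    gv = group_variability
    ax.bar(gv["treatment"], gv["mad"], yerr=gv["boot_se"], capsize=4,
           color="#7a9ec9", edgecolor="black")
    ax.set_ylabel("MAD of right-turn proportion")
    ax.set_xlabel("treatment")
    ax.set_title("Turn-bias variability (error bars: bootstrap SE)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def strip_plot(
    summaries: pd.DataFrame,
    value_col: str,
    path,
    pairwise: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ylabel: str | None = None,
    rng_seed: int = 0,
) -> None:
    """Per-fly dots with group-median lines and optional significance letters."""
    rng = np.random.default_rng(rng_seed)
    labels = sorted(summaries["treatment"].unique())
    letters = (
        significance_letters(labels, pairwise, alpha) if pairwise is not None else None
    )
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    top = summaries[value_col].max()
    for i, lab in enumerate(labels):
        vals = summaries.loc[summaries["treatment"] == lab, value_col].to_numpy()
        x = i + rng.uniform(-0.18, 0.18, size=vals.size)
        ax.plot(x, vals, ".", color="#666666", alpha=0.35, markersize=3)
        ax.hlines(np.median(vals), i - 0.3, i + 0.3, color="crimson", linewidth=2)
        if letters is not None:
            ax.text(i, top * 1.04, letters[lab], ha="center", fontsize=11)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel(ylabel or value_col)
    ax.set_xlabel("treatment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
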