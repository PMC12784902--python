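"""Group-level mean and activity comparisons.

Secondary analyses around the dispersion statistic: a one-way fixed-effects
ANOVA on per-fly right-turn proportion (does any diet shift mean bias?),
with Shapiro-Wilk and Brown-Forsythe/Levene diagnostics attached, and a
tie-corrected Kruskal-Wallis omnibus on turns per minute followed by
pairwise two-sided Mann-Whitney U tests with Benjamini-Hochberg adjustment.

The rank tests and the BH step-up are delegated to scipy/statsmodels; the
exact Mann-Whitney branch (small tie-free samples) is selected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmnibusResult",
    "anova_bias",
    "kruskal_activity",
    "mann_whitney_u",
    "bh_adjust",
    "pairwise_activity_tests",
]

#: largest per-group n for which the exact (enumeration) MWU null is used
_EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class OmnibusResult:
    """Result of a k-group omnibus test (ANOVA or Kruskal-Wallis)."""

    test: str  # "anova" | "kruskal_wallis"
    statistic: float
    df1: int
    df2: int | None
    p_value: float
    diagnostics: dict = field(default_factory=dict)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def anova_bias(
    flies: pd.DataFrame | Mapping[str, Sequence[float]],
    value_col: str = "prop_right",
) -> OmnibusResult:
    """One-way fixed-effects ANOVA on per-fly turn bias across treatments.

    Accepts either a fly-summary DataFrame (grouped on ``treatment``) or a
    mapping label -> values.  Residual normality (Shapiro-Wilk) and
    homoscedasticity (Levene with median centering, the Brown-Forsythe
    form) are reported as diagnostics, not gates: the F test is computed
    regardless.
    """
    if isinstance(flies, pd.DataFrame):
        groups = {k: g[value_col].to_numpy(dtype=float) for k, g in flies.groupby("treatment")}
    else:
        groups = _as_groups(flies)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = list(groups.values())
    if any(a.size < 2 for a in arrays):
        sizes = {k: v.size for k, v in groups.items()}
        raise ValueError(f"each group needs >= 2 observations, got sizes {sizes}")

    f_stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    resid = np.concatenate([a - a.mean() for a in arrays])
    sh_stat, sh_p = sps.shapiro(resid)
    lv_stat, lv_p = sps.levene(*arrays, center="median")
    return OmnibusResult(
        test="anova",
        statistic=float(f_stat),
        df1=k - 1,
        df2=n - k,
        p_value=float(p),
        diagnostics={
            "shapiro_stat": float(sh_stat),
            "shapiro_p": float(sh_p),
            "levene_stat": float(lv_stat),
            "levene_p": float(lv_p),
        },
    )


def kruskal_activity(groups) -> OmnibusResult:
    """Tie-corrected Kruskal-Wallis H on turns-per-minute samples.

    ``groups`` is a mapping label -> values or a sequence of samples.  The
    statistic is divided by the tie correction 1 - sum(t^3 - t)/(N^3 - N)
    and referred to a chi-square with k - 1 df.  If every observation is
    identical the correction degenerates; H = 0, p = 1 is returned.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError(f"need >= 2 groups, got {len(g)}")
    arrays = list(g.values())
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return OmnibusResult(test="kruskal_wallis", statistic=0.0, df1=len(g) - 1,
                             df2=None, p_value=1.0)
    h, p = sps.kruskal(*arrays)
    return OmnibusResult(
        test="kruskal_wallis", statistic=float(h), df1=len(g) - 1, df2=None, p_value=float(p)
    )


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group a versus group b.

    The exact null distribution is used when min(n_a, n_b) <= 8 and the
    pooled sample is tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  Returns (U, p) where
    U counts (a > b) pairs plus half-ties.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= _EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_values: all values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_activity_tests(
    summaries: pd.DataFrame | Mapping[str, Sequence[float]],
    value_col: str = "turns_per_min",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests on activity with one BH family.

    All pairwise comparisons among the treatment groups are treated as a
    single multiple-testing family.
    """
    if isinstance(summaries, pd.DataFrame):
        groups = {k: g[value_col].to_numpy(dtype=float) for k, g in summaries.groupby("treatment")}
    else:
        groups = _as_groups(summaries)
    rows = []
    for la, lb in combinations(sorted(groups), 2):
        u, p = mann_whitney_u(groups[la], groups[lb])
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "median_a": float(np.median(groups[la])),
                "median_b": float(np.median(groups[lb])),
                "u_statistic": u,
                "p_raw": p,
                "method": "mann_whitney_bh",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out
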