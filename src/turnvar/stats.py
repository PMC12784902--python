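"""Turn-bias predictability statistics: MAD, permutation test, bootstrap.

The object of study is inter-individual variability of turn bias.  Each
fly's bias is the proportion of right turns among its arm-to-arm decisions
(right coded 1, left 0); the group-level dispersion of these per-fly
proportions is summarized by the raw median absolute deviation

    MAD(x) = median_i | x_i - median(x) |

with no consistency scaling constant, since the values are proportions and
no normality is assumed.  A low MAD means the cohort behaves predictably
(individuals are alike); a high MAD means strong individuality.

Group contrasts use a label-permutation test on the MAD difference
(exchangeability of flies under the null) with an add-one p-value
p = (1 + #{extreme}) / (1 + n_iter), and uncertainty on each group's MAD
comes from a fly-level percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import bh_adjust

__all__ = [
    "summarize_flies",
    "group_mad",
    "per_fly_choice_mad",
    "perm_test_mad",
    "bootstrap_mad",
    "group_variability",
    "pairwise_mad_tests",
    "PermutationResult",
    "BootstrapResult",
]

_ALTERNATIVES = ("two_sided", "less", "greater")


# ---------------------------------------------------------------------------
# per-fly summaries


def summarize_flies(
    events: pd.DataFrame,
    observation_minutes: float = 120.0,
    min_turns: int = 10,
    roster: pd.DataFrame | None = None,
    include_choice_mad: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a turn-event table into one row per analyzable fly.

    Parameters
    ----------
    events
        Tidy table with columns ``fly_id``, ``treatment``, ``time_s``,
        ``direction`` (values 'L'/'R').
    observation_minutes
        Session length used as the turns/min denominator (whole-session
        convention; per-fly tracked time is not modelled).
    min_turns
        Inclusion threshold: flies with fewer scored turns are excluded and
        reported in the QC table, since a bias proportion from a handful of
        turns is dominated by binomial noise.
    roster
        Optional fly roster (``fly_id``, ``treatment``); flies present in
        the roster but absent from ``events`` are reported as excluded with
        zero turns rather than silently dropped.
    include_choice_mad
        Also compute each fly's within-sequence MAD of its own 0/1 choice
        codes.  For binary data this statistic is degenerate (it is 0
        whenever one direction holds a strict majority) and is provided for
        comparison only; group-level dispersion uses ``prop_right``.

    Returns
    -------
    summaries, excluded
        ``summaries``: ``fly_id``, ``treatment``, ``n_turns``,
        ``prop_right``, ``turns_per_min`` (plus ``choice_mad`` on request).
        ``excluded``: ``fly_id``, ``treatment``, ``n_turns``, ``reason``.
    """
    if observation_minutes <= 0:
        raise ValueError(f"observation_minutes: must be positive, got {observation_minutes}")
    required = {"fly_id", "treatment", "time_s", "direction"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events: missing required columns {sorted(missing)}")
    bad = set(events["direction"].unique()) - {"L", "R"}
    if bad:
        raise ValueError(f"events: direction values outside {{L, R}}: {sorted(map(str, bad))}")
    dup = events.duplicated(subset=["fly_id", "time_s"], keep=False)
    if dup.any():
        rows = events.index[dup].tolist()
        raise ValueError(
            f"events: duplicate (fly_id, time_s) rows at index {rows[:20]}"
            + (" ..." if len(rows) > 20 else "")
        )

    rows = []
    for (fly, treatment), grp in events.groupby(["fly_id", "treatment"], sort=True):
        d = grp["direction"].to_numpy()
        rec = {
            "fly_id": fly,
            "treatment": treatment,
            "n_turns": len(grp),
            "prop_right": float(np.mean(d == "R")),
            "turns_per_min": len(grp) / observation_minutes,
        }
        if include_choice_mad:
            rec["choice_mad"] = group_mad((d == "R").astype(float))
        rows.append(rec)
    cols = ["fly_id", "treatment", "n_turns", "prop_right", "turns_per_min"]
    if include_choice_mad:
        cols.append("choice_mad")
    per_fly = pd.DataFrame(rows, columns=cols)

    if roster is not None:
        seen = set(per_fly["fly_id"])
        zero = roster.loc[~roster["fly_id"].isin(seen), ["fly_id", "treatment"]].copy()
        zero["n_turns"] = 0
        zero["prop_right"] = np.nan
        zero["turns_per_min"] = 0.0
        if include_choice_mad:
            zero["choice_mad"] = np.nan
        per_fly = pd.concat([per_fly, zero[cols]], ignore_index=True)
        per_fly = per_fly.sort_values(["treatment", "fly_id"], ignore_index=True)

    keep = per_fly["n_turns"] >= min_turns
    excluded = per_fly.loc[~keep, ["fly_id", "treatment", "n_turns"]].copy()
    excluded["reason"] = "insufficient_turns"
    return per_fly.loc[keep].reset_index(drop=True), excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# MAD


def group_mad(values) -> float:
    """Raw median absolute deviation, median(|x - median(x)|).

    The sample median uses the midpoint-of-middle-two convention for even n.
    No consistency constant (1.4826) is applied: the statistic stays on the
    scale of the data, here right-turn proportions.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values: at least one value required")
    if not np.all(np.isfinite(x)):
        raise ValueError("values: all values must be finite")
    return float(np.median(np.abs(x - np.median(x))))


def per_fly_choice_mad(directions) -> float:
    """MAD of a single fly's 0/1 choice codes (degenerate for binary data)."""
    d = np.asarray(directions)
    codes = (d == "R").astype(float) if d.dtype.kind in "OUS" else d.astype(float)
    return group_mad(codes)


def _mad_rows(m: np.ndarray) -> np.ndarray:
    med = np.median(m, axis=1, keepdims=True)
    return np.median(np.abs(m - med), axis=1)


# ---------------------------------------------------------------------------
# permutation test


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-permutation test on a MAD difference."""

    group_a: str
    group_b: str
    stat_observed: float  # MAD_a - MAD_b
    p_value: float
    n_iter: int
    alternative: str
    seed: int
    null_quantiles: dict = field(default_factory=dict)


def perm_test_mad(
    values_a,
    values_b,
    n_iter: int = 10_000,
    alternative: str = "two_sided",
    seed: int = 0,
    labels: tuple[str, str] = ("a", "b"),
    _chunk: int = 2_000,
) -> PermutationResult:
    """Permutation test for a difference in MAD between two groups.

    Pooled values are reassigned uniformly at random to groups of the
    original sizes ``n_iter`` times and the statistic MAD_a - MAD_b is
    recomputed each time.  The add-one estimator
    p = (1 + #{extreme}) / (1 + n_iter) guarantees p in (0, 1] and valid
    type-I control.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 values to compare dispersion, got {a.size} and {b.size}"
        )
    if n_iter < 1:
        raise ValueError(f"n_iter: must be >= 1, got {n_iter}")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative: must be one of {_ALTERNATIVES}, got {alternative!r}")

    obs = group_mad(a) - group_mad(b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    rng = np.random.default_rng(seed)

    null = np.empty(n_iter)
    done = 0
    while done < n_iter:
        m = min(_chunk, n_iter - done)
        # row-wise uniform random permutations via argsort of iid uniforms
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[order]
        null[done : done + m] = _mad_rows(perm[:, :na]) - _mad_rows(perm[:, na:])
        done += m

    # permutations whose statistic equals the observed one in exact arithmetic
    # can land an ulp away after two median subtractions; count such numerical
    # ties as extreme (conservative, keeps the test valid)
    tol = 1e-12
    if alternative == "two_sided":
        extreme = np.abs(null) >= abs(obs) - tol
    elif alternative == "less":
        extreme = null <= obs + tol
    else:
        extreme = null >= obs - tol
    p = (1 + int(extreme.sum())) / (1 + n_iter)

    qs = np.percentile(null, [2.5, 25.0, 50.0, 75.0, 97.5])
    return PermutationResult(
        group_a=labels[0],
        group_b=labels[1],
        stat_observed=float(obs),
        p_value=float(p),
        n_iter=int(n_iter),
        alternative=alternative,
        seed=int(seed),
        null_quantiles={
            "q2.5": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
            "q75": float(qs[3]), "q97.5": float(qs[4]),
        },
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    """Fly-level percentile bootstrap of a group MAD."""

    mad: float
    boot_se: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_mad(values, n_boot: int = 10_000, seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap (resampling flies with replacement) of group MAD.

    Returns the bootstrap standard error (SD of resampled MADs) and the
    2.5/97.5 percentile interval.  Degenerate input (all values identical)
    yields SE 0 and a zero-width interval rather than an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"values: need >= 2 values to bootstrap, got {x.size}")
    if n_boot < 100:
        raise ValueError(f"n_boot: must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    mads = _mad_rows(x[idx])
    lo, hi = np.percentile(mads, [2.5, 97.5])
    return BootstrapResult(
        mad=group_mad(x),
        boot_se=float(np.std(mads, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=int(n_boot),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# group-level tables


def group_variability(
    summaries: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    value_col: str = "prop_right",
) -> pd.DataFrame:
    """Per-group MAD of per-fly turn bias with bootstrap SE and 95% CI."""
    rows = []
    for gi, (label, grp) in enumerate(sorted(summaries.groupby("treatment"))):
        boot = bootstrap_mad(grp[value_col].to_numpy(), n_boot=n_boot, seed=seed + gi)
        rows.append(
            {
                "treatment": label,
                "n_flies": len(grp),
                "mad": boot.mad,
                "boot_se": boot.boot_se,
                "ci_low": boot.ci_low,
                "ci_high": boot.ci_high,
                "n_boot": boot.n_boot,
                "seed": boot.seed,
            }
        )
    return pd.DataFrame(rows)


def pairwise_mad_tests(
    summaries: pd.DataFrame,
    n_iter: int = 10_000,
    alternative: str = "two_sided",
    seed: int = 0,
    value_col: str = "prop_right",
) -> pd.DataFrame:
    """All pairwise MAD permutation tests, with raw and BH-adjusted p-values.

    The pairwise tests form one family; both the raw and the
    Benjamini-Hochberg adjusted p-values are reported.
    """
    groups = {k: g[value_col].to_numpy() for k, g in summaries.groupby("treatment")}
    rows = []
    for i, (la, lb) in enumerate(combinations(sorted(groups), 2)):
        res = perm_test_mad(
            groups[la], groups[lb], n_iter=n_iter, alternative=alternative,
            seed=seed + i, labels=(la, lb),
        )
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "mad_a": group_mad(groups[la]),
                "mad_b": group_mad(groups[lb]),
                "stat_observed": res.stat_observed,
                "p_raw": res.p_value,
                "n_iter": res.n_iter,
                "alternative": res.alternative,
                "seed": res.seed,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out
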