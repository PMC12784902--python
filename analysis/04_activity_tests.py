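#!/usr/bin/env python
"""Secondary comparisons: mean turn bias (ANOVA) and activity (rank tests).

Reads the fly summaries written by 03_turn_bias_variability.py and runs the
one-way ANOVA on right-turn proportion (with Shapiro-Wilk and
Brown-Forsythe diagnostics), the tie-corrected Kruskal-Wallis omnibus on
turns per minute, and BH-adjusted pairwise Mann-Whitney tests.  Tables go
to results/analysis/.
"""

import argparse
from pathlib import Path

import pandas as pd

from turnvar import anova_bias, kruskal_activity, pairwise_activity_tests


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summaries", type=Path,
                    default=Path("results/analysis/fly_summaries.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    summaries = pd.read_csv(args.summaries)

    an = anova_bias(summaries)
    print(f"turn bias, one-way ANOVA: F({an.df1},{an.df2}) = {an.statistic:.3f}, "
          f"p = {an.p_value:.4f}")
    print(f"  residual normality (Shapiro-Wilk) p = {an.diagnostics['shapiro_p']:.3g}; "
          f"homoscedasticity (Brown-Forsythe) p = {an.diagnostics['levene_p']:.3g}")

    groups = {k: g["turns_per_min"].to_numpy() for k, g in summaries.groupby("treatment")}
    kw = kruskal_activity(groups)
    print(f"turns/min, Kruskal-Wallis: H = {kw.statistic:.2f}, df = {kw.df1}, "
          f"p = {kw.p_value:.4f}")

    pairwise = pairwise_activity_tests(summaries)
    print("\nPairwise Mann-Whitney (BH-adjusted):")
    print(pairwise.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    args.out.mkdir(parents=True, exist_ok=True)
    omnibus = pd.DataFrame(
        [
            {"test": an.test, "statistic": an.statistic, "df1": an.df1, "df2": an.df2,
             "p_value": an.p_value, **an.diagnostics},
            {"test": kw.test, "statistic": kw.statistic, "df1": kw.df1, "df2": kw.df2,
             "p_value": kw.p_value},
        ]
    )
    omnibus.to_csv(args.out / "omnibus_tests.csv", index=False)
    pairwise.to_csv(args.out / "pairwise_tests.csv", index=False)
    print(f"\ntables written to {args.out}/")


if __name__ == "__main__":
    main()
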