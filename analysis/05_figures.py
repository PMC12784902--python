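#!/usr/bin/env python
"""Report figures: MAD barplot, per-fly bias and activity strip plots.

Reads the tables written by the earlier steps and renders the three report
panels: group MAD with bootstrap-SE error bars, per-fly right-turn
proportion with group medians, and per-fly turns/min with group medians and
compact significance letters from the BH-adjusted pairwise tests.  PNGs go
to results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from turnvar.plots import mad_barplot, strip_plot


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--analysis-dir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
    args = ap.parse_args()

    summaries = pd.read_csv(args.analysis_dir / "fly_summaries.csv")
    gv = pd.read_csv(args.analysis_dir / "group_variability.csv")
    perms = pd.read_csv(args.analysis_dir / "permutation_tests.csv")
    pairwise = pd.read_csv(args.analysis_dir / "pairwise_tests.csv")

    args.out.mkdir(parents=True, exist_ok=True)
    mad_barplot(gv, args.out / "fig_mad.png")
    strip_plot(summaries, "prop_right", args.out / "fig_prop_right.png",
               pairwise=perms, ylabel="proportion of right turns")
    strip_plot(summaries, "turns_per_min", args.out / "fig_turns_per_min.png",
               pairwise=pairwise, ylabel="turns per minute")
    print(f"figures written to {args.out}/")


if __name__ == "__main__":
    main()
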