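# Methods

## Object of study

The pipeline quantifies *inter-individual* variability of a binary choice
behavior. Each fly's behavior is reduced to one number, its right-turn
proportion p̂ᵢ across all scored arm-to-arm decisions in a single session;
the group-level dispersion of these per-fly proportions is the
predictability index. Two nested sources of variance contribute to the
spread of p̂ᵢ: true heterogeneity of the latent biases pᵢ across flies,
and binomial sampling noise p(1−p)/Nᵢ from each fly's finite turn count
Nᵢ. The statistic is deliberately computed on the *observed* proportions
— as an assay of the cohort, not a deconvolution — so the synthetic
generator is calibrated on the same observed scale (below).

An alternative reading, a within-fly MAD of each fly's own 0/1 choice
codes, is exposed as `summarize_flies(include_choice_mad=True)` but is
degenerate for binary data: the within-fly MAD is exactly 0 whenever one
direction holds a strict majority and 0.5 otherwise, so it carries almost
no dispersion information. The across-fly reading is the only one on the
scale of the group MAD values the pipeline reports (~0.07–0.09), and is
the one used everywhere.

## MAD conventions

`group_mad` is the raw median absolute deviation,
median(|xᵢ − median(x)|), with the sample median defined as the midpoint
of the middle two values for even n. No consistency constant (1.4826) is
applied: the constant only converts MAD to a normal-σ estimate, and the
data are proportions with no normality assumption. MAD is
location-invariant, scale-equivariant, permutation-invariant, and zero
iff a strict majority of values equals the median — all property-tested.

## Permutation test

Two groups are compared by MAD_a − MAD_b under the exchangeable null:
pooled values are reassigned to groups of the original sizes uniformly at
random (10,000 iterations by default; random permutations via argsort of
iid uniforms, vectorized in chunks). The p-value uses the add-one
estimator p = (1 + #{extreme}) / (1 + n_iter), which is never 0 and gives
valid (slightly conservative) type-I control. Two-sided by default; the
one-sided variants are available.

Numerical ties: two label assignments can have mathematically equal
statistics that differ by an ulp after two median subtractions, so the
extremeness comparison uses an absolute tolerance of 1e-12 — a permutation
within tolerance of the observed statistic counts as extreme
(conservative). Without this, Monte-Carlo p-values sit a tie's worth below
the exhaustive-enumeration value on small groups.

Calibration and power are verified by simulation in the acceptance tests:
under a same-Beta null (μ=0.5, κ=20, n=100/group, 1000 replicates) the
rejection rate at α=0.05 must fall in the binomial band [0.037, 0.064];
for a κ=60 vs κ=20 dispersion contrast at n=200/group the test must
detect the lower-MAD group in ≥90% of 50 replicates with the correct sign
of ΔMAD in ≥98%.

## Bootstrap

Uncertainty on a group MAD comes from a fly-level nonparametric
bootstrap: resample flies with replacement, recompute the MAD, report the
SD of resampled MADs as the bootstrap SE and the 2.5/97.5 percentiles as
the 95% CI (10,000 resamples by default; percentile interval, not BCa —
the simplest choice, adequate at cohort sizes of hundreds of flies).
Degenerate input (all values identical) returns SE 0 and a zero-width CI.
Coverage of the population MAD is simulation-tested (~95% nominal, ≥90%
asserted over 300 replicates at n=200).

## Inclusion threshold

`min_turns` (default 10) excludes flies whose bias estimate would rest on
too few decisions; excluded flies are listed with a reason rather than
silently dropped. Ten turns caps the per-fly binomial SE at ≈0.16 while
excluding almost no flies under the reference activity distribution
(6 of 1285 in the seed-1 cohort). The threshold is exposed everywhere
(`--min-turns`) because published analyses of this assay type have used
unstated exclusion rules — reported degrees of freedom sometimes imply
far fewer analyzed flies than tested — and matching such a rule exactly
requires sweeping this knob.

## Secondary tests

* One-way fixed-effects ANOVA on p̂ᵢ (scipy `f_oneway`), df (k−1, N−k),
  with Shapiro–Wilk on residuals and Levene's test in its median-centered
  Brown–Forsythe form attached as diagnostics. Brown–Forsythe is the
  robust default for proportion-scale data.
* Kruskal–Wallis on turns/min with the usual tie correction
  1 − Σ(t³−t)/(N³−N) (scipy `kruskal`); an all-identical sample returns
  H=0, p=1 instead of an error.
* Pairwise Mann–Whitney U, two-sided; the exact null is used when
  min(n) ≤ 8 with no ties, otherwise the normal approximation with
  tie-corrected variance and continuity correction (scipy). The three
  pairwise tests form one BH family (statsmodels `fdr_bh`).
* Turns/min uses the fixed session length (120 min) as denominator, not
  per-fly tracked time; configurable via `observation_minutes`.

## Trajectory scoring

Raw centroid tracks are scored with a zone-commitment rule. The maze is
three arms (default 12 mm, bearings 90°/210°/330°) around a center. A
point is CENTER within `center_radius_mm` (2 mm), otherwise it belongs to
the arm angularly nearest its bearing (exact boundary ties break to the
lowest arm index, deterministically), or OUT beyond the arm extent plus
tolerance. A fly is *committed* to an arm only at distance
≥ `commit_radius_mm` (4 mm); a turn is emitted when the committed arm
changes, timestamped at the first committed sample in the new arm. The
2 mm hysteresis band between the radii means positional jitter of
amplitude < 1 mm can never create or destroy events (property-tested).
Scoring operates on the zone-commitment sequence, so it is agnostic to
sampling rate.

Direction needs a convention, since "right" is ambiguous in a three-armed
maze: with arms indexed clockwise viewed from above, a move to
(i+1) mod 3 is Right under the default `cw-right`; `ccw-right` flips all
labels. Every dispersion statistic is invariant to the convention when
mean bias is 0.5, and cyclic relabeling of arms never changes any label
(both tested). The decision-point definition (commitment change, not
center exit) is one defensible reading of automated maze scoring; a
different extraction rule would shift absolute turn counts but not the
bias proportions of an unbiased walker.

## Synthetic cohorts

The generator emulates a single-session, three-group Y-maze experiment:

* Per-fly bias pᵢ ~ Beta(μκ, (1−μ)κ). The mean/concentration
  parameterization makes κ a pure dispersion knob
  (Var = μ(1−μ)/(κ+1)).
* Turn count Nᵢ ~ Poisson(rateᵢ · session), rateᵢ ~
  LogNormal(rate_log_mean, rate_log_sd) — activity in such assays is
  strongly right-skewed (upper quartiles of turns/min more than double
  the median), and the lognormal is the simplest positive skewed law.
* Each event is R with probability pᵢ; event times are uniform order
  statistics over the session (timing feeds no statistic except
  turns/min); an arm-walk consistent with the directions fills
  `arm_from`/`arm_to`.
* Seeding is counter-based: fly (g, i) draws from
  `SeedSequence((master_seed, g, i))`, so adding or removing flies never
  perturbs any other fly, and identical configs are byte-identical.

`study_default_config()` freezes the reference study conditions: groups
control/tryptophan/escitalopram with N = 425/410/450, μ = 0.5 everywhere
(no directional bias), 120-minute sessions. The lognormal rate parameters
are derived in closed form from the reference turns/min quartiles
(log-mean = ln median; log-sd = ln(Q3/Q1)/(2·z₀.₇₅)), giving medians
1.24/1.20/1.45. The Beta concentrations κ = 18.0/21.8/32.2 were
calibrated once, by root-finding on large simulated cohorts
(`analysis/00_calibrate_generator.py` re-derives them), so that the
*observed* group MADs of p̂ᵢ (heterogeneity plus binomial noise under the
matching rate model and the min_turns=10 filter) equal the reference
values 0.086/0.080/0.067. The calibration is a moment match on the
observed scale; it is not re-tuned per seed, so any single simulated
cohort scatters around those targets with a MAD sampling SE of ≈0.005
per group.

What the generator does **not** emulate: within-fly nonstationarity
(bias drift, fatigue), temporal clustering of turns, wall-following or
other spatial structure, tracking noise or dropped frames, multi-fly
interaction, and any arena asymmetry. Passing tests therefore demonstrate
the statistics' correctness and calibration under the hierarchical model,
not robustness to those real-data artifacts; the trajectory generator
exists precisely so the scoring rules can be exercised separately.

## Problem sizes in the test suite

The acceptance checks run at the stated sizes (10⁴ MAD oracle vectors;
1000 calibration replicates at n=100/group; 50 power replicates at
n=200/group; exhaustive enumeration for groups up to (4,4) and
Mann–Whitney up to n=6 per group). Supporting unit tests use smaller
cohorts (tens of flies, shortened sessions, 30–300 replicates) chosen so
the whole suite completes in well under a minute; the properties they
check (dispersion ordering, moment recovery, coverage) are
size-insensitive at those scales.

## Known limitations

* Reproducing a published analysis exactly requires its inclusion filter;
  where that filter is unstated, only filter-insensitive quantities
  (group MADs, medians) can be matched, and the pipeline reports the
  filter's effect instead of guessing it.
* The percentile bootstrap slightly undercovers for very small groups
  (n ≲ 20); BCa is out of scope in this version.
* The permutation test compares total observed dispersion; it does not
  separate latent heterogeneity from binomial noise. Groups with very
  different turn-count distributions can differ in observed MAD for
  activity reasons alone — the activity comparisons are reported
  alongside for exactly this check.
* Single-session design: no repeatability (ICC) estimation across
  sessions, no sequential within-fly statistics.
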