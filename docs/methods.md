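# Methods

This note records the models, defaults and design decisions behind each
pipeline stage, in enough detail to re-derive every number the code produces.

## Exposure reconstruction

Dose trajectories are day-resolution series from birth to follow-up
(inclusive), 0-based from the birth date, ages computed as exact day counts
/ 365.25. A dispense supplies `units_dispensed / daily_units` whole days
(rounded, minimum 1) at `unit_strength x daily_units` mg/day, starting on the
dispense day (half-open interval).

Two rules resolve overlap, on which dispensing data are always ambiguous:

- *Same drug class*: a newer dispense supersedes the remaining supply of the
  previous one (no stockpiling). This matches titration practice — a changed
  prescription replaces the old one — and keeps doses bounded.
- *Different classes* (e.g. IR + XR methylphenidate): supplies run
  concurrently and doses add.

Only stimulant classes contribute dose; non-stimulant dispenses contribute
only to per-day coverage flags. `stop_age` is defined by exhaustion of the
last supply (last non-zero day + 1), not the last dispense date.

Monthly averaging uses fixed 365.25/12-day (30.4375) bins anchored at birth,
calendar-free for reproducibility; each bin value is the arithmetic mean of
its daily doses, so bin-mean x bin-day-count exactly conserves total dose.
For treated subjects the series is restricted to the first-to-last treated
month.

## Smoothing model

The per-subject smoother is a Gaussian GAM: monthly mean dose y_j at month
midpoint age x_j is fit by a cubic B-spline f with clamped uniform knots over
the treated window, minimizing ‖y − Bc‖² + λ‖D₂c‖² with D₂ the second-order
difference operator on the coefficients. Defaults:

- basis dimension k = min(10, max(4, ⌈n_months/4⌉));
- λ selected by GCV, n·RSS/(n − tr H)², over 21 log-spaced points in
  10⁻⁴…10⁶;
- fitted curve evaluated daily over the window and clamped at 0 for feature
  extraction.

The penalty null space contains constants and lines, so noiseless constant or
linear histories are reproduced exactly; this is the basis of the smoother's
oracle tests. Subjects with fewer than 4 monthly points (where a spline is
ill-posed) fall back to their raw monthly means held constant per month and
are flagged rather than excluded, so short-treated subjects stay in the
analysis.

The six-feature profile is (start_age, rel_duration, rel_total_dose,
max_dose, dose_variability, stop_age):

- `rel_duration` = (years of fitted dose ≥ 1 mg/day) / (age at follow-up −
  start-age offset). The 1 mg/day threshold makes "duration" of a smooth
  curve well defined and sits below any prescribable dose. The offset is the
  earliest start age in the sample (computed at run time by default; 2.3 y is
  the conventional value when emulating the reference cohort) — the
  denominator is the span over which treatment was possible at all.
- `rel_total_dose` = raw cumulative dose / same denominator, in **mg per
  eligible-year**. (Published cumulative-use tables in this design print
  values near 5–19 without units, most plausibly g/yr; this package fixes
  mg/yr and documents the choice rather than matching an ambiguous scale.)
- `dose_variability` is the population SD of the fitted curve — fixed
  convention; the sample/population distinction is immaterial after
  z-scoring.

## Similarity graph and community detection

The six features mix years, mg and fractions, so profiles are z-scored per
feature (population SD; zero-variance features are an error, not a silent
drop). The graph is complete with Gaussian kernel weights
w_ij = exp(−‖z_i − z_j‖²/2σ²), σ = the median pairwise Euclidean distance —
a deliberately parameter-light construction, chosen because the clustering
input construction is the least standardized step of this design; kNN
sparsification or correlation similarity could be configured in its place.

Louvain proceeds classically: greedy local moving (nodes visited in a seeded
random order, each moved to the neighbouring community with the largest
positive modularity gain, tie broken by first encounter; sweeps repeat until
no gain exceeds 10⁻¹⁰) alternating with community aggregation into a weighted
super-graph, until an aggregation level improves Q by less than 10⁻⁸.
Resolution is fixed at 1 (plain modularity). The best of 20 seeded restarts
is returned; restarts after the first start local moving from a seeded
random initial partition, which lets the optimizer escape greedy basins that
no visit order avoids (plain singleton-start Louvain demonstrably misses the
global optimum on some small graphs). On all enumerable test graphs
(≤ 8 nodes) the result matches exhaustive search over all partitions.

Stability: B bootstrap replicates resample subjects with replacement
(duplicates kept as distinct nodes), re-standardize, rebuild the graph (σ
re-derived), and re-cluster with a single restart. The headline stability
number is the fraction of replicates reproducing the modal community count —
the weakest faithful notion of "the same solution" — with the mean adjusted
Rand index against the full-sample partition reported alongside as the
stricter notion.

Subgroup naming is by feature means: with exactly three communities, the one
with both the earliest mean start age and the highest mean maximum dose is
`early_and_intense`; of the rest, earlier start = `early_and_moderate`,
later = `late_and_moderate`. Any other count, or a naming ambiguity, falls
back to neutral size-ordered labels with a warning. Stimulant-naive subjects
never enter the graph; they are appended afterwards as their own subgroup.

## Survival analysis

Per domain (SUD, daily smoking, nicotine dependence), cases contribute age at
first substance use (SUD) or first nicotine use (both smoking domains) as
event time; non-cases are censored at follow-up age. The time scale is age
with entry at zero — epidemiologically debatable (no left truncation) but
exactly the construction this design prescribes.

The Cox partial likelihood uses Breslow tie handling by default (Efron
available), Newton–Raphson with step halving, convergence |Δlog L| < 10⁻⁹,
at most 100 iterations; |β| > 50 is reported as monotone likelihood. Family
clustering is corrected by the Lin–Wei sandwich: V = Î⁻¹(Σ_f s_f s_fᵀ)Î⁻¹
with s_f the score residuals summed within family f (score residuals use the
Breslow form; identical to Efron when event times are distinct). Hazard
ratios, 95% CIs, the overall Wald χ² on the subgroup block and all pairwise
contrasts (linear combinations of coefficients, so HR(a,b) = 1/HR(b,a)
exactly) use the robust covariance. Pairwise p-values are two-sided and
unadjusted by default (a Holm switch exists). Cumulative incidence is
1 − exp(−Λ̂₀(t)·exp(β_g)) with the Breslow baseline.

Matched sensitivity analysis: greedy nearest-neighbour selection without
replacement on Mahalanobis distance (pooled covariance) of baseline age and
hyperactive symptoms toward the smallest subgroup's mean, to equal group
sizes; standardized mean differences are reported before and after, both
standardized by the *pre-matching* pooled SD (the usual convention for
judging balance — matched subsets have artificially shrunken within-group
SDs, so re-standardizing post-hoc would overstate residual imbalance).
Covariate-adjusted models add SES, conduct disorder, IQ, ADHD severity and
non-stimulant co-medication as extra terms to the same fit.

## Synthetic cohort generator

The generator's defaults are the study conditions, anchored to the published
subgroup table: three treated subgroups (n = 103 early-and-intense, 51
early-and-moderate, 91 late-and-moderate) with start age, stop age and
plateau dose drawn Normal at the printed means/SDs (e.g. start 7.09 ± 1.53 y
and plateau 53.35 ± 17.89 mg for early-and-intense, start 11.47 ± 2.39 y for
late-and-moderate); 58 stimulant-naive subjects; 219 controls. Follow-up age
is Normal(16.0, 2.3) truncated at 12; baseline covariates are drawn at the
per-group printed moments. 40% of subjects are paired into two-child
families (study entry required a sibling, the retained fraction is not
published; 0.4 is a realistic share).

Dose paths are piecewise constant at day resolution: an optional two-step
titration ramp (half, then three-quarter plateau, 30 days each — suppressed
when the change rate is zero so the no-change limit is exactly flat),
Poisson-timed step changes (rate 2/yr, SD 10 mg for the intense subgroup;
0.5/yr, 5 mg otherwise), and Bernoulli-per-treated-year gaps of 60–120 days
(probability 0.3/0.1/0.2 for late/early-moderate/intense). Doses are
quantized to 5 mg steps with a 2.5 mg floor, reflecting available unit
strengths, and emitted as 30-day supplies, so the trajectory stage
reconstructs the planted path exactly. Because step changes random-walk
around the plateau, realized maximum doses exceed the plateau parameter for
long-treated subjects, and realized feature spreads are wider than the
printed SDs — the planted subgroups overlap, which is the realistic (hard)
regime for the clustering stage.

Event ages follow Weibull proportional hazards per domain:
T = scale·(E/m)^(1/shape), E ~ Exp(1), m = exp(log HR_group)·Z_family, with
Z gamma-distributed (mean 1, variance 0.5) shared within family. Log-HRs are
anchored to the published within-ADHD contrasts with early-and-intense as
reference (SUD 2.70/2.66/3.57 for late/early-moderate/naive; ND
2.78/1.04/3.45; daily smoking 0.68/0.75/0.81); Weibull shape/scale per
domain (6/24, 5/19, 8/22 years) put event fractions at follow-up near the
published per-group percentages. Daily smoking and nicotine dependence share
the age-at-first-nicotine-use field (the earliest occurring event), exactly
as the survival construction assumes. Weibull was chosen over other PH
generators for its closed-form survivor function, which the generator's own
tests exploit.

What the generator does **not** emulate: partial pharmacy coverage (real
transcripts covered ~69% of lifetime; simulated coverage is complete over
treatment episodes), self-reported exposure fallback, instrument-level
outcome scoring, dose-equivalence differences between methylphenidate and
dexamphetamine, and treatment-by-indication feedback (dose paths are drawn
independently of the subject's eventual outcome). Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to those real-data complications.

## Numerical and reporting conventions

- All randomness flows from explicit seeds (numpy `SeedSequence` spawning);
  identical config + seed reproduces every artifact byte for byte.
- Floats in written artifacts are rounded to 6 significant digits at write
  time; table writers emit `repr` floats so write→read round-trips exactly.
- Degenerate inputs fail loudly: zero-variance features, all-zero pairwise
  distances, datasets without events, constant model terms, unlabeled nodes.
- The robust-CI coverage check under frailty needs a "true" marginal hazard
  ratio, but marginal hazards under gamma frailty are non-proportional; the
  estimand is operationalized as the large-sample Cox limit, computed by a
  one-off mega-simulation (n = 80 000) under the same censoring, and
  coverage is assessed against it.

## Problem sizes used in the checks

Exhaustive-search comparisons use 50 random graphs of ≤ 8 nodes (Bell(8) =
4140 partitions each). Planted-profile recovery uses 3 × 50 subjects × 20
seeds with subgroup centroids ≥ 4 within-SD apart after standardization, and
a B = 100 bootstrap. Cox calibration uses 50 cohorts of n = 1000 (HR
recovery), 1000 null cohorts of n = 200 (type-I error), and 500 frailty
cohorts of 150 sibling pairs (coverage). The end-to-end run uses the full
default cohort (303 ADHD + 219 controls) with a B = 200 bootstrap. These
sizes give Monte-Carlo error comfortably inside the asserted bands while
keeping a full run in minutes on one core.

## Known limitations

- Modularity values on complete Gaussian-kernel graphs are intrinsically
  modest (Q ≈ 0.09 on the default cohort) because every pair is connected;
  Q is comparable across runs of this pipeline but not across different
  graph constructions.
- Louvain is greedy; global optimality is verified only on enumerable
  graphs.
- The supersede/sum overlap rule is a modelling choice on ambiguous data.
- Frailty exists only in the generator; the analysis corrects variances for
  clustering but does not estimate frailty models.
- With overlapping subgroups, community misclassification attenuates
  between-subgroup hazard ratios toward 1 — visible in the default cohort,
  where detected-subgroup HRs sit below the planted conditional values while
  the naive-vs-treated contrasts (no clustering involved) do not.
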