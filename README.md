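# stimtraj

Multivariate stimulant-treatment profiling for ADHD cohorts: from pharmacy
dispensing transcripts to treatment subgroups to substance-use outcomes.

Whether stimulant treatment protects against or promotes later substance use
disorders (SUD) and nicotine dependence (ND) in ADHD has been argued both
ways, usually with single summary measures of exposure (treated yes/no, start
age, or duration alone). This package implements the multivariate
alternative: reconstruct each patient's full dose history from pharmacy
records, summarize it as a six-feature *treatment profile*, let a community
detection algorithm find data-driven subgroups of treatment histories, and
compare the subgroups' hazards of SUD, daily smoking and ND with
family-clustered Cox models. It is written for epidemiologists and
biostatisticians who want the whole chain — exposure reconstruction,
profile smoothing, clustering, stability assessment and survival comparison —
as tested, seeded, reusable library code, exercised end to end on a synthetic
cohort generator with known ground truth.

## The pipeline

1. **Trajectory reconstruction** (`stimtraj.trajectory`). For each subject a
   daily dose series d(t), in mg/day, covers every day from birth to
   follow-up: a dispense of `units_dispensed` units at `unit_strength` mg
   taken `daily_units`/day supplies `units/daily_units` days at dose
   `strength x daily_units`; a newer dispense of the same preparation
   supersedes remaining supply, different preparations (IR + XR) add.
2. **Smoothing and features** (`stimtraj.smoothing`). Monthly average daily
   dose is smoothed per subject with a generalized additive model — a
   penalized cubic B-spline with second-order difference penalty, smoothing
   parameter chosen by GCV. Six features summarize the history: start age and
   stop age (raw), total dose relative to eligible years (raw), relative
   treatment duration, maximum dose, and dose variability (SD), the last
   three read off the fitted curve.
3. **Community detection** (`stimtraj.community`). Profiles are z-scored and
   connected in a complete similarity graph with Gaussian kernel weights
   w_ij = exp(−‖z_i − z_j‖² / 2σ²), σ = median pairwise distance. Subgroups
   maximize Newman–Girvan modularity
   Q = (1/2m) Σ_ij [w_ij − k_i k_j / 2m] δ(c_i, c_j)
   via seeded multi-restart Louvain; a non-parametric bootstrap (resample,
   re-standardize, rebuild, re-cluster) quantifies the stability of the
   subgroup count. Stimulant-naive subjects are appended as their own group.
4. **Survival comparison** (`stimtraj.survival`). Per outcome domain, cases
   enter with age at first substance/nicotine use, non-cases are censored at
   follow-up age. The Cox partial likelihood (Breslow ties) is maximized by
   Newton–Raphson, and sibling dependence is handled with the Lin–Wei robust
   covariance Î⁻¹(Σ_families s_f s_fᵀ)Î⁻¹ built from score residuals summed
   within families. Outputs: overall Wald test, pairwise hazard ratios with
   robust CIs, Breslow cumulative-incidence curves, and a matched-group
   sensitivity analysis (Mahalanobis nearest-neighbour balance on baseline
   age and hyperactivity).
5. **Synthetic cohort** (`stimtraj.simulate`). Three planted treated
   subgroups (dose paths with titration, stepwise changes, treatment gaps),
   a stimulant-naive group and controls; sibling pairs share families; event
   ages follow group-specific Weibull proportional hazards with shared gamma
   frailty per family. One seed determines every byte of output.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (303 ADHD subjects, 219 controls):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_extract_features.py
python analysis/03_detect_communities.py --seed 1
python analysis/04_fit_survival.py
python analysis/05_sensitivity_analyses.py
```

With seed 1 the community stage prints

```
k = 3 communities, Q = 0.090
  early_and_intense: n=99
  early_and_moderate: n=33
  late_and_moderate: n=113
  stimulant_naive: n=58
bootstrap (B=200): modal k = 3 in 67.0% of replicates, mean Q = 0.089 (SD 0.007)
```

i.e. the three planted treatment subgroups are recovered and named from their
feature means (earliest start + highest dose = early-and-intense), and the
survival stage prints, among others,

```
sud: n=303, events=61, Wald chi2=7.91 (df 3), p=0.04801
  stimulant_naive vs early_and_intense: HR 2.35 (1.16-4.72), p=0.017
nicotine_dependence: n=303, events=52, Wald chi2=14.42 (df 3), p=0.00239
  late_and_moderate vs early_and_intense: HR 3.44 (1.40-8.45), p=0.00707
```

— the subgroups differ in SUD and ND risk with the early-and-intense group at
the lowest hazard, the ordering planted in the generator. The equivalent
one-shot run is `stimtraj run-all --seed 1 --outdir results/run`, which
writes `features.csv`, `partition.csv`, `stability.json`, per-domain
`results_*.json`, `curves.csv` and a `report.md`.

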