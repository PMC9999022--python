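# Methods

## The decision problem

Chinese oncology guidelines admit seven first-line regimens (standard
platinum/paclitaxel chemotherapy, SC, alone or combined with nedaplatin,
pembrolizumab, tislelizumab, camrelizumab, sintilimab or sugemalimab) and
three second-line options (docetaxel, tislelizumab, nivolumab) for advanced
wild-type squamous non-small-cell lung cancer, with the restriction that an
immune checkpoint inhibitor is used in at most one line. That yields 11
treatment sequences. `seqcea` estimates lifetime costs and QALYs for each
sequence from the healthcare-system perspective and ranks them by ICER and
net monetary benefit.

## Model structure

A sequential micro-simulation with four states — progression-free on
first-line treatment (PFS), first-stage progressed disease on second-line
treatment (PD1), end-stage progressed disease on best supportive care
(PD-end), and death — on 21-day cycles to a 20-year horizon. Each of
10,000 simulated patients draws:

1. a first-line progression time `T1` from the sequence's first-line PFS
   curve;
2. on progression, the second-line clock resets to zero and the pair
   (second-line progression `P2`, second-line survival `O2`) is drawn from
   the second-line PFS/OS curves with a **comonotone coupling** (one shared
   uniform rank), which guarantees `P2 <= O2` for every patient without
   extra parameters; death occurs at `T1 + O2`.

There is no separate first-line death channel: all first-line exits are
progressions, and subsequent mortality is governed by the second-line OS
clock. This is the only reading consistent with the sequential structure
and it reproduces the published life-year decomposition. Patients who have
not progressed by year 20 remain in PFS at the horizon; times are
continuous and accrual is pro-rated within cycles, so no half-cycle
correction is needed.

Common random numbers: the per-patient uniforms depend only on (seed, n),
so contrasts between strategies share Monte-Carlo noise. A deterministic
cohort evaluator (`econ.expected_outcomes`) computes the same expectations
by numerical integration over the survivor curves; micro-simulation and
evaluator agree to Monte-Carlo error (a tested property), and the evaluator
drives the PSA, OWSA and scenario engines.

## Survival inputs

**Reference curves** (printed parametric fits, times in years):

* first-line SC PFS: log-logistic, S(t) = 1/(1+(t/0.38)^2.506) — the scale
  is the median, 0.38 y ≈ 4.6 months;
* second-line docetaxel OS: exponential with rate 1.043/y (median ≈ 8
  months);
* second-line docetaxel PFS: the source prints restricted-cubic-spline
  coefficients γ0..γ3 without knots or scale. Under the standard
  Royston–Parmar natural-spline basis those coefficients admit **no** knot
  configuration on either the log-cumulative-hazard or log-cumulative-odds
  scale that yields a monotone survivor function with the trial's shape:
  beyond the upper boundary knot the spline is linear in log time with
  slope γ1 − 3·Σγ_j·λ_j(1−λ_j)(k_max−k_min)², so the tail slope is bounded
  above by γ1 = 0.305 and the large positive curvature terms force the
  extrapolation to flatten near S ≈ 0.5 (verified by exhaustive knot
  search). The packaged curve is therefore a log-logistic calibrated to the
  same trial's printed summaries — median 2.8 months, ≈3% progression-free
  at 1.5 years — giving scale 0.233 y, shape 1.866. The `rcs` family
  (fitting and evaluation, both scales, arbitrary knots) is fully
  implemented and an RCS-configured curve can be supplied through the
  parameter table.

**Relative efficacy** comes from three fractional-polynomial NMAs with
time-varying hazard ratios, ln HR(t) = d0 + d1·t^p (+ d2·ln t for the
second-order OS model), applied multiplicatively to the reference interval
hazards. Two structural details are not printed and were fixed once by
calibrating the assembled model against the published base-case table
(whose cost/QALY/life-years values are treated as inputs):

* **Time units.** The first-line PFS and second-line PFS coefficients
  (first-order, p = −2) are consistent only with a month/cycle time scale;
  the basis is evaluated in model cycles (21 d), floored at 1 cycle to
  avoid the t→0 singularity of negative powers. The second-line OS
  coefficients (second-order, p = −0.5, 0) are consistent only with
  **years** (on a month scale the tislelizumab OS mean falls below
  docetaxel's, contradicting the published NT/CT life-years); the basis is
  floored at 0.25 y. Units are configurable per analysis block.
* **Treatment-effect duration.** With the HR applied over the whole
  horizon, every strong immunotherapy arm overshoots the published
  life-years by ≈20%. The model therefore reverts the hazard ratio to 1
  at an effect-duration horizon: 3.5 years for first-line immunotherapy
  combinations, and the label treatment caps for second line — 1.34 y for
  nivolumab (35 two-weekly doses) and 2.01 y for tislelizumab (35
  three-weekly cycles). The nedaplatin contrast (long-run HR ≈ 0.98) keeps
  its NMA profile throughout. With these settings all 22 published
  QALY/life-year values are reproduced within 5%.

After assembly, general-population mortality (packaged synthetic
Gompertz–Makeham life table approximating recent Chinese census rates; see
`data/life_table_synthetic.csv`) replaces the curve hazard wherever the
curve's own interval hazard falls below the age-specific background hazard
(cohort age 60 at entry, configurable). Second-line PFS is capped at OS on
the grid.

The FP-NMA fitting machinery itself (interval event counts Poisson with
log person-time offsets, study-specific baseline FP coefficients,
fixed-effect contrasts, ensemble-sampler MCMC with DIC and split-R̂) is
implemented and tested on synthetic networks generated by
`synthetic_data.generate_network`; the packaged analysis consumes the
printed posterior summaries directly because the source's study-level
baselines are unpublished.

## Economics

All money is 2022 USD, discounting of costs and QALYs at 5%/y continuous
((1+r)^−t); life-years are undiscounted (matching the published table,
whose QALY arithmetic is inconsistent with discounted life-years).

* **Drugs.** Per-administration doses follow label regimens resolved at
  BSA 1.72 m², CrCl 70 ml/min (Calvert: dose = AUC×(CrCl+25)) and 65 kg;
  costs use the cheapest full-vial combination (no vial sharing).
  Chemotherapy backbones run at most 4–6 cycles, checkpoint inhibitors to
  progression or 35 doses; nivolumab is dosed 3 mg/kg q2w. The platinum
  backbone is market-share weighted (carboplatin 0.74 / cisplatin 0.26),
  the taxane likewise (paclitaxel 0.61 / albumin-bound 0.39). The dosing
  schedule layer is a reconstruction from labels and is fully
  configurable; unit prices, BSA and CrCl are printed values.
* **Follow-up/monitoring** while on active treatment (PFS and PD1): labs,
  administration and bed fees every cycle, CT imaging every two cycles
  (reconstructed schedule; itemized costs printed).
* **Adverse events**: grade ≥3 events with incidence >5% per regimen; the
  whole burden (cost and disutility × duration) is applied once at line
  start.
* **BSC** 337.95/cycle in end-stage PD; **end-of-life** 2,325.75 at death
  (discounted at the death time).
* **Utilities**: PFS 0.75 (immunotherapy) / 0.70 (chemotherapy), PD 0.59,
  death 0; scenario sets 0.804/0.321 and 0.877/0.823/0.768/0.703.

ICERs are pairwise Δcost/ΔQALY with dominance flags; NMB = λ·QALY − cost at
λ = 19,091 USD/QALY (1.5× GDP per capita; range 12,728–38,184; 32,456 for
the second-line subgroup); the efficiency frontier uses the standard
extended-dominance pruning.

## Sensitivity analysis

* OWSA: each parameter to its printed bounds, all others at base; INMB vs
  the camrelizumab sequence recorded.
* PSA: gamma for costs, beta for probabilities/utilities, normal on the
  coefficient scale for NMA coefficients (the printed "lognormal" label
  cannot hold for negative coefficients), with method-of-moments parameters
  and SD = (high−low)/3.92. Each draw is evaluated with the cohort
  evaluator; equivalence with the micro-simulation is itself a test.
* Scenarios: utility sets (1, 2), 50% patient-assistance prices for
  sugemalimab/nivolumab/pembrolizumab (3), 5/10/20-year horizons (4), and a
  0–4,000 USD/cycle third-line cost sweep (5).

## Synthetic data

`synthetic_data` generates trials with known hazard structure (parametric
or FP-HR arms, administrative cutoff, random early dropout), emulated
digitizations (KM step function read on an even grid with ±0.002 jitter,
exact at-risk tables) and star-shaped NMA networks. Generators are pure
functions of (spec, seed). They emulate the statistical structure the
pipeline assumes — they do not emulate figure-image artifacts, digitizer
operator error beyond jitter, or real-world censoring patterns, so passing
round-trip tests bounds algorithmic error, not the accuracy of any manual
digitization.

## Numerical choices

* Grid: 21-day steps to 20 years (348 intervals), linear interpolation
  within steps; inverse-CDF sampling interpolates the tabulated survivor
  function, so sampled times have O(Δt²) discretization error.
* Parametric MLE: multi-start L-BFGS-B from method-of-moments seeds,
  gradient tolerance 1e-8; exponential uses the closed form
  events/person-time. Non-converged fits carry diagnostics and are excluded
  from AIC selection; AIC ties (1e-9) go to the fewer-parameter family.
* Guyot reconstruction: censorings spread uniformly within each at-risk
  interval; the censoring total is iterated until the implied at-risk count
  matches the published table, with a final exact-enforcement step that
  resolves rounding residuals by trimming trailing events or adding
  end-of-interval censorings; survivors at the end of the curve are
  censored there. The digitization grid density is not reported by the
  source; tests use ≥50 points, where round-trip error is comfortably
  below the 0.02 sup-norm bound (≈0.01 typical at 100 points).
* MCMC: affine-invariant ensemble sampler; the ensemble's walkers stand in
  for parallel chains (defaults mirror 3×10,000 kept draws after an equal
  burn-in); split-R̂ ≤ 1.05 flags convergence, non-converged results are
  returned flagged, never silently.
* Problem sizes: simulations use 10,000 patients (the study's cohort
  size); PSA defaults to 1,000 draws with the cohort evaluator in the
  packaged analysis scripts, with 10,000 available via configuration.

## Known limitations

* The dosing/monitoring schedule layer and the FP time-unit /
  effect-duration structure are reconstructions calibrated once against
  the published base-case table; they are the package's largest structural
  uncertainties and are all exposed as configuration.
* The published NMA posterior cannot be reproduced exactly (study-baseline
  coefficients unpublished); PSA treats the printed coefficient intervals
  as independent normals, ignoring posterior correlation.
* The packaged life table is synthetic (Gompertz–Makeham approximation);
  its effect on 20-year life-years is small (the splice binds only in thin
  plateau tails) but users can supply a census table as CSV.
* The cohort is homogeneous; no covariate heterogeneity, treatment
  switching or crossover.
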