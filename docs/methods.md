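# Methods

`isosub` implements a complete analysis pipeline for studying what happens,
cross-sectionally, when time is reallocated between sedentary behaviour,
light physical activity (LPA) and moderate-to-vigorous physical activity
(MVPA) in children and adolescents: accelerometer epoch processing, a
synthetic multi-study cohort generator, the three-step substitution
modelling framework, and reporting. The real pooled dataset it is built
around — the International Children's Accelerometry Database (ICAD) — is
access-restricted, so the generator reproduces its published structure and
every empirical claim in this repository is about synthetic data; published
coefficients enter only as calibration constants and worked-example inputs
(`isosub.reference`).

## Epoch processing

Raw streams are ordered (timestamp, count) pairs at a fixed epoch length
that divides 60 s. Processing steps, in order:

1. **Reintegration** to 60-s epochs by summing constituent epochs. Input
   must be gap-free and aligned within each calendar day; gaps raise an
   error rather than being zero-filled, since silent zero-fill would
   manufacture sedentary time.
2. **Non-wear detection**: an epoch is non-wear iff it lies inside a window
   of ≥ 60 min containing at most 2 non-zero epochs, with zero epochs at
   both window ends. The interruption allowance is interpreted as *at most
   2 non-zero epochs in total per window, of any magnitude, consecutive or
   not*, and interruptions may not open or close a run — the most literal
   reading of the 60-min/2-min rule, frozen by an oracle test: the
   production linear-time two-pointer scan is checked epoch-for-epoch
   against a brute-force O(n²) window enumeration
   (`isosub.validation.nonwear_mask_oracle`, JIT-compiled when numba is
   available) on fuzzed day-length series.
3. **Daily validity**: a day is valid with ≥ 10 h and ≤ 16 h of wear. The
   16-h cap (overnight wear) is applied per day, not per person —
   the conservative choice; both bounds are configurable. Days are calendar
   days in the stream's local clock.
4. **Intensity classification** of wear epochs by count cut-points.
   Defaults are the Evenson youth thresholds: sedentary ≤ 100 counts/min,
   MVPA ≥ 2296 counts/min; band upper edges are inclusive (our convention,
   stated here because the boundary epoch is otherwise ambiguous). Every
   wear epoch falls in exactly one band, so sedentary + LPA + MVPA equals
   wear minutes exactly on every day record.
5. **Per-person summaries**: means over valid days only; persons need ≥ 1
   valid day. Counts per minute (cpm) is the per-day ratio of wear counts
   to wear minutes averaged over valid days; the convention is not uniquely
   defined in the literature, and this choice matches how pooled-database
   descendants tabulate it.

## Synthetic cohort generator

The generator emulates the pooled sample's published structure: 13 study
clusters, 18,200 persons by default, ages 4–18 split as children (< 10),
adolescents (10 to < 15) and older adolescents (≥ 15) with the published
group mix, and per-group behaviour means/SDs equal to the published
descriptives (e.g. adolescents: sedentary 372 (82), LPA 361 (65), MVPA
54 (29) min/day).

Behaviours are drawn as independent truncated normals (truncated at 0) and
**wear time is defined as their sum**. The published tables give only
marginal means/SDs, not a joint model; closing the composition by summation
(rather than rescaling the behaviours to a separately drawn wear total)
keeps each behaviour exactly on its configured marginal and guarantees the
sum constraint S + L + M = T that the substitution algebra relies on. The
cost is that simulated wear time has a slightly different mean/SD than the
published wear row (the published behaviours sum to 774, not 779 min/day in
adolescents, and real behaviours are negatively correlated); the published
wear values are used only to schedule day lengths.

Outcomes follow the partition-model data-generating process per age group:

    y = α + b_sed·(S/10) + b_lpa·(L/10) + b_mvpa·(M/10) + γ·sex [+ δ·WC]
        + u_study + ε,   u ~ N(0, σ_u²),  ε ~ N(0, σ_e²)

with sex ~ Bernoulli(0.5) coded 0 = female, 1 = male. The default planted
model is waist circumference with the published adolescent coefficients:
the partition sedentary coefficient 0.035 cm per 10 min/day anchors the
scale, and b_mvpa, b_lpa are placed so the substitution contrasts equal the
published isotemporal estimates exactly (b_mvpa − b_sed = −0.589,
b_lpa − b_sed = −0.046 cm per 10 min/day). The published partition MVPA
coefficient (−0.555) would give a contrast of −0.590 — a 0.001 printing
inconsistency across independently rounded fits; the contrasts are taken as
authoritative. Per-group intercepts are solved so group outcome means land
on the published values. The study-intercept and residual SDs are **not
published**; defaults are order-of-magnitude choices (25% and 85% of the
mean published outcome SD respectively) and should be treated as such.
Skewed outcomes (insulin) can be generated multiplicatively by
exponentiating the linear predictor, to exercise the log-transform
sensitivity path.

Epoch streams are realised from integer day compositions: band counts are
drawn uniformly within each band's range, arranged in shuffled bouts, with
scheduled non-wear blocks (≥ 60 min of zeros) separated by more than the
interruption allowance. Wear epochs are strictly positive so detection
recovers the schedule exactly, which is what makes the roundtrip property —
process(realise(c)) = c, exactly — testable. Realistic features the
generator deliberately omits: diurnal profiles, autocorrelated counts,
zero-count wear epochs, device noise, day-to-day composition variation, and
realistic within-band count distributions (uniform draws inflate simulated
cpm relative to real children). Passing tests therefore demonstrate
correctness of the pipeline's logic and estimators under the stated model,
not robustness to real accelerometer artefacts.

## Substitution models

Before fitting, behaviours (and wear) are divided by 10 so coefficients are
per 10 min/day reallocated. The three model classes per outcome × age
group:

- **Single-factor**: one behaviour + covariates — the behaviour's total
  effect. Covariates mirror the partition set (sex; WC unless WC is the
  outcome) for comparability; wear time is excluded by default but exposed
  as a switch, since published descriptions of single-factor models rarely
  state it.
- **Partition**: all three behaviours + covariates, no wear time (wear is
  their sum, so including it would be degenerate). Coefficients are effects
  of adding time to one behaviour, the others held fixed.
- **Isotemporal substitution (ISM)**: drop one behaviour, keep the other
  two and wear time. The coefficient on a retained behaviour estimates
  reallocating time into it from the dropped behaviour, total time
  constant.

Because S + L + M = T, the ISM design is an invertible linear
reparameterization of the partition design: the ISM coefficient for j with
k dropped equals b_j − b_k. This identity is exact in the algebra and holds
to ≈ 1e-14 numerically; it is verified on fuzzed cohorts against a pooled
OLS oracle and under the random-effects estimator, and it forces exact
antisymmetry between the "reduce j" and "reduce k" table cells (published
tables show this only up to printed rounding, because each row came from a
separate fit).

**Estimation.** Two estimators share one design path:

- *Pooled OLS* (statsmodels), the reference estimator.
- *Random-effects GLS* with the study as the panel: Swamy–Arora variance
  components (σ_e² from within-study residuals with degrees of freedom
  n − G − rank; σ_u² from the between regression on study means, debiased
  by σ_e²/T̄ with T̄ the harmonic mean study size, floored at 0), then
  quasi-demeaning of y and X by θ_g = 1 − √(σ_e²/(σ_e² + T_g σ_u²)) and OLS
  on the transformed data. The θ range and both variance components are
  reported on every fit. One study ⇒ θ = 0 and the estimator reduces to
  OLS.

Variance is either conventional or cluster-robust (sandwich aggregating
score contributions by study). Cluster-robust p-values and CIs use the
normal reference distribution; with 5–13 clusters these intervals are known
to undercover somewhat, which we document rather than correct (small-sample
cluster corrections are out of scope). For that reason the simulation-based
coverage check of the planted ISM effect evaluates the random-effects
estimator's *model-based* interval, which is correctly specified under the
generator's own assumptions; cluster-robust remains the default for data
analysis, where the random-intercept model cannot be trusted.

Missing data are handled complete-case per model. Significance flags follow
the footnote convention * p < 0.05, ** p ≤ 0.001. Collinearity diagnostics
per fit: VIF_j = 1/(1 − R²_j) from regressing each exposure on the other
non-intercept columns, tolerance its reciprocal; rank-deficient designs
raise an error naming the offending columns. A sex × MVPA interaction
screen (Wald p for the interaction added to the partition model) is
provided for deciding whether sexes can be pooled.

## Reporting

Relative effects are 100·|β| divided by the age-group outcome mean, rounded
half-up to one decimal; they are invariant to outcome unit rescaling, and
the direction label (favourable/unfavourable) uses each outcome's risk
orientation (higher HDL-C good; everything else bad). The denominator is
the observed outcome mean among rows entering the fit unless an explicit
means table is injected. Against the published full-precision coefficients
and group means, nine published headline percentages reproduce exactly (WC
0.5/0.9/1.0%, SBP 0.1%, HDL-C 0.7%, LDL-C 0.9/0.5%, triglycerides 2.2%,
insulin 2.4%). The published *glucose* percentages (0.4%) do **not**
reproduce from the printed inputs (|−0.016|/5.16 ≈ 0.3%), so glucose is
excluded from the worked examples. Rendered tables use ASCII formatting
("-0.589", three decimals) rather than typeset minus signs, print "Dropped"
in the omitted behaviour's cell, and warn on missing model classes. Insulin
units are passed through as printed (labelled mmol/L at magnitudes 34.8–
74.3, which suggests pmol/L); no unit harmonisation is attempted.

## Problem sizes and numerical choices

The test-suite and acceptance problem sizes are chosen to make each
property sharp at interactive cost: 200 cohorts of n = 500 for the
reparameterization identity (tolerance 1e-8; observed ≈ 5e-14), 1,000
fuzzed day-length series for the non-wear oracle, 500 compositions for the
stream roundtrip (exact equality), and 500 replicates of adolescent-only
cohorts (13 studies × 154 persons) for planted-effect recovery — mean
estimate within 2 Monte-Carlo SEs of −0.589 and 95% CI coverage within
[93%, 97%]. The analysis drivers use a scaled-down cohort (13 × 48 persons,
3 days) whose epoch streams still exercise every processing rule. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; per-stage substreams are derived with
`SeedSequence` so stages are independently reproducible.

Degenerate inputs are errors, not silent repairs: non-divisor epoch
lengths, stream gaps, negative counts, infeasible truncations (mean more
than 8 SD below zero), compositions exceeding 24 h, non-wear blocks under
60 min, constant outcomes, single-sex strata in the interaction screen,
rank-deficient designs, cluster-robust requests with fewer than two
studies, and non-positive outcomes under a log transform (offending rows
listed).

## Known limitations

- The generator's independence of behaviours (before closure) understates
  the negative sedentary–activity correlation in real children; VIFs in
  simulated ISM designs (~1.5) are consequently mild, though comparable to
  the published diagnostics (mean VIF ≤ 1.75, tolerance > 0.62).
- Identical compositions across a person's days remove within-person
  variance; estimators that exploit repeated measures are out of scope.
- About 1 in 7 simulated persons draws a composition above the 16-h cap
  and loses all days to the validity rule — a deliberate consequence of
  calibrating to published marginals while enforcing the cap per day.
- No bout detection, vigorous band, triaxial input, compositional (ilr)
  analysis, multiple imputation, or small-cluster bootstrap.
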