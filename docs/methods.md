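# Methods

This note records the models implemented in `dietval`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Two-point DLW model

The engine assumes mono-exponential elimination of both tracers over the
metabolic period. With background-corrected enrichments (ppm excess over
the reference standard, the pre-dose sample as baseline):

- elimination constant: k = ln(E_plateau / E_final) / Δt, with Δt taken
  from the sample timestamps in hours/24 rather than assumed to be exactly
  7.0 days;
- plateau enrichment: arithmetic mean of the two same-day post-dose
  samples (the protocol collects two samples for exactly this purpose);
- dilution space by the plateau method: N = dose·(E_dose − E_tap)/(E_plateau
  − E_pre), with the dose excess taken as APE·10⁴ ppm and tap water assumed
  at the reference standard;
- TBW = (N_d/1.041 + N_O/1.007)/2, the divisors correcting each tracer's
  apparent space for in vivo exchange; FFM = TBW/0.732; FM = weight − FFM;
- rCO₂ = 0.4554·N·(1.007·k_O − 1.043·k_d)·22.26 with N the mean of the
  two spaces in mol. The combination rule for N is a genuine free choice
  (the source protocols say only that both spaces inform it); the mean is
  the default and the config exposes the constants;
- TDEE = rCO₂·(1.106 + 3.94/RQ).

**RQ.** The respiratory quotient is not measurable by DLW and must be
assumed. Default 0.85, a typical food quotient for a mixed Western diet;
configurable in (0.67, 1.3]. Every TDEE result records the RQ used.

**Quality control.** The dilution-space ratio N_d/N_O is checked against
(1.000, 1.070) and the elimination-rate ratio k_O/k_d against
(1.100, 1.700) by default; both ranges are configurable. Values outside a
range are flagged, never dropped. Negative rCO₂ (kinetics inconsistency)
and FFM exceeding body weight are likewise returned flagged rather than
clipped, so the caller decides.

## Intake aggregation

An eating occasion is a 'before' image record closed by an 'after' record
(leftovers) or an 'ate everything' record (zero leftovers). Consumed
energy per occasion is before − after, floored at 0 with a warning when
leftovers exceed the before total (a recording error, physically
impossible). Closing records match the most recent open 'before' of the
same participant-day; unmatched closers are kept in the table but ignored
in aggregation, with a log entry, and never dropped silently. Days with
no recorded occasion enter the series with zero intake by default — not
recording is itself the reporting behaviour under study — and a switch
(`IntakeSeries.include_zero_days`) excludes them instead, since the source
protocols do not say which convention was used.

Within-subject variation uses the sample (n−1) SD because per-participant
day counts are small: CV_i = 100·SD/mean over a participant's days, and
the cohort value CV_wTDEI is the root mean square of the CV_i.

## Goldberg cut-offs

S = √(CV²_wTDEI/d + CV²_wB + CV²_tP), with the band
PAL·exp(sd·S/(100·√n)) for sd = ±2. Defaults: d = 6 assessment days (the
value consistent with both published S calculations this package
reproduces; configurable), CV_wB = 4.1% (BMR repeatability for
free-living women). CV_wTDEI and CV_tP default to study-specific values
computed from the cohort (pooled intake CV, and 100·SD/mean of the
individual PALs); literature values can be substituted via config.

Cohort PAL is the mean of individual TDEE:BMR ratios by default (the
ratio-of-means variant is available); boundary ratios classify as
plausible because under- and over-reporting are defined by strict
inequalities. BMR uses Mifflin-St Jeor; the revised Harris–Benedict
equation is provided alongside because published cohort BMR tables are
sometimes closer to it.

The energy-balance method is ΔES = (ΔFM_g·9.5 + ΔFFM_g·1.1)/days, the
standard tissue energy densities.

## Agreement statistics

- Bland–Altman: differences are test − reference. LoA = bias ± 1.96·s
  (fixed multiplier). CIs of bias and LoA use the t quantile with n−1 df
  — not 1.96 — with SE bias = s/√n and SE LoA = s·√(3/n) (the classical
  approximation); the t choice reproduces the published confidence bounds
  this package's tests check.
- Paired tests are gated on Shapiro–Wilk at α = 0.05: paired t if the
  differences pass, Wilcoxon signed-rank otherwise. Zero-variance
  differences yield a degenerate result with the bias but no p-value.
  p-values are Bonferroni-multiplied (default ×3, the three pairwise
  method comparisons) and capped at 1.
- Pearson results always carry both r and r², explicitly labelled,
  because validation reports frequently conflate them (including printing
  signed "R²" values that can only be r).
- MPD is the mean of individual percentage differences 100·(aᵢ−bᵢ)/bᵢ,
  not the percentage difference of group means; the two differ materially
  when the spread is wide, and tests pin the definition against a
  brute-force loop. Exact-zero differences are counted separately rather
  than forced into either side.
- ICC: one-way random-effects σ²_b/(σ²_b + σ²_w). On balanced data the
  ANOVA (method-of-moments) estimator is used directly; on unbalanced data
  variance components come from REML (statsmodels MixedLM) — for a
  balanced one-way layout the two coincide whenever the between component
  is positive, and a test cross-checks the paths. The confidence interval
  is the exact F interval on the ANOVA representation with Searle's
  effective group size n₀ for unbalanced layouts. With zero within-subject
  variance the interval degenerates to (1, 1).

## Synthetic cohort generator

The generator emulates: 30 adult women with anthropometrics drawn from
truncated normals (age 28.5 ± 6.7 y, height 1.63 ± 0.07 m, weight
57.8 ± 6.1 kg, joint rejection until BMI ∈ [18.5, 24.9]); a body-fat
fraction of 0.28 ± 0.04 (a realistic range for normal-weight young women)
giving FFM, FM, and TBW = 0.732·FFM; TDEE ~ 2235.2 ± 456.5 kcal/day;
isotope kinetics constructed by exact inversion of the engine's chain
(dilution-space ratio drawn uniformly in the observed 1.005–1.035 band,
elimination-rate ratio in 1.193–1.366, dose by the 1.8 / 0.12 g per kg TBW
rule), so that with zero enrichment noise the engine recovers the true
TDEE to machine precision; and reported intake with a within-subject CV
of 42.55%.

Reporting error is decomposed into a participant-level additive bias
(app −329.6 ± 599.1, recall −543.0 ± 642.6 kcal/day) and day-level
lognormal variation. The day multiplier applies to the *biased* mean, so
the CV of reported days — the quantity a validation study actually
measures — equals the configured within-CV; intake positivity motivates
the lognormal. A biased mean below 50 kcal/day is clamped (a participant
cannot report negative intake); at the default conditions this is a
<1% tail event with negligible effect on bias recovery.

Energy balance: true mean intake = TDEE + imbalance, imbalance ~ N(0,
250 kcal/day) by default — free-living weight drift of a few hundred
grams over a week. The realized weekly energy gap is converted to body
stores with 75% of the energy entering fat mass, and weight change is the
resulting mass change; `delta_energy_stores` inverts it exactly. With
`energy_balance=False` intake equals TDEE and weight is held stable.

App days are split into 3–9 eating occasions (Dirichlet shares around a
7.5 ± 1.9 occasions/day draw); ~20% of occasions close with an 'after'
record holding 5–30% leftovers, the rest with 'ate everything', so paired
records aggregate back to the daily totals exactly. Macronutrients scale
proportionally with energy at fixed g/kcal ratios per tool. The recall
reports a single day with its own bias draw.

Not emulated: food-item identity, portion-size estimation error as a
separate channel (it is folded into the bias and day noise), intra-day
timing structure beyond evenly spaced occasions, correlation between
reporting bias and anthropometrics, and isotope-sample memory or
calibration effects. Passing recovery tests therefore show that the
estimators are correct for the assumed error structure, not that any
particular real instrument follows that structure.

One global seed drives everything through named substreams (cohort,
isotopes per participant, intake per tool and participant), so any single
stage can be regenerated independently and every run is reproducible.

## Problem sizes and tolerances

Recovery suites run at the study scale (30 participants × 7 days):
bias-recovery coverage uses 500 seeded replicates against the nominal 95%
CI with a ≥ 90% pass criterion; ICC recovery uses 200 replicates at
σ²_b/(σ²_b+σ²_w) = 0.25 with a ±0.1 band on the mean estimate; the
pooled-CV check uses 60 replicates with a ±5-point band. Exact arithmetic
identities (band symmetry, LoA width, unit coherence) are asserted at
1e-9–1e-12; the noise-free DLW round trip at 1e-6 relative. Distribution
checks (mean weight ±0.2 kg) use n = 10,000 draws.

## Known limitations

- The ICC confidence interval is the one-way exact-F interval even when
  components come from REML on unbalanced data; for mildly unbalanced
  weekly designs the approximation error is small.
- The Goldberg classification treats BMR as error-free at the individual
  level; BMR equation error enters only through CV_wB in the band width.
- The Bland–Altman model is level-independent: proportional bias is
  visible in the plot helper but deliberately not modelled.
- The generator's truncated-normal anthropometrics with BMI rejection
  shift the marginal means slightly from their nominal values (< 0.1 kg
  at the defaults); tests account for this with the stated bands.
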