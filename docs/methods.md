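# Methods

`sustdiet` implements an end-to-end analysis of how adherence to a
planetary-health diet relates to nutrient adequacy, mood, vagal heart-rate
variability and cognition, together with a synthetic-cohort generator that
plants known effects so the whole chain is testable without participant
data. This note records the models, the defaults and why, and what the
synthetic experiments do and do not demonstrate.

## Dietary assessment

**FFQ to intakes.** Food-frequency responses are ordinal codes 0–8
(never/<1 per month up to 6+ per day), each carrying a servings/day
multiplier (`data/frequency_multipliers.csv`); multiplied by the item's
portion size this gives g/day. Nutrients accumulate linearly through a
bundled ~39-item composition table (`data/composition.csv`) — a **synthetic
miniature** with realistic per-100 g values, not an excerpt of any licensed
database. Food-group masses accumulate through fractional allocations
(`data/allocations.csv`); fruit juice contributes half its mass to total
fruit and half to sugar-sweetened-beverage mass, the miniature analogue of
disaggregation rules in full FFQ-processing software. Participant-specified
"other foods" extend both the intake map and the table; a duplicate item
name must carry an identical composition row and its amounts are summed.

**Diet indices.** Both indices score components piecewise-linearly on
0–10 and sum with equal weight.

* *WISH* (13 EAT-Lancet food groups, total 0–130). Protective groups ramp
  from 0 at zero intake to 10 at the reference intake (whole grains 232,
  vegetables 300, fruits 200, fish 28, legumes 75, nuts 50, unsaturated
  oils 40 g/day); limited groups score 10 at/below the reference cap and
  decay to 0 at an upper anchor (red meat 28→100, poultry 58→116, eggs
  25→75, saturated oils 11.8→47, added sugars 31→124 g/day); dairy is
  range-peaked (10 on 250–500 g/day, 0 at zero and at 1000 g/day). The
  added-sugars component scores added-sugar *mass* from the nutrient
  accumulation, not beverage mass. All anchors ship as editable CSV and
  are **reconstructed defaults**: published component-level summaries
  constrain them only loosely, and totals on real data are not claimed to
  match any specific published appendix.
* *Modified AHEI-2010* (10 components, total 0–100; alcohol excluded and
  treated as a covariate). Cutoffs follow the published 2010 construction
  (vegetables 0→5 servings/day, fruit 0→4, whole grains 0→75 g/day,
  nuts+legumes 0→1 serving/day, long-chain n-3 0→250 mg/day, PUFA 2→10 %
  energy, and reversed SSB 1→0 servings, red/processed meat 1.5→0
  servings, trans fat 4→0.5 % energy, sodium 3337→1112 mg/day). Fat
  components convert to % energy at 9 kcal/g; PUFA excludes long-chain
  n-3.

**Adherence.** Per food group: gap = mean intake − recommended level (the
range midpoint when a range is recommended), a paired t test of actual
versus recommended, and % non-adherent = share outside [min, max]. A
zero-variance difference vector is flagged degenerate rather than
producing a spurious t.

**Tertiles.** Boundaries at the 33.3rd/66.7th percentiles; boundary ties
go to the lower tertile for reproducibility; an all-equal score vector
degenerates to a single group with a warning.

## Nutrient adequacy

Ten nutrients are scored against UK Reference Nutrient Intakes for adults
(19+), sex-specific where UK values differ (`data/rni_uk.csv`). An intake
strictly below the RNI is flagged; intake exactly at the RNI counts as
adequate. NAR = 100 × min(intake/RNI, 1); MAR = unweighted mean NAR, so
MAR = 100 iff every nutrient meets its RNI. Below-RNI flags feed 2×2
cluster-by-adequacy tables tested by Pearson chi-square **without
continuity correction** — the convention that reproduces published
statistics of this kind exactly; pairs with missing flags are dropped, so
the effective n is reported per nutrient.

## Heart-rate variability

Input is a beat-to-beat R-R interval series (plain text, ms/beat), with
each interval timestamped at its ending R peak. The pipeline:

1. *Artifact detection*: flag beats deviating from the median of up to 11
   surrounding beats (5 each side, centre excluded) by more than 0.45 s.
   The "local average" definition is ours; the moving median makes the
   detector robust to bursts of consecutive ectopics.
2. *Correction*: cubic-spline interpolation over clean beats, evaluated at
   the flagged beat times. Beat times are left untouched, so total
   duration is preserved exactly; the residual error is the interpolation
   error at the flagged beats.
3. *Resampling*: cubic spline through (beat time, interval) pairs,
   evaluated on a 4 Hz grid.
4. *Welch PSD*: Hann windows of 120 s with 50% overlap and linear
   detrending (recordings are six minutes, so the Kubios-style 300 s
   default would leave a single window; 120 s gives five half-overlapped
   windows). All parameters are exposed.
5. *Band power*: trapezoidal integral over 0.15–0.4 Hz, reported absolute
   (s², also ms²) and in normalized units = 100 × HF/(total power above
   0.04 Hz). Normalized units are the default analysis input because
   published descriptive magnitudes (~50) match a percentage, not ms²;
   this is a reconstruction, flagged as such.

With the generator's additive two-sinusoid R-R model, a 0.25 Hz
modulation of amplitude A carries analytic power A²/2, which the pipeline
recovers within 10% (and ×16 within 5% under amplitude quadrupling). The
cubic-spline tachogram error for a 0.25 Hz sinusoid falls below 1% of
amplitude once beats are ~0.6 s apart; at 0.85 s spacing it is ~2%, which
is irrelevant to band power but visible in waveform comparisons.

## Statistical battery

* **Mood harmonisation**: POMS (elated–depressed, 0–36, higher = better)
  and PANAS negative affect (10–50, higher = worse) are collapsed into
  within-scale quantile groups (default Q = 4, consistent with published
  group means of ~2.0–2.6 on the harmonised scale); group 1 = best mood.
  Ties break by input order, deterministically.
* **Log transform** of a variable iff |sample skewness| > 1; zeros offset
  by half the smallest positive value.
* **Paired t, Pearson chi-square (no continuity correction), BH-FDR**
  (step-up at q = 0.05 by default; a published "δ = 0" is treated as a
  typographical slip).
* **Cook's distance exclusion**: distances from the full-sample step-2
  fit; cases with D > 4/N excluded once, no iterative refitting. Note the
  4/N rule is aggressive: on *clean* simulated cohorts it removes ~6% of
  cases and biases a planted standardized effect of −0.30 to ≈ −0.33.
  The calibration experiments therefore disable it (nothing is planted
  for it to catch), while the applied pipeline keeps it as the default
  contamination guard.
* **Hierarchical regression**: step 1 enters sex, BMI, kcal, alcohol,
  exercise; step 2 adds the diet score. All variables are z-scored on the
  analysed (post-exclusion) sample; reported are standardized β with 95%
  CIs, R² per step, and the R²-change F =
  ((R²₂−R²₁)/q)/((1−R²₂)/(N−p₂−1)).
* **Repeated-measures AN(C)OVA**: univariate (contrast-transformed) sums
  of squares. Each within effect uses an orthonormal contrast basis;
  contrast scores are regressed on the between design (intercept +
  mean-centred continuous covariates, so within effects are evaluated at
  the covariate mean). Mauchly's test runs on the contrast-space residual
  covariance; when it is significant at 0.05 the Greenhouse–Geisser ε
  (clipped to [1/(k−1), 1]) rescales both df. A two-level factor always
  has ε = 1. The implementation is cross-checked against an independent
  statistics package on covariate-free designs, and its type-I rate under
  a planted null is 0.03–0.07 at nominal 0.05 over 500 simulations.
* **Cognition-log scoring**: serial sevens → % correct of 28 trials and
  mean RT; flanker → % correct and mean RT per condition over 72 trials;
  word recall → abstract/concrete counts at immediate and delayed phases
  against the 30-word list (case-insensitive membership).

## Cluster analysis

K-means (Euclidean, k-means++ starts, best of 50 restarts by within-SS,
seeded) on the 13 **standardized** WISH component scores of the top
WISH tertile — components, not raw g/day, because published cluster
profiles are reported as standardized component means. Components that
are constant within the tertile (e.g. a saturated added-sugars score)
carry no information and are dropped with a warning. The judgement-based
k choice is codified reproducibly: chosen k = the largest k in 2–6 whose
marginal gain in variance explained is ≥ 10 percentage points and whose
smallest cluster holds ≥ 10% of the sample; no qualifying k flags "weak
structure", and gains vetoed only by the size rule are recorded as
overrides. Cluster comparisons use one-way ANOVA (F, p, η²) for
continuous variables and the chi-square route above for adequacy flags.

## The synthetic cohort

The generator emulates the *structure* of a young-adult UK cohort
(default N from the published fractions 216/328, 54/328, 57/328, giving
216/54/57 by per-archetype rounding — the published headcounts are
internally inconsistent by one) with three archetypes:

* *unsustainable* (majority): meat-heavy, refined grains, few vegetables,
  sugary drinks; WISH ≈ 58, MAR ≈ 84.
* *balanced* sustainable: high plants and fish, moderate meat;
  WISH ≈ 83, MAR ≈ 97.
* *restricted* sustainable: red meat, poultry and fish near zero, low
  unsaturated oils, fortified plant milk; WISH ≈ 91 but MAR ≈ 90, with
  planted below-RNI shortfalls in protein, zinc, selenium, iron and
  folate relative to the balanced pattern.

Item-level servings/day are log-normal around archetype profile means
(`data/archetype_profiles.csv`), snapped to the FFQ's frequency grid, and
pushed through the same FFQ → composition pipeline the analysis uses, so
scores, nutrients and MAR are internally consistent rather than drawn
directly. Profile means were calibrated once so that scored WISH
components approximate published cluster-level component means and the
restricted-pattern shortfalls have the planted contrasts; nutrient
prevalences that could not be matched simultaneously (notably calcium and
iodine, which track dairy mass, and a restricted protein shortfall
stronger than the published 15.5%) were resolved in favour of the
component scores and the planted contrasts, and are documented here
rather than silently matched.

Mood is a latent negative-affect variable, linear in the
cohort-standardized MAR with standardized slope `diet_mood_beta`
(default −0.3) plus independent Gaussian noise scaled so the latent
variance is 1; it is emitted on POMS or PANAS (default 80%/20% mix) so
harmonisation is exercised. Because the effect is planted on adequacy,
the WISH→mood association is *induced* through the WISH–MAR correlation
(~0.5 under the defaults) — the generator reproduces the qualitative
pattern that overall sustainable-diet adherence predicts better mood
while the restricted sub-pattern predicts worse mood, without hard-coding
either regression coefficient. The balanced-vs-restricted MAR gap is
about one cohort SD, so the cluster-level mood contrast is d ≈ β-sized;
cluster-mood significance in a majority of seeds is demonstrated at a
planted β = −0.5 (at β = −0.3 the contrast at n ≈ 111 is underpowered by
design, mirroring a small-to-medium effect).

R-R series use the additive two-sinusoid model above (0.25 Hz "vagal"
and 0.10 Hz gains per archetype, beat-wise Gaussian noise, mean RR
~0.85 s, 360 s duration) with optional ectopic corruption (default 1% of
beats shifted ±0.6 s) to exercise artifact correction. Task logs are
Bernoulli/Gaussian trial draws (28 serial-sevens trials, 72 flanker
trials balanced over three conditions, 15+15-word recall with delayed
retention), independent of diet by default.

**What the generator does not emulate**: FFQ item-level measurement
error and correlated response styles; seasonal/weekday intake variation;
real food-composition covariance across the full item bank; non-sinusoidal
HRV (respiratory frequency drift, nonstationarity); item-level mood
psychometrics. Passing the planted-effect tests therefore shows the
*estimators* are calibrated and the pipeline is internally consistent —
not that the published effect sizes would replicate in new data.

## Numerical choices and degenerate inputs

Deterministic seeding throughout (`numpy.random.default_rng`); equal
seeds give byte-identical serialized cohorts. Zero-variance paired
differences, all-equal tertiles, constant clustering columns, sub-Q mood
groups and perfect regression fits are all handled explicitly (flag,
warning or informative error rather than NaN). Proportions are
apportioned by largest remainder when they sum to 1 exactly, per-archetype
rounding when quoted as published rounded fractions. Experiment sizes in
the test-suite and acceptance script (100-seed coverage, 500-rep type-I,
50-seed cluster recovery, 10-seed ARI summary) were chosen to keep Monte
Carlo error small relative to the asserted margins.

## Known limitations

Index anchors are reconstructions; absolute WISH/AHEI totals are not
comparable to unpublished appendix scorings. The miniature composition
table cannot reproduce population-level nutrient distributions (folate
and calcium prevalences deviate most). Headline regression and ANOVA
statistics of the motivating cohort depend on its deposited data and are
covered here only as sign-and-significance patterns, not numerically.
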