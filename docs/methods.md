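# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `tierstack`, in the order the pipeline
runs them.

## 1. Outcome schemes

Annual usage counts are partitioned by a `UsageClassScheme` into four tiers:
tier 0 is `[0, t1)`, tiers 1–2 are the half-open bands `[t_k, t_{k+1})`, and
tier 3 is `≥ t3`. The packaged schemes are LOS `(7, 14, 30)` bed days and ED
`(3, 5, 10)` visits. The boundary convention is "count ≥ threshold"
throughout, so the three binary exceedance labels form a monotone staircase
that reconstructs the tier exactly (`tier = number of thresholds cleared`);
this identity is enforced by exhaustive and property-based tests. Alternative
schemes are plain config (name + thresholds). Ordinal-regression outcome
models are out of scope.

## 2. Synthetic registry generator

The generator emulates the statistical shape of a large chronic-disease
registry without using any real data. Per patient: a persistent latent
frailty `u ~ N(0,1)`; age, sex, four comorbidity indicators (prevalence
increasing in frailty and age), mean HbA1c, and an ordinal housing category;
a linear risk score `s` combining them. Per calendar year,
`eta = s + N(0, 0.55)`.

* **Counts.** Any inpatient usage is Bernoulli with logit
  `z0 + 1.1·eta`; given usage, bed days are `1 + NegBinom` with log-mean
  `1.0 + 0.55·eta` and dispersion 0.9. ED visits follow the same
  zero-inflated negative-binomial structure with its own coefficients.
  The usage intercept `z0 = −1.4955` is the frozen output of
  `calibrate_usage_intercept`, a bisection against a 10⁶-draw Monte Carlo
  oracle targeting 36% annual usage prevalence (the generator's declared
  calibration target; registry-scale reports place the share of patients with
  any inpatient usage at roughly 35–37%). No public dispersion or
  zero-inflation figures exist for these counts, so those parameters are
  calibration choices, selected once for realistic tier prevalences
  (~86 / 7.9 / 4.6 / 1.4% across LOS tiers), not facts about any registry.
* **Costs.** `cost = bed_days × charge × tail`, with per-day charge
  LogNormal(log 700, 0.6) SGD and tail multiplier `1 + Lomax(shape 2.0,
  scale 1.6)`. Aggregate cost is therefore Pareto-tailed. The tail and
  charge dispersion were calibrated jointly so that the top decile of
  patients holds 80% ± a few tenths of a point of total cost at n = 10⁵
  (stable across seeds; the Lomax shape of 2.0 keeps the mean finite and the
  share estimator well behaved). Mean cost per patient with usage lands near
  SGD 17k. Zero bed days always means zero cost, and Spearman correlation
  between cost and bed days exceeds 0.95 by construction.
* **Structure.** Counts are generated for `n_years + 1` calendar years;
  record `y` pairs year `y` (predictors) with year `y+1` (targets), so a
  patient's "next" counts reappear as the following record's "current"
  counts, and the frailty induces genuine year-to-year usage correlation.
  One record per patient per year; identical spec + seed reproduces the frame
  byte for byte. An optional `missingness_rate` drops records uniformly,
  emulating complete-case exclusion; no NaNs are ever emitted.

What the generator does **not** emulate: registry coding of comorbidities,
realistic covariate marginals beyond plausibility, informative missingness,
COVID-era utilisation shifts, or a risk signal that is mostly *observable*.
The last point matters when interpreting pipeline output: the frailty (SD
0.75 within `eta`) is hidden from the models, so base-learner AUROCs on
synthetic cohorts sit near 0.65–0.75 and identified-user percentages are far
below those achievable on large real registries. Passing tests demonstrate
the machinery and its invariants, not clinical-grade discrimination.

## 3. Base learners

Each (outcome, threshold) task gets an independently trained binary model —
no shared ordinal structure — in one of four families:

| family | implementation | notes |
|---|---|---|
| `logistic` | unpenalized `LogisticRegression` after standardization | plain GLM maximum likelihood, so a saturated fit reproduces closed-form 2×2 odds ratios |
| `boosted_tree` | `XGBClassifier` defaults | seeded |
| `mlp` | `MLPClassifier` defaults after standardization | default `max_iter` retained; convergence warnings suppressed during fit |
| `mars` | spline basis expansion (degree 2, 4 knots) + L2 logistic | an adaptive-spline stand-in for the MARS family behind the same scorer interface; the family tag is preserved in reporting |

Hyperparameters are deliberately library defaults (no tuning, no probability
calibration); only explicit overrides are honoured. Model seeds are derived
per (family, outcome, threshold) from a master seed via `SeedSequence`
hashing. Inputs must be complete cases; missing values raise. Because the
three threshold models are independent, a probability triple can violate
monotonicity (`p_1 ≥ p_2 ≥ p_3`); `monotone_violation_rate` reports the
prevalence of such triples without correcting them.

## 4. Stacking ensemble

Meta-features are `(p_1, p_2, p_3, current-year usage)`. The training year is
split 75:25 (stratified by tier by default; a flag disables stratification),
and **random upsampling to equal tier counts is applied to the train side
only, after the split** — balancing before splitting would leak duplicated
minority rows into the test set. Base probabilities are computed once per
patient-year and duplicated by the upsampling, not re-estimated on resampled
rows. The meta-learner (random forest, boosted trees, or linear SVM; library
defaults, seeded) then fits the four-tier outcome; `fit_meta` refuses
unbalanced labels unless balancing is explicitly waived. Linear SVM tier
scores for AUROC are decision values mapped through a softmax; tree
tie-breaks follow library defaults under the fixed seed.

Temporal validation applies the frozen base scorers and meta-learner forward
to the next year's records; a `refit_base` flag instead re-estimates base
learners on the validation-year records before scoring them (off by default —
freezing matches deployment and avoids using validation-year labels).

A practical observation reproduced by the package: with library-default
boosted trees or random forests as meta-learners, the duplicated upsampled
rows are easy to memorise (near-perfect balanced-training accuracy), and
out-of-sample predictions drift back toward the majority tier; the linear SVM
meta-learner flags substantially more users at the cost of more unnecessary
predictions. This trade-off is surfaced by the program metrics rather than
hidden.

## 5. Evaluation

* **Program metrics** partition actual users into correct / under / over /
  missed (percentages of users; they sum to 100 exactly in exact arithmetic)
  with `identified = 100 − missed`, and report unnecessary predictions as a
  percentage of actual non-users. The cell definitions were chosen so that
  these identities close on every published row they are checked against;
  percentages are reported to 1 decimal place.
* **Accuracy** uses the exact binomial (Clopper–Pearson) 95% CI.
* **Multiclass AUROC** is the unweighted (macro) mean of one-vs-rest AUROCs.
  Each tier's variance comes from the DeLong structural-components estimator;
  the macro variance treats tiers as independent (sum of variances over k²).
  A tier with no positives or no negatives is dropped from the average with a
  warning, never silently zeroed. (Named-tool conventions: DeLong for AUROC,
  exact binomial for accuracy.)
* **Per-class diagnostics** collapse each tier one-vs-rest; ratios with empty
  denominators are NaN markers, never silent zeros.

## 6. Economic impact simulation

Eligibility defaults to `identified_users` (actual users flagged into any
tier); `correct_only` restricts to exact-tier hits. Reached non-users accrue
zero benefit (they have no next-year inpatient cost to reduce) and are
reported separately as intervention burden.

The fixed-effects benchmark is `0.5 × Σ eligible costs` (uniform 50% benefit,
full reach) — an optimistic upper bound. The Monte Carlo default scenario
uses 10,000 iterations; tier-level reach `Normal(0.50/0.70/0.90, 0.05)` for
predicted tiers 1/2/3 (tier 0 receives no intervention), per-patient
Bernoulli uptake at the drawn reach, and benefit fractions
`Normal(0.20, 0.05)` drawn per patient (a per-iteration switch exists, which
raises between-iteration spread at equal mean). Dispersions are standard
deviations on the fraction scale — an SD of 0.05 around a 0.90 mean spans
0.85–0.95 at ±1σ. All normal draws are **truncated by clipping** to [0, 1]:
simple, monotone, and documented; consequently no draw can exceed the total
eligible cost. Lognormal and gamma benefit distributions are available
behind a switch (moment-matched, then clipped); normal is the default.
Iterations are generated in fixed chunks of 512 so results are independent of
memory layout. Summaries use linear-interpolation quantiles and sample SD
(ddof = 1; 0 for a single draw). The dominant model maximises the median
total benefit; ties break by higher mean, then lexicographic id, logged.

Currency is SGD; `sgd_to_usd` divides by 1.370 (SGD per USD). Intervention
costs, ROI netting and multi-year projection are out of scope.

## 7. Sensitivity grid

For one predicted tier at a time (patients predicted into other tiers are
excluded from the cell simulations), reach and mean benefit are swept over
strictly increasing levels (default 0.1–0.9 step 0.1 → 81 cells, 1000 runs
per cell). Within a cell the reach is fixed (SD 0), so stochasticity comes
only from Bernoulli uptake and benefit draws. Cell seeds derive from
(grid seed, tier, reach index, benefit index), making cells independent yet
reproducible, and a 1×1 grid reduces exactly to a direct Monte Carlo run
under the matched scenario. "Average benefit per patient" divides each
iteration's total by the number of patients *reached* in that iteration
(iterations reaching no one are excluded from the per-patient summary); a
switch changes the denominator to all eligible patients. On heavy-tailed
cohorts the per-patient IQR narrows as reach grows, since more of the tail is
averaged in. Surfaces export to long-format CSV/JSON for 3-D plotting; a
static matplotlib rendering is optional.

## 8. Orchestration and reproducibility

`run_all` executes simulate → temporal split → 12-combination sweep per
outcome → evaluation → ranking (correct predictions desc, identified users
desc, id asc; top-5 slice) → Monte Carlo economics of the top models for LOS
→ dominant-model selection → sensitivity grids. One master seed fans out to
every stage via `SeedSequence` hashed with stage tokens, so adding a stage
never disturbs existing seeds and the whole run is bit-reproducible. Each
stage logs record counts; failures abort with a stage-tagged error, retaining
partial outputs next to a `FAILED` marker. The manifest records seeds,
library versions and artifact paths.

Default problem sizes in the packaged configs and tests are desk scale
(cohorts of 1,200–10,000 patients, reduced iteration counts) — chosen so the
full pipeline and suite run comfortably on a laptop core; the generator and
simulators scale linearly to registry-sized inputs, and the calibration
checks run at n = 10⁵.

## 9. Known limitations

* Synthetic cohorts demonstrate mechanics, not achievable discrimination;
  absolute metric levels on them should not be quoted as model performance.
* Non-monotone base-probability triples are reported, not repaired.
* Upsampling plus default tree meta-learners can memorise duplicates (see §4).
* The benefit model ignores intervention costs and within-tier effect
  heterogeneity; reach and benefit are independent draws.
* No hyperparameter tuning, probability calibration, voting ensembles,
  ordinal classifier chains, or decision-curve analysis.
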