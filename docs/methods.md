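# Methods

This note records the statistical models the package implements, the
design choices made where the underlying methodology left the design
open, and what the synthetic-data generator does and does not emulate.

## Study design being modelled

The pipeline reproduces the analysis of a cross-sectional gene–diet
interaction study: apparently healthy obese adults (BMI ≥ 30 kg/m²,
ages 20–50), a semi-quantitative FFQ converted to g/day food-group
intakes, fasting biomarkers, duplicate blood-pressure readings, a
PCR-RFLP genotype for the FADS2 rs174583 C/T variant, and sex-stratified
inference on diet-quality tertiles. Subjects with reported energy
outside 800–4200 kcal/day are treated as implausible reporters and
excluded; the energy interval is closed (a report of exactly 800 or
4200 kcal/day is retained, since only values *outside* the range are
excluded).

## Diet scores

**DASH (Fung construction).** Eight components. Five emphasized food
groups (fruits, vegetables, whole grains, low-fat dairy, and nuts +
legumes merged into one component) score their sex-specific quintile
rank 1–5; three discouraged components (sodium as a nutrient, red +
processed meat, sweetened beverages) score 6 − rank. The merge of nuts
and legumes is the only component layout consistent with both "eight
components" and the 8–40 total range. Quintile boundaries sit at the
20/40/60/80th empirical percentiles (linear-interpolation quantiles)
within each sex; a subject's rank is one plus the number of boundaries
its intake strictly exceeds, so ties share the lowest qualifying
quintile and a degenerate constant stratum collapses to rank 1.

**MDS (Trichopoulou construction, alcohol-free).** Eight binary
indicators at sex-specific medians: vegetables, legumes, fruits + nuts,
cereals, fish + seafood and the MUFA:SFA ratio score 1 at or above the
median (at-median belongs to the "≥" side by the score's definition);
meat and dairy score 1 below the median. A subject with SFA = 0 has an
undefined ratio and is left unscored for that component and the total.

**Tertiles.** Cut points at the 33.3/66.7th percentiles per stratum,
ties to the lower tertile. Tertiles are assigned after eligibility
filtering, i.e. the quantile machinery sees only the analysed cohort.

## Derived phenotypes

* Friedewald LDL-C = TC − HDL-C − TG/5 (mg/dl), enforced invalid at
  TG ≥ 400 mg/dl (configurable to return a missing value instead).
* AIP = log₁₀(TG/HDL-C).
* HOMA-IR = glucose × insulin / 405 (mass units, mg/dl × µU/ml); QUICKI
  = 1/(log₁₀ insulin + log₁₀ glucose). Both constants are the standard
  mass-unit forms and are configurable.
* Metabolic syndrome: NCEP ATP III — ≥ 3 of {WC > 102 cm (men) / 88 cm
  (women); SBP ≥ 130 or DBP ≥ 85 mmHg; TG ≥ 150; HDL < 40 (men) / < 50
  (women); glucose ≥ 100}. An alternative ruleset (`unisex_wc88`: WC >
  88 cm for everyone, glucose ≥ 110) is available by name, reflecting a
  second definition sometimes used for predominantly female samples.
* Risk flags: TC ≥ 220, LDL ≥ 160, sex-specific low HDL, TG ≥ 150,
  BP ≥ 130/85, glucose ≥ 100, HOMA-IR > 2.6 (strict), QUICKI below a
  configurable cut. The QUICKI cut defaults to 0.33; a sometimes-quoted cut of
  "38" in some sources is a typographical artifact of the 0–1 index and
  is not used.
* DASS-21: subscale = 2 × sum of its seven 0–3 items (0–42, always
  even), severity from the Lovibond bands shipped as editable config.
* Blood pressure is the mean of the two readings; if one is missing the
  available reading is used.

## Inference

Adjustment sets: crude (none); model 1 = age + physical activity + SES;
model 2 = model 1 + waist circumference. Physical activity and SES enter
as unordered categorical covariates (indicator coding). SES is the sum
of three ordinal indicator scales (education, occupation, house
ownership; family size optional) cut at empirical tertiles into
low/middle/high.

Binary risk outcomes are fitted by binary logistic regression with
genotype dummies (CC reference) and Wald 95% CIs. The genotype-on-score
association uses a three-level multinomial logit with CC as reference,
reported as per-score-unit ORs. Quasi-separated fits are flagged, not
silently reported.

The gene × diet interaction is the partial F-test of the genotype ×
tertile block in `response ~ C(genotype) + C(tertile) +
C(genotype):C(tertile) + covariates` (OLS), run separately per sex, 4
numerator df when all nine cells are occupied. Adjusted cell means are
computed by standardisation: every subject's covariate row is combined
with the target cell's factor levels, predictions are averaged, and the
SE follows from the delta method on the averaged design row. With no
covariates this reduces exactly to the raw cell means, and the procedure
is invariant to affine recoding of continuous covariates. Post-hoc
contrasts compare adjusted means within genotype across tertiles by
t-tests on the residual df (LSD by default, Bonferroni by flag).
Responses are analysed untransformed by default; skewed responses such
as TG may optionally be log-transformed upstream. The significance
threshold is 0.05 throughout with no multiplicity correction by default,
matching common practice in this study type.

## Synthetic-cohort generator

The generator emulates the *marginal* structure the analysis assumes:

* Genotypes i.i.d. at the observed mix CC/CT/TT = 0.378/0.519/0.103
  (implying f(T) = 0.3625), or Hardy–Weinberg at a configurable MAF.
* Food-group intakes are independent log-normals with medians anchored
  to the emulated cohort's reported intake summaries (fruits 444, vegetables 320,
  cereals 523, nuts 11, legumes 49, red/processed meat 49, fish 6.4,
  dairy 260 g/day; sodium 3500 mg/day) and log-scales back-solved from
  the reported interquartile ranges; sex acts as a multiplicative factor
  (1.12 male / 0.86 female) on the medians. Whole grains and low-fat
  dairy are Beta-distributed shares of cereals and total dairy; the
  MUFA:SFA ratio is normal (1.21, 0.31) applied to a log-normal SFA.
* Reported energy is a linear function of the caloric components plus
  reporting noise. It was calibrated once so that draws stay inside the
  800–4200 kcal/day plausibility window ≥ 99% of the time with the mean
  at ~3040 kcal/day; this makes the simulated energy SD (~345) narrower
  than a real FFQ's (~1080) — the two cannot coexist, and the window
  property is what the eligibility stage needs to be testable. By
  default the end-to-end generator also clips energy into the window so
  the standard 347-subject cohort passes eligibility unfiltered.
* Biomarkers are Gaussian around the reported means/SDs (TC 188.4/33.7,
  TG 120.0/58.5, HDL 45.0/8.9, glucose 91.5/9.5, SBP 115.6/16.4, DBP
  76.3/12.3), floored at physiological minima; insulin is log-normal
  (median 13.1 µU/ml). Intakes and biomarkers are independent across
  components — no correlation structure, no confounding between diet
  and genotype (genotypes are randomized, as in nature).
* Effects are planted on top: per-response genotype main-effect shifts,
  genotype × tertile cell shifts (planted on the tertile scale, matching
  the analysis), and binary outcomes drawn from a logistic model on
  genotype. The default effect is a TT-vs-CC odds ratio of 3.58 on a
  high-TG outcome at 25% baseline prevalence.

Because the generator matches marginals but not the dependence structure
of real dietary data (energy–intake correlations, intake–biomarker
links, measurement error of the FFQ), passing calibration tests shows
that the *inference machinery* is correct and well-calibrated, not that
the pipeline would reach the same substantive conclusions on any
particular real cohort.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical config + seed reproduces the
cohort byte-for-byte.

## Calibration and recovery experiments

`genediet.calibration` runs four seeded Monte-Carlo studies used by the
acceptance checks (problem sizes chosen to keep each under ~30 s on one
CPU):

* **Null calibration** — 1000 cohorts of n = 350 with no effects: the
  interaction F-test's rejection rate at α = 0.05 (expected 0.05
  ± 0.02) and the coverage of crude-OR 95% CIs for 1 (~95%).
* **OR recovery** — a true TT-vs-CC OR of 3.5 planted at the observed
  genotype mix, n = 5000 per cohort. One replicate's Wald SE on the log
  OR is ≈ 0.10 (the TT group is only ~10% of the cohort), comparable to
  a ±10% recovery band, so recovery is assessed as estimator accuracy:
  the mean log OR over 30 replicates, reported on the OR scale.
* **Interaction power** — a 0.8-SD shift in one CT × tertile cell at
  n = 350. The exact power of the 4-df test follows from the noncentral
  F distribution with λ = n δ² p_g(1−p_g) q_t(1−q_t) = 12.4, giving
  0.812; the 500-rep simulation (Monte-Carlo SE ≈ 0.018) is checked for
  agreement with that exact value. The CT genotype hosts the planted
  cell because it is the largest stratum — the same single-cell shift in
  the TT stratum (10% of subjects) would be detectable with power of
  only ~0.36 at this sample size.

## Degenerate inputs and numerical conventions

Constant variables summarize with SD 0 and skewness defined as 0;
descriptive routing reports median (IQR) when |skewness| > 1, else mean
(SD). Empty genotype levels are dropped from the multinomial fit with a
warning; empty interaction cells flag the result and the partial F-test
proceeds on the remaining rank if estimable. Fragment calling uses
nearest-expected matching within ±10 bp (gel resolution); contradictory
band patterns are rejected rather than guessed. The Hardy–Weinberg test
is the standard exact test by enumeration of heterozygote counts
conditional on allele counts, computed in log space.

## Known limitations

FFQ item-level data, food-composition lookups and questionnaire
administration are out of scope — the pipeline starts from g/day
food-group intakes. The generator provides no population structure
beyond HWE, no intake correlations, and no missing-data mechanism (add
missingness explicitly to test complete-case behaviour). Cohort-specific
published table values (tertile-stratified cell statistics, specific
interaction p-values) depend on the original subject-level data and are
not reproducible from marginals; the package instead verifies the
arithmetic identities that are recomputable and the statistical
properties (calibration, coverage, power, recovery) of the methods.
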