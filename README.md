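# genediet

Gene–diet interaction analysis for nutritional epidemiology: a tested,
reusable implementation of the analytical chain used in cross-sectional
candidate-gene studies of obese cohorts — FFQ-derived diet-quality
scoring, derived cardiometabolic phenotypes, PCR-RFLP genotype calling,
and sex-stratified association and interaction inference — together with
a synthetic-cohort generator so the whole pipeline can be exercised and
calibrated without access to subject-level data.

The package is aimed at epidemiologists and biostatisticians who want a
scriptable, reproducible version of an analysis that is usually run by
hand in SPSS: given one subject-level table it computes everything from
the diet scores to the genotype × diet ANCOVA, and given no data at all
it can simulate a cohort with known planted effects and verify that the
inference machinery recovers them.

## What it computes

**Diet-quality indices.** The DASH score (Fung construction): eight
food-group/nutrient components scored by sex-specific quintile rank
within the study population — emphasized components (fruits, vegetables,
whole grains, low-fat dairy, nuts + legumes) score their rank 1–5,
discouraged components (sodium, red/processed meat, sweetened beverages)
are reverse-scored 6 − rank; total 8–40. The Mediterranean Diet Score
(Trichopoulou construction, alcohol-free): eight binary indicators at
sex-specific medians (1 at/above the median of the six protective
components, including the MUFA:SFA ratio; 1 below the median of the two
non-protective components); total 0–8.

**Phenotype panel.** LDL-C by Friedewald (TC − HDL − TG/5, valid for
TG < 400 mg/dl), atherogenic index of plasma log₁₀(TG/HDL),
HOMA-IR = glucose × insulin / 405, QUICKI = 1/(log₁₀ insulin +
log₁₀ glucose), averaged duplicate blood pressure, NCEP ATP III
metabolic-syndrome status (≥ 3 of 5 criteria), eight binary
cardiometabolic risk flags, DASS-21 mental-health subscales (doubled
seven-item sums, 0–42), and a VAS appetite summary.

**Genotyping.** FADS2 rs174583 C/T calls from TauI restriction-fragment
patterns (CC → 192 + 380 bp, TT → 572 bp, CT → all three; nearest-match
within a ±10 bp gel tolerance), cohort genotype/allele frequencies
(f(T) = p(TT) + p(CT)/2) and an exact Hardy–Weinberg test.

**Inference.** Sex-stratified ANOVA/χ² comparison tables across
score tertiles; binary logistic odds ratios of risk flags on genotype
(CC reference) and multinomial odds ratios of genotype on score totals,
each under three adjustment sets (crude; + age, physical activity, SES;
+ waist circumference); and the genotype × diet-tertile interaction
tested by the partial F-test in the ANCOVA
`response ~ genotype * tertile + covariates`, with covariate-standardised
adjusted cell means ± SE and LSD (or Bonferroni) post-hoc contrasts
within genotype.

## Worked example

```python
from genediet import SimulationConfig, simulate_cohort, fit_genotype_outcome_or
from genediet import score_dash, score_mds
from genediet.genotyping import genotype_frequencies

sim = simulate_cohort(SimulationConfig(n=5000, seed=1))
for r in fit_genotype_outcome_or(sim.cohort, "high_tg_sim", "crude"):
    print(f"{r.contrast}: OR {r.odds_ratio:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")
```

```
CT vs CC: OR 1.06 (95% CI 0.92-1.21)
TT vs CC: OR 3.31 (95% CI 2.72-4.04)
```

The generator's default effect plants a TT-vs-CC odds ratio of 3.58 on a
high-triglyceride outcome; the crude logistic model recovers it (3.31,
CI covering the truth) at n = 5000. On the default 347-subject cohort the
score marginals land on their configured anchors — DASH mean 24.0 (SD
3.8), MDS mean 4.01 (SD 1.43) — and `score_dash` / `score_mds` /
`genotype_frequencies` give the per-subject and cohort-level tables.

The same flow is available from a shell:

```bash
genediet run-all --seed 1 --out results_dir      # simulate + full analysis
genediet simulate --n 347 --seed 1 --out cohort.csv
genediet analyze cohort.csv --out results_dir    # analyse an existing table
```

`run-all` writes the analysis bundle as CSV/JSON: cohort descriptives,
intake summary, sex-stratified tertile comparison tables, diet–genotype
and genotype–risk odds-ratio tables, interaction tests with plot-ready
adjusted cell means, the exclusion log, allele statistics, and a run
manifest (config hash, seed, version).

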