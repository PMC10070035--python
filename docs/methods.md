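# Methods

This note records the models the package implements, the conventions and
defaults it chooses where the field leaves them open, and what the synthetic
data used by the tests does and does not establish.

## Phenotype generation

**Event substrate.** All phenotyping operates on a long table of coded
clinical events: participant, source (hospital, primary_care, self_report,
prescription), vocabulary (ICD10, ICD9, READ, CUSTOM), code, calendar date,
and an optional numeric value with unit for measurements. Dates are
date-granular ISO-8601; time of day is ignored because EHR exports are
date-granular. Validation is total: a malformed row either raises a named
error (missing column, empty file) or is counted in a rejection report
(unparseable date, unknown source or vocabulary, empty code, non-numeric
value). Events dated before the participant's birth are dropped with a
warning.

**Distinct-date counting.** Wherever a rule requires a minimum number of
events, events are counted by distinct calendar date: same-day duplicate
codes count once. This guards against administrative/billing duplicates and
is applied uniformly (code groups, composite predicates, post-onset event
counts).

**Code groups.** A code-group map assigns (vocabulary, pattern, match-mode)
rows to groups, phecode-style; prefix matching is how related ICD-9/ICD-10
codes collapse into one clinical entity. Case = at least `min_count` distinct
event dates in the group; control = not a case and not a case of any listed
exclusion group (the phecode control-exclusion convention); otherwise
missing.

**Composite phenotypes.** Case rules are finite boolean trees (ANY/ALL/NOT)
whose leaves assert "≥ k distinct-date events matching a code set, optionally
restricted to one source". NOT is disallowed at the root of a case rule (a
case definition must be positive evidence). Non-cases satisfying the optional
exclusion rule become missing rather than controls. A sex restriction sets
the opposite (and unknown) sex to missing.

**Quantitative traits.** Repeated measurements matching a code set (and
optional unit filter) are filtered to a plausible range if one is declared —
the package's mechanism for outlier control, since primary-care values
contain entry errors — then aggregated (mean, median, first, last, min, max;
first/last order by date with same-day ties averaged). Participants with
fewer than `min_measurements` surviving values are missing.

**Trajectories.** The per-participant OLS slope of value against age in
years, requiring ≥ 3 measurements on ≥ 2 distinct dates. Age uses 365.25-day
years throughout (standard epidemiological convention).

**Drug response.** Index date = first matching prescription. The response is
mean(post-window values) − mean(pre-window values) with defaults pre = 365
days half-open before the index date and post = [index+30, index+365]. A
measurement on the index date counts in neither window; the post window
starts at a lag ≥ 1 day so the acute prescription visit itself is excluded.
These windows are package defaults, declared and overridable, not claimed to
match any particular published pipeline.

**Progression.** Age of onset = age at the earliest case-qualifying event
(the events matching positive, non-negated predicates of the case rule, or
the group's code set for code-group phenotypes); post-onset event count =
distinct-date qualifying events on/after onset. Both are missing for
non-cases; a case with no dated qualifying event is missing with a warning.

**Collapsing correlated traits.** Pearson correlation on pairwise-complete
observations (pairs sharing < 30 non-missing values are treated as
uncorrelated — too little overlap to estimate r); an edge where |r| ≥ 0.9
(default, configurable); connected components; one representative kept per
component — curated if supplied, else the column with most non-missing
values, ties broken lexicographically. Pearson rather than Spearman because
the collapsing targets near-duplicate measures of the same quantity, where
linear correlation is the natural notion; 0.9 is a conservative default for
"extremely highly correlated".

**Sex strata.** Stratified copies set the opposite sex to missing; unknown
sex is missing in both strata to avoid silent misclassification.
Sex-restricted definitions emit only their permitted stratum.

**Orchestration.** `build_phenotype_matrix` runs code groups, composites,
quantitative traits, trajectories, drug response, progression, collapsing and
stratification in that fixed order, and emits a per-column generation log
(case/control/missing counts). The engine is deterministic and invariant to
input row order; duplicate phenotype ids are fatal.

## Genetic predictors

Additive uses the dosage in [0, 2] directly. Dominant (1{g≥1}), recessive
(1{g=2}) and genotypic (het, hom-alt indicators) require hard calls; imputed
fractional dosages are rejected unless the hard-call option is set, which
rounds to the nearest integer within 0.1 (a common practice threshold) and
sets the rest missing. Multiallelic CNV copy numbers (integers 0–8 by
default) are used directly under the linear additive coding or mapped through
user-specified collapsed categories; unmapped copies become missing with a
warning.

Risk scores are Σⱼ wⱼ·d′ᵢⱼ with dosages aligned to the effect allele: as-is
when the effect allele equals alt, flipped (2−d) when it equals ref, fatal
otherwise — no strand inference, because silent strand flips are a worse
failure mode than a loud error. Missing dosages follow a declared policy:
`mean_impute` (default; replaces with the cohort mean dosage, i.e. 2× the
alt-allele frequency, preserving n across the phenome) or `complete` (score
missing). The policy is reported per run, and is not claimed to match any
particular published pipeline.

## Association testing

All fits are complete-case: rows missing the response, predictor or any
covariate are dropped first and post-drop counts recorded. No covariate
imputation.

**Linear.** OLS by the normal equations; SEs from σ̂²(XᵀX)⁻¹ with the n−p
denominator; two-sided t p-values on n−p df. Rank-deficient designs are
flagged `collinear`, never silently dropped. An optional rank-based inverse
normal transform Φ⁻¹((r−3/8)/(n+1/4)) (Blom offset, average ranks for ties)
is available for derived quantitative traits with awkward distributions.

**Logistic.** Newton–Raphson with step-halving; converged iff the parameter
step falls below 1e-6 within 25 iterations AND max|β̂| ≤ 15. The cap is the
working definition of separation: a finite but runaway estimate signals a
likelihood without an interior maximum even when the iteration technically
stabilises. Wald p-values per predictor column.

**Firth.** Newton iterations on the modified score U*(β) with step-halving
on the penalized log-likelihood ℓ*(β) = ℓ(β) + ½ log det I(β); the leverages
hᵢ are recomputed from the weighted design at each iterate. Convergence when
the step falls below 1e-6 or the modified score falls below 1e-6 — the
optimality condition itself, which also terminates benign micro-oscillations
at floating precision. Wald inference on the penalized estimates; a
penalized-LRT p-value is available as an option. The 2×2 correspondence with
half-count correction and a dense grid search over ℓ* serve as independent
oracles in the tests.

**Fallback.** Try logistic; on non-convergence (including the cap) refit
with Firth and report method `firth` with the trigger reason logged. The
trigger is this package's behavioural contract — non-convergence OR runaway
estimate — chosen for robustness; equivalence to any external
implementation's internal trigger is not claimed.

**Genotypic 2-df test.** Likelihood ratio of the full model (het + hom
indicators + covariates) against the covariates-only model, referred to
χ²₂; both nested fits use the same engine, penalized on both sides when the
fallback triggers, so the likelihoods are comparable. If an indicator is
constant after the complete-case drop the test degrades to a flagged 1-df
test on the remaining column. The tabulated row reports the first (het)
column's Wald estimate alongside the 2-df p.

**Run orchestration.** Combinations are filtered before fitting: binary
phenotypes need ≥ 50 cases and ≥ 50 controls (conventional PheWAS floors,
configurable), quantitative ones ≥ 100 complete observations; every skip is
logged with its reason, so the skip log and the results partition the
planned grid. The sex covariate is removed automatically inside sex strata
and for sex-restricted phenotypes (it would be constant or near-constant
there). Output ordering is deterministic.

**FDR.** Benjamini–Hochberg step-up q-values over all converged tests of the
run jointly (one FDR per PheWAS, the per-variant convention); a per-stratum
option exists. Non-converged fits carry no p-value and are excluded from m.
Empirical sizes in the simulation harness count p ≤ α so that the α = 1
boundary rejects everything.

## Synthetic cohorts

The generator emulates the structure that the pipeline consumes: sex and
birth dates (uniform 1940–1970), Poisson-count coded events with dates
uniform between age 30 and a 2020 censoring date, fixed-visit Gaussian
measurements, Hardy–Weinberg hard-call dosages at stated minor-allele
frequencies, categorical CNV copies on 0–8, and injected effects —
quantitative (value shifted by β per model-coded dosage unit) or binary
(event presence follows a logistic model in the dosage). One global seed is
expanded into fixed labelled substreams per component so stages reproduce
when rerun independently; the same seed yields byte-identical outputs.

Deliberately absent: linkage disequilibrium, relatedness, population
structure, realistic code frequency tables, informative missingness and
measurement-error structure. The tests therefore establish correctness of
the estimators and plumbing under clean, independent sampling — parameter
recovery, calibration, determinism — not robustness to the confounding
present in real biobank data.

## Simulation sizes and numerical conventions

The type-I harness uses n = 5000, 2% cases, maf 0.05, 1000 replicates — the
imbalanced rare-variant regime the fallback exists for; at these settings
each replicate carries ~100 cases. Null-calibration checks of the 2-df test
run at 300 replicates with the corresponding 99% binomial band; coverage
checks of the null-effect injector use 200 replicates. Empirical rates at
these sizes carry binomial noise of a few parts per thousand, and the test
bands account for it. Problem sizes were chosen so the whole suite runs on a
single CPU in a few minutes while leaving the estimands identifiable.

Degenerate inputs fail loudly and specifically: one-class responses,
collinear designs, all-tied transforms, empty result sets, allele
mismatches, unknown code-set references. Missing values are NaN in memory
and `NA` on disk (empty strings accepted on input); reals round-trip through
TSV at 10 significant digits.

## Known limitations

Wald p-values are conservative in small-event-count regimes (the
Hauck–Donner effect), so empirical sizes at α = 0.05 can sit slightly below
nominal even when calibration is otherwise sound; the penalized-LRT option
trades this for slightly anti-conservative behaviour at the same sizes. The
phenotype engine performs no unit harmonisation beyond the declared unit
filter and no terminology mapping between vocabularies; a code set must list
each vocabulary it intends to match. GRS weights are taken as given — no
training, clumping or thresholding. X-chromosome dosage conventions are not
implemented.
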