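# phewaskit

Phenome-wide association studies (PheWAS) from linked electronic-health-record
data: deep phenotype generation and association testing with Firth-fallback
logistic regression.

A PheWAS turns the usual genetic-association question around: instead of many
variants against one trait, it tests one genetic predictor — a variant, a
multiallelic copy-number variant, or a genetic risk score (GRS) — against the
whole phenome. Doing that well requires two things that `phewaskit` provides
as a single library:

1. **A phenotype engine** that converts long-format coded clinical events
   (hospital ICD-9/ICD-10, primary-care codes, self-report, prescriptions,
   timestamped measurements) into an analysis-ready participants × phenotypes
   matrix. It supports phecode-style code groups with control exclusions,
   composite case/control definitions combining data sources through boolean
   logic, quantitative traits aggregated from repeated primary-care
   measurements, longitudinal trajectory slopes, drug-response deltas,
   disease-progression phenotypes (age of onset, post-onset event counts),
   collapsing of extremely highly correlated traits, and sex-specific strata.
2. **An association engine** with minimum-count filters, OLS for quantitative
   traits (optionally after a rank-based inverse normal transform), logistic
   regression with Firth fallback for binary traits, a 2-df genotypic
   likelihood-ratio test, additive/dominant/recessive/genotypic encodings,
   linear or collapsed CNV codings (copy numbers 0–8), weighted risk scores
   with effect-allele alignment, and Benjamini–Hochberg FDR across the run.

Because individual-level biobank data are access-restricted, the package also
ships a seeded synthetic-cohort generator (`phewaskit.synth`) that emulates
the relevant structure — coded events per person per source, repeated
measures, Hardy–Weinberg dosages, integer CNV copy numbers, and *known
injected* genotype–phenotype effects — so every stage is testable offline and
estimator recovery can be verified against ground truth.

## The statistical core

For a binary phenotype with linear predictor η = Xβ, ordinary logistic
regression maximizes the log-likelihood ℓ(β) = Σᵢ yᵢηᵢ − log(1+exp(ηᵢ)).
When a low-frequency predictor meets a strong case–control imbalance the data
may be (quasi-)separated: the MLE runs to infinity, Newton iterations fail,
and Wald inference breaks down. `phewaskit` fits standard logistic regression
first and, when the fit fails to converge or the estimate exceeds a cap
(|β̂| > 15, the working signature of separation), falls back to Firth
penalized logistic regression, which maximizes

    ℓ*(β) = ℓ(β) + ½ log det I(β)

(the Jeffreys-prior penalty, with I(β) = XᵀWX the Fisher information) via the
modified score

    U*(β) = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢ ,

where hᵢ is the leverage of the weighted design. Firth estimates are finite
under any separation and carry reduced small-sample bias; on a saturated 2×2
table the penalized estimate equals the half-count-corrected log odds ratio
log((a+½)(d+½)/((b+½)(c+½))), which the test suite uses as a closed-form
oracle. Multiple testing is controlled with the Benjamini–Hochberg step-up
q-value, q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j, over all converged tests in a run.

## Worked example

`examples/03_firth_fallback.py` — separation and the fallback:

```
plain logistic: converged=False (max iterations reached)
firth fallback: method=firth, beta=3.2189, se=2.6833
closed form for this table: log((2.5*2.5)/(0.5*0.5)) = 3.2189

type-I error at alpha=0.05 over 200 null replicates (n=5000, 2% cases, maf 0.05):
  standard Wald logistic: 0.045
  firth fallback:         0.045
```

The exposed-cases-only 2×2 table has no finite MLE, so the plain fit is
flagged and the engine returns the finite penalized estimate, which matches
the closed form. Under a null with 2% cases and minor-allele frequency 0.05,
the empirical rejection rate at α = 0.05 stays near nominal.

`examples/04_grs_phewas.py` — risk-score PheWAS with an injected effect of
0.5 per score unit on one trait among 20 nulls (n = 2000):

```
injected effect 0.5 estimated as 0.514 (se 0.030); q-value 1.26e-58
1 of 21 tests significant at FDR 1% (expected: just the injected trait)
```

The other examples cover cohort simulation (`01`) and the phenotype engine on
a six-person event table (`02`). A thin CLI mirrors the pipeline stages for
shell use:

```bash
phewaskit simulate   --spec spec.yaml --out cohort/ --seed 17
phewaskit phenotypes --events cohort/events.tsv --participants cohort/participants.tsv \
                     --definitions defs.yaml --code-map map.tsv --out pheno.tsv
phewaskit grs        --weights grs_weights.tsv --dosages cohort/dosages.tsv --out scores.tsv
phewaskit phewas     --pheno pheno.tsv --dosages cohort/dosages.tsv --grs scores.tsv \
                     --out results.tsv --plot manhattan.png
```

The pipeline is deterministic: the same seed yields byte-identical outputs.

## Layout

```
src/phewaskit/   core.py (types + I/O)   synth.py (synthetic cohorts)
                 phenotypes.py (phenotype engine)   encoding.py (genetic predictors)
                 association.py (regression engines)   runner.py (PheWAS orchestration)
                 cli.py (thin command-line layer)
examples/        one narrative script per capability
docs/methods.md  models, conventions, defaults and their rationale
tests/           pytest suite with oracle-based end-to-end checks
```

Scope notes: the package ships the phenotype-definition *schema* plus a small
illustrative library, not a curated biobank phenotype catalogue; there is no
mixed-model/relatedness correction, no BGEN/PLINK-binary parsing, and no
strand inference for risk-score allele alignment (mismatches fail loudly).
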