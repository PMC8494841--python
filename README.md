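# cogpgs

Polygenic scores, longitudinal cognitive trajectories, and amyloid
mediation — a tested, reusable implementation of the analysis chain linking
common genetic variation to the rate of cognitive decline in early
Alzheimer's disease.

The package is for researchers who have (or want to emulate) three inputs —
genotypes, external GWAS summary statistics, and longitudinal cognitive
testing with CSF amyloid biomarkers — and who want to ask: *how much of the
polygenic effect on cognitive decline runs through amyloid pathology, and
which variants carry it?*

## What it computes

**Polygenic scores.** After variant/sample QC (call rate > 99%, MAF ≥ 5%,
HWE p > 5 × 10⁻⁸, person missingness ≤ 1%, ±3 SD heterozygosity) and greedy
LD clumping (r² < 0.1 within 1000 kb), scores are built at seven GWAS
p-value thresholds (0.05 down to 5 × 10⁻⁸) with the PLINK formula

```
PRS_j = Σ_i S_i · G_ij / (P · M_j)
```

where S_i = ln OR_i from the discovery GWAS, G_ij the effect-allele dosage,
P the ploidy, and missing genotypes replaced by the population allele
frequency × P. The APOE region (chr19:44.4–46.5 Mb, GRCh37) is excluded and
the ε-defining variants rs7412/rs429358 reintroduced; ε2/ε4 counts also
enter the regressions as covariates.

**Trajectories.** A maximum-likelihood linear mixed model
`score ~ 1 + time` with correlated random intercept and slope per subject;
the per-subject conditional modes (BLUPs) are extracted, rank-based
inverse-normal transformed (Blom offset 3/8), and regressed on each
standardized score with adjustment for age, gender, education, baseline
score (slope models only), APOE ε2/ε4 counts and the top 10 genotype PCs,
with Bonferroni control over the seven-threshold family.

**Mediation.** Difference-method mediation through binary amyloid status
(Aβ+ iff CSF Aβ42/Aβ40 < 0.09): total effect c, direct effect c′, indirect
effect c − c′ and proportion mediated (c − c′)/c, with percentile CIs from
1000 subject-level bootstrap resamples.

**Decomposition.** A leave-one-out heuristic that splits a score's variant
set into amyloid-dependent and amyloid-independent subsets: rebuild the
score n times leaving one variant out, rank variants by the p-value of the
score→amyloid association, scan nested top-k scores in both rank orders,
and select the largest k that still behaves as fully independent (no
mediation, association survives amyloid adjustment) or fully dependent
(association lost under adjustment), with a refinement pass tagging
partially dependent variants.

**Synthetic cohorts.** Because cohort-scale clinical genetics data cannot
ship with a package, `cogpgs.simulate` generates a full study with recorded
ground truth — HWE genotypes in LD blocks, a GWAS panel spanning all seven
thresholds, amyloid status logistic in a mediated variant burden, and
bounded integer MMSE-like trajectories — so every stage has a recovery
test against planted truth.

## Worked example

```python
import pandas as pd
from cogpgs import (SimulationConfig, simulate_study, fit_trajectories,
                    int_transform, score, standardize_scores, mediate)

study = simulate_study(SimulationConfig(seed=1, include_apoe=False))
effects = fit_trajectories(study.longitudinal, outcome="score")
slope = pd.Series(int_transform(effects.effects["slope"]),
                  index=effects.effects.index)
causal = study.truth.variants.query("`class` in ['direct','mediated']")["id"]
records = study.summary_stats[study.summary_stats["id"].isin(causal)]
prs = standardize_scores(score(study.genotypes, records.reset_index(drop=True)))
print(mediate(prs, study.covariates["ab_status"], slope,
              study.covariates[["age", "gender", "education_years"]].astype(float),
              n_boot=1000, seed=1).summary())
```

prints

```
             Aβ status
      a=+0.604 /      \ b=-0.407
            /        \
  score ----------------> slope
      c  = -0.2535 (p=9.19e-09)   total
      c' = -0.1979 (p=9.61e-06)   direct
      c-c' = -0.0555 [95% CI -0.0899, -0.0283]   mediated (21.9% mediation)
      n=500, bootstraps=1000, seed=1
```

Read: one SD of polygenic burden predicts 0.25 SD steeper (transformed)
decline in total; adjusting for amyloid status leaves −0.20 direct, so
21.9% of the effect is mediated by amyloid — against a recorded generator
truth of 21.0% for this seed. The `examples/` directory walks through each
capability (simulation, scoring, trajectories, mediation, decomposition,
full pipeline) the same way.

There is also a thin CLI: `cogpgs simulate | qc | score | fit | run-all |
init-config` (results to files, logs to stderr; `cogpgs run-all --seed 11`
reproduces a full bundle byte-for-byte).

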