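# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite shows.

## The analysis chain

The pipeline is a two-stage (extract-then-regress) design, chosen for
fidelity to common practice in longitudinal cognitive genetics rather than
statistical efficiency: a joint longitudinal model would share information
across stages but would not correspond to the procedure being reproduced.

1. **Quality control.** Samples first (missingness > 1%, heterozygosity
   beyond ±3 SD of the cohort mean rate), then variants (autosomal,
   biallelic, call rate > 99%, MAF ≥ 5%, HWE p > 5 × 10⁻⁸). Each variant
   rule is evaluated on the same input matrix, so variant filters commute;
   the sample-then-variant order is the only ordering choice. The HWE test
   is the 1-df chi-square against expectations at the observed allele
   frequency — deterministic and adequate at MAF ≥ 5%; an exact test would
   matter only for rare variants, which the MAF filter removes. The ±3 SD
   heterozygosity rule operationalises "extreme heterozygosity", for which
   no published cutoff exists; with fewer than 3 samples the SD is
   undefined and the filter is skipped with a warning, and an SD of zero
   means no outliers.

2. **Scores.** Greedy clumping takes the best remaining variant by
   discovery p-value and removes same-chromosome neighbours within
   ±1000 kb at r² ≥ 0.1, with r² the squared Pearson correlation of
   dosages over pairwise-complete samples and p-ties broken by
   (chromosome, position, id). Thresholding yields nested subsets at
   0.05, 5e-3, …, 5e-8. Scoring follows PRS_j = Σ S_i G_ij / (P·M_j).
   Two readings of the missing-genotype rule conflict: the denominator
   M_j counts non-missing variants, yet a missing G_ij is replaced by a
   population-frequency term, which implicitly treats the variant as
   observed. The default resolves this as mean imputation (substituted
   variants count; denominator P·N); `strict_denominator=True` implements
   the literal M_j. The substitution value is the cohort frequency of the
   *aligned effect allele* × ploidy — identical to the conventional
   "MAF × P" statement whenever the effect allele is the minor allele
   (the standard GWAS coding), and the only choice that keeps scores
   exactly invariant under re-listing a variant on its other allele.
   Allele alignment accepts exact or swapped matches only; strand
   resolution of A/T-C/G variants is out of scope for synthetic data.

3. **Trajectories.** `score ~ 1 + time` with correlated random intercept
   and slope, fitted by maximum likelihood (statsmodels MixedLM; lbfgs
   with cg and powell restarts; non-convergence is flagged on the result,
   never silently returned). Conditional modes (BLUPs) per subject are the
   analysis outcome. Noise-free data (every subject exactly on a line) sit
   on the boundary of the parameter space where iterative fitting is
   fragile; that case is detected (max per-subject least-squares residual
   < 1e-8 of the outcome scale) and solved in closed form — the ML limit
   with zero residual variance, where conditional modes equal each
   subject's own line.

4. **Association.** The extracted intercepts/slopes are inverse-normal
   transformed — rank r of n maps to Φ⁻¹((r − 3/8)/(n + 1/4)), the Blom
   offset, with average ranks for ties — then regressed by OLS on the
   standardized score plus covariates (age, gender, education, APOE ε2/ε4
   counts, top-10 genotype PCs; baseline test score for slope models
   only, since for intercept models it is essentially the outcome).
   Bonferroni correction uses family size m = 7 (the threshold series per
   outcome panel); m is a parameter because the original family
   definition is ambiguous, and the chosen m is recorded in every output.
   Rank-deficient designs raise an error naming the collinear columns.

5. **Mediation.** Difference method: c from OLS of the transformed slope
   on score + covariates, c′ and b adding the binary amyloid status, the
   score→amyloid path a from a logistic model (reported, not used in the
   point estimate), indirect = c − c′, proportion mediated = (c − c′)/c.
   Percentile bootstrap (default 1000 resamples) resamples whole subjects;
   identical seeds give bit-identical CIs. The difference method is used
   because the mediated effect is defined as "c − c′" in the procedure
   being reproduced; in the linear-outcome case it coincides with the
   product-of-coefficients path estimate. When |c| < 1e-8 the proportion
   is undefined and its CI suppressed. The proportion's bootstrap CI is
   reported only when at least half the resamples have a non-degenerate
   total effect.

6. **Decomposition.** The leave-one-out scan rebuilds the score without
   each variant (weights fixed, denominator using n − 1) and records the
   logistic score→amyloid p-value; removal of an amyloid-independent
   variant *sharpens* the association (these variants dilute it), removal
   of a dependent variant *weakens* it. Nested top-k scores in ascending
   (independent side) and descending (dependent side) leave-one-out-p
   order are then tested against the slope, unadjusted and
   amyloid-adjusted, plus a bootstrap mediation flag per k. Selection
   returns the **largest** qualifying k — maximality mirrors the "more
   extensive models did not meet the conditions" stopping logic — with
   non-contiguous qualification warned about, never silently resolved.
   "Significant mediation" inside the scan means the 95% bootstrap CI of
   the indirect effect excludes zero; the scan uses 200 bootstrap
   resamples per k by default (configurable) against 1000 for the
   headline mediation — a cost/stability compromise for an O(n·k) loop.
   Refinement re-tests the selected dependent set without each member;
   members whose removal restores the adjusted association are labelled
   "partial". Final classes: selected ascending top-k_I independent,
   selected descending top-k_D dependent/partial (dependent wins on
   overlap), and any variant outside both selections keeps its
   leave-one-out candidate label so the classes always partition the set.
   Ties in leave-one-out p are broken by (|β|, id) and logged.

## The synthetic study conditions

The generator emulates a single-site longitudinal memory cohort:

| parameter | default | rationale |
|---|---|---|
| subjects | 500 | mid-size deeply phenotyped cohort |
| variants | 200 in LD blocks of 10 | enough for a 7-level threshold series |
| latent LD (AR-1) | 0.6 | moderate block LD; genotype r is attenuated below the latent value by the threshold model, strongly so for unequal MAFs |
| MAF | U(0.05, 0.5) | post-QC spectrum |
| causal variants | 20 direct + 10 mediated | mixed architecture for the decomposition |
| causal \|ln OR\| | U(0.15, 0.35) | common-variant effect sizes |
| amyloid model | logit p(Aβ+) = −0.25 + 1.0·(mediated burden) | ~42–44% Aβ+ prevalence |
| slope model | −0.20 − 0.12·D − 0.25·Aβ + N(0, 0.3²) MMSE/yr | see calibration below |
| intercept | N(28.5, 1.2²) | MMSE near ceiling |
| visits | 0/2/4/6 y, monotone dropout 0.15 after visit 3 | ≥3 visits guaranteed; realized mean follow-up ≈ 5.7 y |
| residual SD | 1.0 MMSE | test–retest noise |
| outcome | rounded, clipped to [0, 30] | MMSE-like; a continuous copy is kept for clean recovery tests |

Genotypes come from a latent multivariate-Gaussian threshold model applied
independently to two haplotypes per subject, which guarantees HWE per
variant and makes the LD target the *latent* AR(1) correlation. The two
APOE ε variants are drawn as joint ε2/ε3/ε4 haplotypes (0.08/0.77/0.15) so
ε2+ε4 ≤ 2 always holds, carry large GWAS weights, and act through the
amyloid (mediated) pathway — consistent with amyloid-mediated APOE effects
on decline.

**Effect-size calibration.** The study condition the mediation stage must
recover is a true mediated proportion near 0.20. With the defaults above,
the recorded truth — computed per dataset by regressing the noise-free
slope component on the standardized causal-variant score with and without
amyloid — averages 0.199 (no-APOE configuration, 12 seeds). These values
were calibrated once against the recorded truth and then frozen. Magnitudes
are chosen for clear detectability at n = 500, not to match any particular
cohort's effect sizes.

**What the generator does not emulate.** Population structure (beyond an
optional two-cluster construction in tests), genotyping batch effects,
imputation uncertainty, informative dropout, practice effects, and floor
effects in severely impaired subjects. Passing recovery tests therefore
show the estimators are consistent under the stated generative model, not
that real-cohort estimates are unbiased — in particular, BLUP shrinkage
and the ratio form of the mediated proportion add a small (+0.03 at the
default conditions) upward finite-sample drift to the mediated-proportion
estimate that is well inside the tolerance used in its recovery test.

## Numerical choices and degenerate inputs

- One global seed; every stochastic stage draws a deterministic child seed
  (numpy `SeedSequence.spawn`), so whole pipeline runs are byte-identical
  for a fixed config, and all tabular output uses a fixed `%.10g` float
  format (`%.17g` for summary statistics, whose odds ratios near 1 need
  full precision to round-trip).
- PCA standardizes dosage columns by 2p̂ and √(2p̂(1−p̂)), mean-imputes
  missing calls (only inside PCA — never in QC statistics), fixes
  component signs by the largest-magnitude loading, and returns all-zero
  scores for a zero-rank (all-identical) matrix; k above the rank raises.
- Quasi-complete separation in logistic fits is flagged (|β| > 15 or
  SE > 100, or an optimizer failure) and the p-value set to missing
  rather than trusted.
- Monomorphic variants: HWE p = 1 by convention (flagged); zero-variance
  scores refuse standardization; zero-variance reduced scores in the
  leave-one-out scan are flagged rows, not errors.
- The amyloid cutoff is strict (ratio < 0.09 positive; 0.09 exactly is
  negative); non-positive or missing ratios yield missing status and the
  subject is dropped from amyloid analyses with a warning.
- The person call-rate "1% cut-off" is read as missingness > 1% excludes
  the sample; the complementary reading (call rate < 99%) is numerically
  identical.

## Known limitations

- LD reference is the cohort itself; external reference panels are not
  supported.
- Hard-call dosages only ({0,1,2, missing}); imputed fractional dosages
  are out of scope.
- The decomposition is a heuristic: selection thresholds sit at α = 0.05
  uncorrected inside the scan (the scan's own p-values are exploratory),
  and classification quality depends on the amyloid-path strength of the
  mediated variants; at the default conditions the dependent class is
  recovered with sensitivity ≈ 0.86 and precision ≈ 0.62 (pooled over 50
  simulated panels), as measured by the acceptance suite.
- Composite cognitive endpoints are not computed; the pipeline accepts any
  numeric outcome column.
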