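"""Build the seven-threshold polygenic score series.

Clumps the summary statistics against cohort LD (r^2 < 0.1 within 1000 kb),
handles the APOE region (excluded, with rs7412/rs429358 reintroduced), and
scores every sample at each of the seven GWAS p-value cutoffs.
"""

from cogpgs import (
    SimulationConfig,
    clump,
    exclude_apoe_region,
    score_threshold_series,
    simulate_study,
)

study = simulate_study(SimulationConfig(seed=1))

records = exclude_apoe_region(study.summary_stats, study.genotypes)
clumped = clump(records, study.genotypes)
print(f"{len(study.summary_stats)} summary records -> {len(clumped)} after "
      "APOE handling and LD clumping")

scores = score_threshold_series(study.genotypes, clumped)
for k, ss in scores.items():
    print(f"PRS{k} (p <= {ss.p_cutoff:g}): {ss.n_variants} variants, "
          f"first subject z-score {ss.scores.iloc[0]:+.3f}")

# Each line is one nested score: deeper thresholds keep only the most
# significant GWAS variants.  Scores are standardized (mean 0, SD 1) so the
# regression coefficients downstream are per-SD effects.
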