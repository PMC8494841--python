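"""Generate a synthetic memory-clinic cohort with recorded ground truth.

Builds genotypes in LD blocks, a GWAS summary-statistic panel spanning all
seven p-value thresholds, amyloid status driven by a mediated variant
burden, and MMSE-like longitudinal trajectories.
"""

from cogpgs import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1))

geno = study.genotypes
truth = study.truth
print(f"genotypes: {geno.n_samples} subjects x {geno.n_variants} variants")
print(f"variant classes: {truth.variants['class'].value_counts().to_dict()}")
print(f"amyloid-positive fraction: "
      f"{study.covariates['ab_status'].eq('positive').mean():.3f}")
print(f"mean follow-up: {truth.mean_follow_up_years:.2f} years")
print(f"true proportion of the genetic slope effect mediated by amyloid: "
      f"{truth.true_proportion_mediated:.3f}")
print(f"observations truncated at the MMSE bounds: {truth.truncation_count}")

# The variant classes say how each variant was wired into the phenotype:
# "direct" variants steepen decline regardless of amyloid, "mediated"
# variants act only by raising the probability of amyloid positivity, and
# "null" variants do nothing.  The recorded mediated proportion is what the
# mediation stage should recover.
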