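"""Synthetic cohort generator with recorded ground truth.

Emulates the data a longitudinal memory-clinic genetics study works with:

* genotypes in Hardy–Weinberg equilibrium, MAF >= 5%, arranged in LD blocks
  (latent multivariate-Gaussian threshold model per haplotype; the
  configured correlation is the latent AR(1) parameter, so realised
  genotype correlations are slightly attenuated);
* GWAS summary statistics whose planted causal variants span all seven
  p-value threshold levels;
* binary amyloid status whose probability follows a logistic function of
  the burden of *mediated* variants, plus a CSF Aβ42/Aβ40 ratio consistent
  with the 0.09 cutoff;
* MMSE-like longitudinal trajectories where the per-subject slope carries a
  direct genetic effect and an amyloid-mediated effect, bounded to [0, 30]
  and rounded to integers (a continuous untruncated copy is kept for clean
  recovery tests).

Every quantity the downstream stages estimate — per-subject intercepts and
slopes, per-variant class labels, the proportion of the genetic effect
mediated by amyloid — is recorded in a :class:`TruthRecord`.  One global
seed drives everything; each stochastic stage receives a deterministic
child seed, so identical configs reproduce bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .genotypes import GenotypeMatrix
from .scoring import SUMMARY_COLUMNS, THRESHOLDS


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Effect-size defaults are calibrated so that roughly 20% of the total
    genetic effect on the cognitive slope runs through amyloid status, the
    mediated proportion the pipeline is meant to recover, while keeping the
    total effect clearly detectable at the default sample size.
    """

    n_subjects: int = 500
    n_variants: int = 200
    ld_block_size: int = 10
    ld_rho: float = 0.6                 # latent AR(1) adjacent correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotype_missing_rate: float = 0.002
    # variant classes and effects
    n_direct: int = 20
    n_mediated: int = 10
    direct_effect: float = 0.12         # MMSE/year per SD of direct burden
    mediated_effect: float = 0.25       # MMSE/year attributable to Aβ+
    causal_weight_range: tuple[float, float] = (0.15, 0.35)  # |ln OR|
    swap_allele_fraction: float = 0.1   # summary rows listed on other allele
    # amyloid model
    ab_intercept: float = -0.25         # logit of Aβ+ prevalence at mean burden
    ab_slope: float = 1.0               # log-odds per SD of mediated burden
    ab_intercept_effect: float = 0.0    # MMSE lost at baseline if Aβ+
    # longitudinal design
    visit_schedule: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)
    dropout: float = 0.15               # per-visit hazard after the 3rd visit
    base_intercept: float = 28.5
    base_slope: float = -0.20           # MMSE/year population mean decline
    intercept_sd: float = 1.2
    slope_sd: float = 0.30
    residual_sd: float = 1.0
    include_apoe: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"MAF range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_subjects < 1 or self.n_variants < 1:
            raise ValueError("dimensions must be positive")
        if len(self.visit_schedule) < 3:
            raise ValueError("visit schedule needs at least 3 time points")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("intercept_sd", "slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 < self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in (-1, 1)")
        if self.n_direct + self.n_mediated > self.n_variants:
            raise ValueError("more causal variants than variants")
        if not 0.0 <= self.genotype_missing_rate < 1.0:
            raise ValueError("genotype_missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated cohort."""

    subjects: pd.DataFrame = field(repr=False)   # true intercept/slope, burdens, Aβ
    variants: pd.DataFrame = field(repr=False)   # id, class, weight
    true_proportion_mediated: float
    mean_follow_up_years: float
    truncation_count: int
    seed: int

    def __post_init__(self) -> None:
        pm = self.true_proportion_mediated
        if np.isfinite(pm) and not (0.0 <= pm <= 1.0):
            raise ValueError(f"mediation proportion {pm} outside [0, 1]")
        cls = self.variants["class"]
        if not cls.isin(["direct", "mediated", "null", "apoe"]).all():
            raise ValueError("every variant needs exactly one class label")

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "true_proportion_mediated": self.true_proportion_mediated,
            "mean_follow_up_years": self.mean_follow_up_years,
            "truncation_count": self.truncation_count,
            "subjects": self.subjects.reset_index().to_dict(orient="list"),
            "variants": self.variants.to_dict(orient="list"),
        }


_APOE_META = pd.DataFrame(
    {
        "id": ["rs429358", "rs7412"],
        "chrom": ["19", "19"],
        "pos": [45411941, 45412079],
        "a1": ["C", "T"],   # effect alleles: ε4-defining C, ε2-defining T
        "a2": ["T", "C"],
        "maf": [0.15, 0.08],
    }
)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def _children(config: SimulationConfig, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _variant_panel(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant metadata (ids, loci, alleles, MAF).

    Blocks of ``ld_block_size`` adjacent variants share a chromosome and sit
    20 kb apart; successive blocks are 3 Mb apart (outside any clumping
    window), cycling through the 22 autosomes.  The two APOE ε variants are
    appended, inside the APOE region on chromosome 19.
    """
    rng = _children(config)[0]
    n = config.n_variants
    block = config.ld_block_size
    ids, chroms, pos = [], [], []
    for i in range(n):
        b, within = divmod(i, block)
        chrom = (b % 22) + 1
        stack = b // 22
        ids.append(f"var{i + 1:05d}")
        chroms.append(str(chrom))
        pos.append(1_000_000 + stack * 3_000_000 + within * 20_000)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)]
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    panel = pd.DataFrame(
        {
            "id": ids,
            "chrom": chroms,
            "pos": pos,
            "a1": [p[1] for p in pairs],
            "a2": [p[0] for p in pairs],
            "maf": maf,
        }
    )
    if config.include_apoe:
        panel = pd.concat([panel, _APOE_META], ignore_index=True)
    return panel


def _variant_effects(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic class labels, scoring weights and discovery p-values.

    Causal variants cycle through the seven threshold bins so every score
    level is non-empty (guaranteed whenever there are >= 7 causal
    variants); null variants get uniform p-values and near-zero weights.
    """
    rng = _children(config)[1]
    panel = _variant_panel(config)
    n = config.n_variants
    classes = np.array(["null"] * n, dtype=object)
    causal_idx = rng.choice(n, size=config.n_direct + config.n_mediated, replace=False)
    classes[causal_idx[: config.n_direct]] = "direct"
    classes[causal_idx[config.n_direct:]] = "mediated"

    lo_w, hi_w = config.causal_weight_range
    weights = rng.normal(0.0, 0.02, size=n)
    weights[causal_idx] = rng.uniform(lo_w, hi_w, size=len(causal_idx))

    pvals = rng.uniform(0.0, 1.0, size=n)
    # cycle causal variants through bins (t_{k+1}, t_k] plus a sub-genome-wide bin
    bin_edges = list(THRESHOLDS) + [5e-10]
    order = rng.permutation(causal_idx)
    for j, i in enumerate(order):
        k = j % 7
        hi_p, lo_p = bin_edges[k], bin_edges[k + 1]
        u = rng.uniform(np.log(lo_p * 2), np.log(hi_p))
        pvals[i] = np.exp(u)

    eff = panel.copy()
    if config.include_apoe:
        classes = np.append(classes, ["apoe", "apoe"])
        weights = np.append(weights, [1.2, -0.45])
        pvals = np.append(pvals, [1e-50, 1e-10])
    eff["class"] = classes
    eff["weight"] = weights
    eff["p"] = pvals
    return eff


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes with block LD via a latent Gaussian threshold model.

    Two haplotypes per subject are drawn independently; within a block the
    latent Gaussians follow an AR(1) with parameter ``ld_rho`` and an
    allele is carried when the latent value falls below Φ⁻¹(MAF).  Blocks
    are independent.  Missing calls are planted completely at random at
    ``genotype_missing_rate``.
    """
    rng = _children(config)[2]
    panel = _variant_panel(config)
    n_sub, n_var = config.n_subjects, config.n_variants
    maf = panel["maf"].to_numpy()

    dosage = np.zeros((n_sub, len(panel)))
    block = config.ld_block_size
    rho = config.ld_rho
    for start in range(0, n_var, block):
        stop = min(start + block, n_var)
        size = stop - start
        lag = np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
        cov = rho ** lag
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(size))
        thr = ndtri(maf[start:stop])
        for _hap in range(2):
            Z = (L @ rng.standard_normal((size, n_sub))).T
            dosage[:, start:stop] += (Z < thr).astype(float)
    if len(panel) > n_var:
        # APOE ε haplotypes drawn jointly (ε2/ε3/ε4 ~ 0.08/0.77/0.15) so the
        # two defining variants never imply more than two ε2+ε4 alleles
        hap = rng.choice(3, size=(n_sub, 2), p=[0.08, 0.77, 0.15])
        e2 = (hap == 0).sum(axis=1).astype(float)   # rs7412-T dosage
        e4 = (hap == 2).sum(axis=1).astype(float)   # rs429358-C dosage
        for j in range(n_var, len(panel)):
            dosage[:, j] = e4 if panel.iloc[j]["id"] == "rs429358" else e2
    if config.genotype_missing_rate > 0:
        mask = rng.random(dosage.shape) < config.genotype_missing_rate
        dosage[mask] = np.nan
    samples = [f"S{i + 1:04d}" for i in range(n_sub)]
    return GenotypeMatrix(dosage, samples, panel[["id", "chrom", "pos", "a1", "a2"]])


def simulate_summary_stats(config: SimulationConfig) -> pd.DataFrame:
    """External-GWAS-style summary statistics for the simulated panel.

    A fraction of rows (``swap_allele_fraction``) is listed on the other
    allele with the sign of the log-odds flipped, exercising downstream
    allele alignment.  Returns the standard summary-stat frame
    (id, chrom, pos, a1, a2, beta, p).
    """
    rng = _children(config)[3]
    eff = _variant_effects(config)
    out = eff[["id", "chrom", "pos", "a1", "a2"]].copy()
    out["beta"] = eff["weight"]
    out["p"] = eff["p"]
    if config.swap_allele_fraction > 0:
        swap = rng.random(len(out)) < config.swap_allele_fraction
        a1 = out["a1"].to_numpy().copy()
        out.loc[swap, "a1"] = out.loc[swap, "a2"].to_numpy()
        out.loc[swap, "a2"] = a1[swap]
        out.loc[swap, "beta"] = -out.loc[swap, "beta"]
    return out[SUMMARY_COLUMNS]


def _burden(dosage: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted allele burden, mean-imputed and standardised (zeros if the
    weighted burden has no variance)."""
    filled = np.where(np.isnan(dosage), np.nanmean(dosage, axis=0), dosage)
    raw = filled @ weights
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else np.zeros(len(raw))


def simulate_cohort(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Longitudinal MMSE-like outcomes, covariates and amyloid status.

    Amyloid positivity is Bernoulli with logit linear in the mediated
    burden; the true slope is
    ``base_slope − direct_effect·D_j − mediated_effect·A_j + deviation``.
    The recorded true proportion mediated is computed from the noise-free
    part of the slope regressed on the standardized causal-variant score,
    with and without amyloid adjustment.
    """
    rng = _children(config)[4]
    eff = _variant_effects(config)
    present = eff["id"].isin(genotypes.variants["id"])
    eff = eff.loc[present].reset_index(drop=True)
    cols = [genotypes.variant_index(v) for v in eff["id"]]
    G = genotypes.dosages[:, cols]
    w = eff["weight"].to_numpy()
    direct_mask = (eff["class"] == "direct").to_numpy()
    # the APOE ε variants act through amyloid, like the mediated class
    mediated_mask = eff["class"].isin(["mediated", "apoe"]).to_numpy()
    causal_mask = direct_mask | mediated_mask

    n = genotypes.n_samples
    D = _burden(G[:, direct_mask], w[direct_mask]) if direct_mask.any() else np.zeros(n)
    M = (
        _burden(G[:, mediated_mask], w[mediated_mask])
        if mediated_mask.any()
        else np.zeros(n)
    )
    p_ab = expit(config.ab_intercept + config.ab_slope * M)
    ab = (rng.random(n) < p_ab).astype(float)

    # CSF ratio drawn consistently with the 0.09 cutoff
    ratio = np.where(
        ab == 1,
        np.clip(rng.normal(0.065, 0.010, n), 0.02, 0.0899),
        np.clip(rng.normal(0.125, 0.015, n), 0.0901, 0.20),
    )

    det_slope = (
        config.base_slope
        - config.direct_effect * D
        - config.mediated_effect * ab
    )
    slope = det_slope + rng.normal(0.0, config.slope_sd, n)
    intercept = (
        config.base_intercept
        - config.ab_intercept_effect * ab
        + rng.normal(0.0, config.intercept_sd, n)
    )

    age = rng.normal(72.0, 5.0, n)
    education = np.clip(rng.normal(12.0, 3.6, n), 5.0, 25.0)
    gender = (rng.random(n) < 0.55).astype(int)

    sched = np.asarray(config.visit_schedule, dtype=float)
    rows = []
    follow_up = np.empty(n)
    truncated = 0
    for i, subj in enumerate(genotypes.samples):
        n_visits = len(sched)
        for v in range(3, len(sched)):
            if rng.random() < config.dropout:
                n_visits = v
                break
        times = sched[:n_visits]
        follow_up[i] = times[-1]
        resid = rng.normal(0.0, config.residual_sd, n_visits)
        y_cont = intercept[i] + slope[i] * times + resid
        y_mmse = np.clip(np.rint(y_cont), 0, 30)
        truncated += int(((y_cont > 30.0) | (y_cont < 0.0)).sum())
        for t, yc, ym in zip(times, y_cont, y_mmse):
            rows.append((subj, float(t), int(ym), float(yc)))
    long_df = pd.DataFrame(
        rows, columns=["subject_id", "time_years", "score", "score_continuous"]
    )

    baseline = long_df[long_df["time_years"] == sched[0]].set_index("subject_id")["score"]
    idx = pd.Index(genotypes.samples, name="subject_id")
    covariates = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "education_years": education,
            "ab_ratio": ratio,
            "ab_status": np.where(ab == 1, "positive", "negative"),
            "baseline_score": baseline.reindex(idx).to_numpy(),
        },
        index=idx,
    )

    pm_true = float("nan")
    if causal_mask.any():
        X = _burden(G[:, causal_mask], w[causal_mask])
        if X.std() > 0 and 0 < ab.sum() < n:
            c = np.polyfit(X, det_slope, 1)[0]
            A2 = np.column_stack([np.ones(n), X, ab])
            c_prime = np.linalg.lstsq(A2, det_slope, rcond=None)[0][1]
            if abs(c) > 1e-12:
                pm_true = float(np.clip(1.0 - c_prime / c, 0.0, 1.0))

    subjects = pd.DataFrame(
        {
            "true_intercept": intercept,
            "true_slope": slope,
            "det_slope": det_slope,
            "direct_burden": D,
            "mediated_burden": M,
            "ab_true": ab.astype(int),
        },
        index=idx,
    )
    truth = TruthRecord(
        subjects=subjects,
        variants=eff[["id", "class", "weight"]].copy(),
        true_proportion_mediated=pm_true,
        mean_follow_up_years=float(follow_up.mean()),
        truncation_count=truncated,
        seed=config.seed,
    )
    return long_df, covariates, truth


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    summary_stats: pd.DataFrame = field(repr=False)
    longitudinal: pd.DataFrame = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)
    truth: TruthRecord


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete study (genotypes, GWAS panel, cohort, truth)."""
    cfg = config or SimulationConfig()
    geno = simulate_genotypes(cfg)
    stats = simulate_summary_stats(cfg)
    long_df, cov, truth = simulate_cohort(geno, cfg)
    return SimulatedStudy(cfg, geno, stats, long_df, cov, truth)
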