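"""End-to-end orchestration: simulate/read -> QC -> scores -> trajectories
-> association -> mediation -> decomposition, as one reproducible run.

Every stochastic stage receives a child seed derived deterministically from
the global seed, all tabular output is tab-delimited with a fixed float
format, and a manifest records the config hash, seeds and per-stage filter
counts, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decomposition import DecompositionResult, decompose
from .genotypes import GenotypeMatrix, read_genotypes
from .mediation import MediationResult, mediate
from .qc import QcThresholds, genotype_pca, sample_qc, variant_qc
from .scoring import (
    ScoreSet,
    apoe_allele_counts,
    classify_ab_status,
    clump,
    exclude_apoe_region,
    read_summary_stats,
    score_threshold_series,
)
from .simulate import SimulationConfig, simulate_study
from .trajectories import (
    AssociationResult,
    RandomEffects,
    associate,
    fit_trajectories,
    int_transform,
    interaction_test,
)

log = logging.getLogger("cogpgs")
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips losslessly to YAML."""

    # data source: either a simulation config or four input paths
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    genotypes_path: str | None = None
    summary_stats_path: str | None = None
    longitudinal_path: str | None = None
    covariates_path: str | None = None
    # analysis parameters
    qc: QcThresholds = field(default_factory=QcThresholds)
    clump_r2: float = 0.1
    clump_window_kb: int = 1000
    ploidy: int = 2
    strict_denominator: bool = False
    standardize_scores: bool = True
    pca_components: int = 10
    covariates: tuple[str, ...] = ("age", "gender", "education_years")
    family_size: int = 7
    alpha: float = 0.05
    n_boot: int = 1000
    scan_n_boot: int = 200
    seed: int = 0
    outcome_column: str = "score"
    outdir: str = "cogpgs_run"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            for key in ("maf_range", "causal_weight_range", "visit_schedule"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["simulation"] = SimulationConfig(**sim)
        if d.get("qc") is not None:
            d["qc"] = QcThresholds(**d["qc"])
        if d.get("covariates") is not None:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (the output path is
        excluded so relocated runs keep the same identity)."""
        d = self.to_dict()
        d.pop("outdir", None)
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_inputs(
    genotypes_path: str,
    summary_stats_path: str,
    longitudinal_path: str,
    covariates_path: str,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and validate the four input tables.

    Genotypes come from VCF (GT field; ALT counted as the effect allele) or
    a dosage TSV; phenotypes are a long table (subject_id, time_years,
    score); covariates are one row per subject.  Unknown covariate columns
    are preserved.
    """
    geno = read_genotypes(genotypes_path)
    stats = read_summary_stats(summary_stats_path)
    long_df = pd.read_csv(longitudinal_path, sep="\t")
    need = {"subject_id", "time_years"}
    if not need <= set(long_df.columns):
        raise ValueError(f"{longitudinal_path}: needs columns {sorted(need)}")
    cov = pd.read_csv(covariates_path, sep="\t")
    if "subject_id" not in cov.columns:
        raise ValueError(f"{covariates_path}: needs a subject_id column")
    cov = cov.set_index("subject_id")
    log.info(
        "inputs: %d samples x %d variants, %d summary rows, %d visits, %d subjects",
        geno.n_samples, geno.n_variants, len(stats), len(long_df), len(cov),
    )
    return geno, stats, long_df, cov


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: RunConfig
    genotypes: GenotypeMatrix
    scores: dict[int, ScoreSet]
    effects: RandomEffects
    associations: pd.DataFrame
    interaction: AssociationResult | None
    mediation: MediationResult | None
    decomposition: DecompositionResult | None
    best_threshold: int | None
    manifest: dict


def _ab_series(covariates: pd.DataFrame) -> pd.Series:
    if "ab_status" in covariates.columns:
        s = covariates["ab_status"]
        if s.dtype == object:
            return s.map({"positive": 1.0, "negative": 0.0})
        return s.astype(float)
    if "ab_ratio" in covariates.columns:
        status = covariates["ab_ratio"].map(classify_ab_status)
        return status.map({"positive": 1.0, "negative": 0.0})
    raise ValueError("covariate table needs ab_status or ab_ratio")


def _apoe_covariates(geno: GenotypeMatrix) -> pd.DataFrame | None:
    ids = set(geno.variants["id"])
    if not {"rs429358", "rs7412"} <= ids:
        log.warning("rs429358/rs7412 not genotyped; APOE covariates unavailable")
        return None
    d4 = geno.dosages[:, geno.variant_index("rs429358")]
    d2 = geno.dosages[:, geno.variant_index("rs7412")]
    e2 = np.full(geno.n_samples, np.nan)
    e4 = np.full(geno.n_samples, np.nan)
    bad = 0
    for i in range(geno.n_samples):
        if np.isnan(d4[i]) or np.isnan(d2[i]):
            continue
        try:
            st = apoe_allele_counts(int(d4[i]), int(d2[i]))
        except ValueError:
            bad += 1
            continue
        e2[i], e4[i] = st.e2, st.e4
    if bad:
        log.warning("%d samples with impossible APOE genotypes set to missing", bad)
    return pd.DataFrame(
        {"apoe_e2": e2, "apoe_e4": e4}, index=pd.Index(geno.samples, name="sample")
    )


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write the result bundle."""
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="[cogpgs:%(levelname)s] %(message)s",
    )
    seeds = [int(s.generate_state(1)[0] >> 1) for s in
             np.random.SeedSequence(config.seed).spawn(4)]
    outdir = Path(config.outdir)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seeds": {"mediation": seeds[0], "decomposition": seeds[1]},
        "stages": {},
    }

    # --- stage: data -----------------------------------------------------
    if config.simulation is not None:
        # the global seed governs every stage, including the simulation
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        log.info("simulating study (seed %d)", sim_cfg.seed)
        study = simulate_study(sim_cfg)
        geno, stats = study.genotypes, study.summary_stats
        long_df, cov_table = study.longitudinal, study.covariates
        truth = study.truth
    else:
        paths = (
            config.genotypes_path, config.summary_stats_path,
            config.longitudinal_path, config.covariates_path,
        )
        if any(p is None for p in paths):
            raise ValueError("need all four input paths when not simulating")
        geno, stats, long_df, cov_table = read_inputs(*paths)
        truth = None
    manifest["stages"]["input"] = {
        "n_samples": geno.n_samples, "n_variants": geno.n_variants,
        "n_summary": len(stats),
    }

    # --- stage: QC (samples first, then variants) ------------------------
    geno_s, sample_report = sample_qc(geno, config.qc)
    geno_qc, variant_report = variant_qc(geno_s, config.qc)
    manifest["stages"]["sample_qc"] = {
        "input": geno.n_samples,
        "retained": geno_s.n_samples,
        "removed": geno.n_samples - geno_s.n_samples,
    }
    manifest["stages"]["variant_qc"] = {
        "input": geno_s.n_variants,
        "retained": geno_qc.n_variants,
        "removed": geno_s.n_variants - geno_qc.n_variants,
    }
    log.info(
        "QC: %d/%d samples, %d/%d variants retained",
        geno_s.n_samples, geno.n_samples, geno_qc.n_variants, geno_s.n_variants,
    )

    # --- stage: covariates (amyloid, APOE counts, PCs) --------------------
    cov_table = cov_table.loc[cov_table.index.intersection(geno_qc.samples)]
    ab = _ab_series(cov_table)
    apoe = _apoe_covariates(geno_qc)
    k = min(config.pca_components, geno_qc.n_samples - 1)
    pcs = genotype_pca(geno_qc, k=k)
    model_cov = cov_table.reindex(geno_qc.samples)[list(config.covariates)].astype(float)
    model_cov.index.name = "sample"
    if apoe is not None:
        model_cov = model_cov.join(apoe)
    model_cov = model_cov.join(pcs)
    baseline = (
        cov_table.reindex(geno_qc.samples)["baseline_score"].astype(float)
        if "baseline_score" in cov_table.columns
        else None
    )
    ab = ab.reindex(geno_qc.samples)
    ab.index.name = "sample"
    if baseline is not None:
        baseline.index.name = "sample"

    # --- stage: polygenic scores -----------------------------------------
    stats_apoe = exclude_apoe_region(stats, geno_qc)
    clumped = clump(
        stats_apoe, geno_qc, r2_max=config.clump_r2, window_kb=config.clump_window_kb
    )
    manifest["stages"]["clump"] = {"input": len(stats_apoe), "retained": len(clumped),
                                   "removed": len(stats_apoe) - len(clumped)}
    scores = score_threshold_series(
        geno_qc, clumped, ploidy=config.ploidy,
        standardize=config.standardize_scores,
        strict_denominator=config.strict_denominator,
    )
    log.info("scores at %d thresholds: %s",
             len(scores), {k: s.n_variants for k, s in scores.items()})

    # --- stage: trajectories ---------------------------------------------
    effects = fit_trajectories(long_df, outcome=config.outcome_column)
    manifest["stages"]["trajectories"] = {
        "n_subjects": effects.n_subjects,
        "n_observations": effects.n_observations,
        "excluded_subjects": effects.n_excluded_subjects,
        "converged": effects.converged,
        "fixed_slope": effects.fixed_slope,
    }

    # --- stage: associations ---------------------------------------------
    rows = []
    results: dict[tuple[int, str, str], AssociationResult] = {}
    m = config.family_size
    for kk, ss in scores.items():
        for target in ("slope", "intercept"):
            for model, extra in (("base", None), ("ab_adjusted", ab.rename("ab_status"))):
                cov_m = model_cov
                if extra is not None:
                    cov_m = model_cov.join(extra)
                res = associate(
                    ss, effects, target, cov_m, family_size=m,
                    baseline_scores=baseline,
                )
                results[(kk, target, model)] = res
                rows.append(
                    {
                        "threshold": kk, "p_cutoff": ss.p_cutoff,
                        "n_variants": ss.n_variants, "target": target,
                        "model": model, "beta": res.beta, "se": res.se,
                        "p": res.p, "p_bonferroni": res.p_bonferroni,
                        "n": res.n,
                    }
                )
    associations = pd.DataFrame(rows)

    base_slope = associations.query("target == 'slope' and model == 'base'")
    best_threshold = (
        int(base_slope.loc[base_slope["p"].idxmin(), "threshold"])
        if len(base_slope)
        else None
    )
    log.info("best slope-associated score: threshold %s", best_threshold)

    interaction = None
    mediation_res = None
    decomposition_res = None
    if best_threshold is not None:
        best = scores[best_threshold]
        interaction = interaction_test(
            best, effects, "slope", ab, model_cov, baseline_scores=baseline
        )
        slope_int = pd.Series(
            int_transform(effects.effects["slope"]),
            index=effects.effects.index, name="slope_int",
        )
        slope_int.index.name = "sample"
        mediation_res = mediate(
            best, ab, slope_int, model_cov,
            n_boot=config.n_boot, seed=seeds[0],
        )
        from .scoring import threshold_series

        best_records = threshold_series(clumped)[best_threshold]
        if len(best_records) >= 3:
            decomposition_res = decompose(
                best_records, geno_qc, ab, slope_int, model_cov,
                alpha=config.alpha, ploidy=config.ploidy,
                scan_n_boot=config.scan_n_boot, seed=seeds[1],
            )
        else:
            log.warning("best score has <3 variants; decomposition skipped")

    result = PipelineResult(
        config=config, genotypes=geno_qc, scores=scores, effects=effects,
        associations=associations, interaction=interaction,
        mediation=mediation_res, decomposition=decomposition_res,
        best_threshold=best_threshold, manifest=manifest,
    )
    if write_outputs:
        _write_bundle(
            result, outdir, sample_report, variant_report, clumped, truth,
            slope_int=None,
        )
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _write_bundle(
    result: PipelineResult,
    outdir: Path,
    sample_report: pd.DataFrame,
    variant_report: pd.DataFrame,
    clumped: pd.DataFrame,
    truth,
    slope_int=None,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    # bundles are location independent: the emitted config never embeds the
    # output path, so identical runs are byte-identical wherever they land
    dataclasses.replace(cfg, outdir=".").to_yaml(outdir / "config.yaml")
    head = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    result.genotypes.to_dosage_tsv(outdir / "genotypes_qc.tsv")
    sample_report.to_csv(outdir / "qc_samples.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    variant_report.to_csv(outdir / "qc_variants.tsv", sep="\t", index=False,
                          float_format=_FLOAT_FMT)
    clumped.to_csv(outdir / "clumped_summary_stats.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    for k, ss in result.scores.items():
        df = pd.DataFrame({"sample_id": ss.scores.index, "prs": ss.scores.to_numpy(),
                           "m": ss.m.to_numpy()})
        df.to_csv(outdir / f"scores_PRS{k}.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    result.effects.effects.to_csv(outdir / "random_effects.tsv", sep="\t",
                                  float_format=_FLOAT_FMT)
    result.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)
    if result.mediation is not None:
        med = result.mediation
        _dump_json(
            {**head, "a": med.a, "a_p": med.a_p, "b": med.b, "b_p": med.b_p,
             "c": med.c, "c_p": med.c_p, "c_prime": med.c_prime,
             "c_prime_p": med.c_prime_p, "indirect": med.indirect,
             "proportion_mediated": med.proportion_mediated,
             "ci_indirect": list(med.ci_indirect),
             "ci_proportion": list(med.ci_proportion) if med.ci_proportion else None,
             "n_boot": med.n_boot, "boot_seed": med.seed, "n": med.n},
            outdir / "mediation.json",
        )
        (outdir / "mediation.txt").write_text(med.summary() + "\n")
    if result.decomposition is not None:
        dec = result.decomposition
        dec.per_variant.to_csv(outdir / "decomposition_variants.tsv", sep="\t",
                               index=False, float_format=_FLOAT_FMT)
        dec.scan_ascending.to_csv(outdir / "decomposition_scan_ascending.tsv",
                                  sep="\t", index=False, float_format=_FLOAT_FMT)
        dec.scan_descending.to_csv(outdir / "decomposition_scan_descending.tsv",
                                   sep="\t", index=False, float_format=_FLOAT_FMT)
        _dump_json(
            {**head, "k_independent": dec.k_independent,
             "k_dependent": dec.k_dependent, "alpha": dec.alpha,
             "scan_seed": dec.seed},
            outdir / "selection.json",
        )
    if truth is not None:
        _dump_json({**head, **truth.to_json_dict()}, outdir / "truth.json")
    _dump_json({**head, **result.manifest}, outdir / "manifest.json")
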