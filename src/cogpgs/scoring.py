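"""Polygenic score construction.

Implements the PLINK-style score

    PRS_j = sum_i S_i * G_ij / (P * M_j)

where ``S_i`` is the log odds ratio of variant *i* from external GWAS summary
statistics, ``G_ij`` the effect-allele dosage of sample *j*, ``P`` the ploidy
and ``M_j`` the number of non-missing variants for sample *j*.  A missing
genotype is replaced by ``MAF_i * P``.  Upstream of scoring: amyloid status
classification from the CSF Aβ42/Aβ40 ratio, APOE-region exclusion with
reintroduction of the ε-defining variants rs7412/rs429358, greedy LD
clumping, and the seven-level p-value threshold series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, _norm_chrom

#: GWAS p-value cutoffs defining score levels 1-7 (level 7 = genome-wide).
THRESHOLDS: tuple[float, ...] = (5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)

#: APOE gene region on GRCh37/hg19 (inclusive bounds).
APOE_REGION = ("19", 44_400_000, 46_500_000)

#: The ε-haplotype defining variants, reintroduced after region exclusion.
APOE_SNPS = ("rs7412", "rs429358")

SUMMARY_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "beta", "p"]


def read_summary_stats(path) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV with columns
    ``ID, CHR, POS, A1, A2, OR, P`` (or already-converted ``BETA`` instead of
    ``OR``).  A1 is the effect allele; OR is converted to ln(OR) on load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "CHR": str})
    cols = {c.upper(): c for c in df.columns}
    required = ["ID", "CHR", "POS", "A1", "A2", "P"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: summary stats missing columns {missing}")
    out = pd.DataFrame(
        {
            "id": df[cols["ID"]].astype(str),
            "chrom": df[cols["CHR"]].astype(str),
            "pos": df[cols["POS"]].astype(int),
            "a1": df[cols["A1"]].astype(str),
            "a2": df[cols["A2"]].astype(str),
            "p": df[cols["P"]].astype(float),
        }
    )
    if "BETA" in cols:
        out["beta"] = df[cols["BETA"]].astype(float)
    elif "OR" in cols:
        out["beta"] = np.log(df[cols["OR"]].astype(float))
    else:
        raise ValueError(f"{path}: need an OR or BETA column")
    if ((out["p"] <= 0) | (out["p"] > 1)).any():
        raise ValueError(f"{path}: p-values must be in (0, 1]")
    return out[SUMMARY_COLUMNS]


def write_summary_stats(records: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "ID": records["id"],
            "CHR": records["chrom"],
            "POS": records["pos"],
            "A1": records["a1"],
            "A2": records["a2"],
            "OR": np.exp(records["beta"]),
            "P": records["p"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class ScoreSet:
    """Per-sample polygenic scores at one p-value threshold."""

    label: str
    p_cutoff: float
    scores: pd.Series              # indexed by sample id
    m: pd.Series                   # per-sample non-missing variant count
    n_variants: int
    ploidy: int = 2
    variant_ids: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")
        if (self.m > self.n_variants).any():
            raise ValueError("per-sample variant count exceeds total count")


@dataclass(frozen=True)
class ApoeStatus:
    """APOE ε2 / ε4 allele counts for one sample."""

    e2: int
    e4: int

    def __post_init__(self) -> None:
        if not (0 <= self.e2 <= 2 and 0 <= self.e4 <= 2):
            raise ValueError("allele counts must be in 0..2")
        if self.e2 + self.e4 > 2:
            raise ValueError("a diploid carries at most two ε alleles")


def classify_ab_status(ratio: float) -> str | None:
    """Binary amyloid status from the CSF Aβ42/Aβ40 ratio.

    Positive iff ratio < 0.09 (strict).  Non-positive or missing ratios
    yield ``None`` (status unknown; subject excluded downstream).
    """
    if ratio is None or not np.isfinite(ratio) or ratio <= 0:
        warnings.warn(f"invalid Aβ42/Aβ40 ratio {ratio!r}: status set to missing")
        return None
    return "positive" if ratio < 0.09 else "negative"


def exclude_apoe_region(
    records: pd.DataFrame, genotypes: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Drop summary-stat records inside the APOE region
    (chr19:44,400,000-46,500,000, GRCh37, inclusive), then reintroduce
    rs7412 and rs429358 provided they are genotyped."""
    chrom, lo, hi = APOE_REGION
    in_region = (
        records["chrom"].map(_norm_chrom).eq(chrom)
        & records["pos"].between(lo, hi)
    )
    keep = records.loc[~in_region]
    readd_ids = []
    for rsid in APOE_SNPS:
        hit = records.loc[in_region & (records["id"] == rsid)]
        if hit.empty:
            continue
        if genotypes is not None and rsid not in set(genotypes.variants["id"]):
            warnings.warn(
                f"{rsid} not genotyped: cannot reintroduce; APOE covariate "
                "will be unavailable"
            )
            continue
        readd_ids.append(hit)
    if readd_ids:
        keep = pd.concat([keep] + readd_ids)
    return keep.sort_index().reset_index(drop=True)


def apoe_allele_counts(dosage_rs429358_C: int, dosage_rs7412_T: int) -> ApoeStatus:
    """ε-allele counts from the two defining variants.

    ε4 count equals the rs429358-C dosage and ε2 count the rs7412-T dosage;
    the unphased double heterozygote is assigned ε2/ε4 (ε1 and ε3r are
    vanishingly rare).  Combinations implying more than two ε2+ε4 alleles
    are impossible in a diploid and raise.
    """
    e4, e2 = int(dosage_rs429358_C), int(dosage_rs7412_T)
    if not (0 <= e4 <= 2 and 0 <= e2 <= 2):
        raise ValueError("dosages must be in {0, 1, 2}")
    if e2 + e4 > 2:
        raise ValueError(
            f"rs429358-C={e4} with rs7412-T={e2} implies >2 ε alleles "
            "(would require an ε1 haplotype count above ploidy)"
        )
    return ApoeStatus(e2=e2, e4=e4)


def _pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation over samples with both dosages observed."""
    ok = ~(np.isnan(d1) | np.isnan(d2))
    if ok.sum() < 2:
        return 0.0
    x, y = d1[ok], d2[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def clump(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: int = 1000,
) -> pd.DataFrame:
    """Greedy LD clumping of summary-stat records.

    Repeatedly take the remaining record with the smallest p-value as an
    index variant and discard all remaining same-chromosome records within
    ±``window_kb`` whose dosage r² with the index is >= ``r2_max`` (r²
    computed from the cohort genotypes over pairwise-complete samples).
    Records absent from the genotype panel are dropped with a warning
    beforehand.  Ties in p are broken by (chromosome, position, id).
    Output preserves ascending-p order of the retained index variants.
    """
    known = set(genotypes.variants["id"])
    present = records["id"].isin(known)
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} summary-stat variants absent from genotypes; "
            "dropped before clumping"
        )
    recs = records.loc[present].copy()
    recs = recs.sort_values(
        ["p", "chrom", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    window = window_kb * 1000

    col = {v: genotypes.variant_index(v) for v in recs["id"]}
    alive = np.ones(len(recs), dtype=bool)
    chrom = recs["chrom"].map(_norm_chrom).to_numpy()
    pos = recs["pos"].to_numpy()
    kept_rows = []
    for i in range(len(recs)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        alive[i] = False
        di = genotypes.dosages[:, col[recs.at[i, "id"]]]
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        for j in np.flatnonzero(near):
            if _pairwise_r2(di, genotypes.dosages[:, col[recs.at[j, "id"]]]) >= r2_max:
                alive[j] = False
    return recs.iloc[kept_rows].reset_index(drop=True)


def threshold_series(records: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Nested subsets of (clumped) records at the seven p-value cutoffs.

    Level k (1-7) holds records with p <= THRESHOLDS[k-1]; empty levels are
    skipped with a warning.
    """
    out: dict[int, pd.DataFrame] = {}
    for k, cutoff in enumerate(THRESHOLDS, start=1):
        sub = records.loc[records["p"] <= cutoff].reset_index(drop=True)
        if sub.empty:
            warnings.warn(f"threshold level {k} (p<={cutoff:g}) has no variants")
            continue
        out[k] = sub
    return out


def _align_effects(
    records: pd.DataFrame, genotypes: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Align record effect alleles to the genotype dosage coding.

    Returns (column indices, dosage matrix coded on each record's effect
    allele).  A record whose alleles match the genotyped pair in swapped
    orientation has its dosage recoded G -> P - G; any other allele
    combination raises, naming the offending variants.
    """
    cols = np.array([genotypes.variant_index(v) for v in records["id"]])
    gv = genotypes.variants.iloc[cols]
    same = (records["a1"].to_numpy() == gv["a1"].to_numpy()) & (
        records["a2"].to_numpy() == gv["a2"].to_numpy()
    )
    swapped = (records["a1"].to_numpy() == gv["a2"].to_numpy()) & (
        records["a2"].to_numpy() == gv["a1"].to_numpy()
    )
    bad = ~(same | swapped)
    if bad.any():
        raise ValueError(
            "allele mismatch between summary stats and genotypes for: "
            + ", ".join(records["id"].to_numpy()[bad][:10])
        )
    G = genotypes.dosages[:, cols].copy()
    G[:, swapped] = 2.0 - G[:, swapped]
    return cols, G


def score(
    genotypes: GenotypeMatrix,
    records: pd.DataFrame,
    ploidy: int = 2,
    label: str = "PRS",
    p_cutoff: float = np.nan,
    strict_denominator: bool = False,
) -> ScoreSet:
    """Compute PRS_j = Σ S_i·G_ij / (P·M_j) for every sample.

    A missing genotype contributes the cohort frequency of the (aligned)
    effect allele times ploidy in place of ``G_ij``.  For the usual GWAS
    coding — effect allele = minor allele — this is exactly the printed
    ``MAF_i · P`` rule; when a record is coded on the major allele the
    aligned frequency keeps the substitution mean-consistent and makes
    scores invariant to allele flips.  By default a substituted variant
    still counts as observed, so the denominator is ``P·N`` — the
    mean-imputation reading of the formula.  With
    ``strict_denominator=True`` the denominator is the literal ``P·M_j``
    (non-missing count only) while the numerator keeps the substitution.
    """
    if records.empty:
        raise ValueError("cannot score an empty record set")
    _, G = _align_effects(records, genotypes)
    S = records["beta"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        eff_freq = np.nanmean(G, axis=0) / ploidy
    eff_freq = np.nan_to_num(eff_freq, nan=0.0)
    miss = np.isnan(G)
    Gfill = np.where(miss, eff_freq * ploidy, G)
    numer = Gfill @ S
    m_obs = (~miss).sum(axis=1)
    n = len(records)
    if strict_denominator:
        denom = ploidy * np.maximum(m_obs, 1)
    else:
        denom = np.full(genotypes.n_samples, ploidy * n, dtype=float)
    prs = numer / denom
    idx = pd.Index(genotypes.samples, name="sample")
    return ScoreSet(
        label=label,
        p_cutoff=float(p_cutoff),
        scores=pd.Series(prs, index=idx, name=label),
        m=pd.Series(m_obs, index=idx, name="m"),
        n_variants=n,
        ploidy=ploidy,
        variant_ids=list(records["id"]),
    )


def standardize_scores(scoreset: ScoreSet) -> ScoreSet:
    """Centre to mean 0 and scale to SD 1 (denominator n-1)."""
    x = scoreset.scores.to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance scores cannot be standardized")
    z = (x - x.mean()) / sd
    return replace(
        scoreset,
        scores=pd.Series(z, index=scoreset.scores.index, name=scoreset.label),
        standardized=True,
    )


def score_threshold_series(
    genotypes: GenotypeMatrix,
    records: pd.DataFrame,
    ploidy: int = 2,
    standardize: bool = True,
    strict_denominator: bool = False,
) -> dict[int, ScoreSet]:
    """Score every non-empty threshold level of the (clumped) record set."""
    out = {}
    for k, sub in threshold_series(records).items():
        ss = score(
            genotypes,
            sub,
            ploidy=ploidy,
            label=f"PRS{k}",
            p_cutoff=THRESHOLDS[k - 1],
            strict_denominator=strict_denominator,
        )
        out[k] = standardize_scores(ss) if standardize else ss
    return out
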