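"""Genotype quality control and genotype principal components.

Variant-level filters: autosomal, biallelic, call rate, minor-allele
frequency, and a 1-df chi-square Hardy–Weinberg equilibrium test.
Sample-level filters: genotype missingness and extreme heterozygosity
(distance from the cohort mean heterozygosity rate in SD units).
PCA operates on the column-standardised dosage matrix with per-variant
mean imputation of missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults follow common array-QC practice for a
    moderately sized cohort (MAF >= 5% rather than 1%)."""

    variant_call_rate_min: float = 0.99   # retain call rate > this (strict)
    maf_min: float = 0.05                 # retain MAF >= this
    hwe_p_min: float = 5e-8               # retain HWE p > this (strict)
    sample_missingness_max: float = 0.01  # remove missingness > this (strict)
    het_sd_multiplier: float = 3.0        # remove |het - mean| > mult * SD

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "maf_min", "sample_missingness_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.het_sd_multiplier < 0:
            raise ValueError("het_sd_multiplier must be non-negative")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy–Weinberg
    proportions computed from the observed allele frequency.

    Monomorphic variants (allele frequency 0 or 1) return p = 1 by
    convention, with a warning: the test is undefined there but such
    variants are always removed by the MAF filter anyway.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)  # frequency of the A allele
    if p in (0.0, 1.0):
        warnings.warn("monomorphic variant: HWE test undefined, returning p=1")
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    out = np.empty(genotypes.n_variants)
    counts = genotypes.genotype_counts()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (n0, n1, n2) in enumerate(counts):
            out[i] = hwe_test(n0, n1, n2) if (n0 + n1 + n2) > 0 else np.nan
    return out


def variant_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply variant-level filters; every rule is evaluated on the input
    matrix so the filters are order-independent.

    Returns the filtered matrix and a per-variant report with a ``kept``
    flag and comma-separated failure ``reasons``
    (``non_autosomal, multiallelic, call_rate, maf, hwe``).
    """
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    thr = thresholds or QcThresholds()

    autosomal = genotypes.is_autosomal()
    # duplicated (chrom, pos) pairs indicate a multi-allelic site split
    # across records; also reject degenerate allele pairs
    locus = genotypes.variants[["chrom", "pos"]].astype(str).agg(":".join, axis=1)
    multi = locus.duplicated(keep=False).to_numpy()
    bad_alleles = (
        genotypes.variants["a1"].astype(str) == genotypes.variants["a2"].astype(str)
    ).to_numpy()
    call = genotypes.call_rate()
    maf = genotypes.maf()
    hwe_p = _hwe_pvalues(genotypes)

    reasons = []
    for i in range(genotypes.n_variants):
        r = []
        if not autosomal[i]:
            r.append("non_autosomal")
        if multi[i] or bad_alleles[i]:
            r.append("multiallelic")
        if not call[i] > thr.variant_call_rate_min:
            r.append("call_rate")
        if not maf[i] >= thr.maf_min:
            r.append("maf")
        if not hwe_p[i] > thr.hwe_p_min:
            r.append("hwe")
        reasons.append(",".join(r))

    report = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "call_rate": call,
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": [r == "" for r in reasons],
            "reasons": reasons,
        }
    )
    kept = report["kept"].to_numpy()
    return genotypes.subset(variant_mask=kept), report


def sample_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove samples with excess genotype missingness (> 1% by default) or
    extreme heterozygosity (beyond ±multiplier·SD of the cohort mean het
    rate).  With fewer than 3 samples the SD is undefined and the
    heterozygosity filter is skipped with a warning; SD = 0 means no
    heterozygosity outliers.
    """
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    thr = thresholds or QcThresholds()

    miss = genotypes.sample_missingness()
    n_obs = (~np.isnan(genotypes.dosages)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.nansum(genotypes.dosages == 1, axis=1) / np.maximum(n_obs, 1)
    het[n_obs == 0] = np.nan

    het_out = np.zeros(genotypes.n_samples, dtype=bool)
    if genotypes.n_samples < 3:
        warnings.warn("fewer than 3 samples: heterozygosity filter skipped")
    else:
        mu, sd = float(np.nanmean(het)), float(np.nanstd(het, ddof=1))
        if sd > 0:
            het_out = np.abs(het - mu) > thr.het_sd_multiplier * sd

    reasons = []
    for i in range(genotypes.n_samples):
        r = []
        if miss[i] > thr.sample_missingness_max:
            r.append("missingness")
        if het_out[i]:
            r.append("heterozygosity")
        reasons.append(",".join(r))

    report = pd.DataFrame(
        {
            "sample": genotypes.samples,
            "missingness": miss,
            "het_rate": het,
            "kept": [r == "" for r in reasons],
            "reasons": reasons,
        }
    )
    kept = report["kept"].to_numpy()
    return genotypes.subset(sample_mask=kept), report


def genotype_pca(genotypes: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal component scores of the standardised dosage matrix.

    Each variant column is centred by 2p̂ and scaled by sqrt(2p̂(1-p̂))
    (the allele-frequency standardisation standard for genotype PCA);
    missing dosages are mean-imputed (zero after centring).  Component
    signs are fixed deterministically (largest-magnitude loading positive).
    """
    n, m = genotypes.n_samples, genotypes.n_variants
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {n}")
    p = genotypes.effect_allele_freq()
    scale = np.sqrt(2 * p * (1 - p))
    X = genotypes.dosages - 2 * p
    X[np.isnan(X)] = 0.0
    nz = scale > 0
    X[:, nz] = X[:, nz] / scale[nz]
    X[:, ~nz] = 0.0
    X = X - X.mean(axis=0)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        # all samples identical: every component score is zero
        scores = np.zeros((n, k))
    elif k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    else:
        scores = U[:, :k] * s[:k]
        # deterministic sign convention
        for j in range(k):
            lead = np.argmax(np.abs(Vt[j]))
            if Vt[j, lead] < 0:
                scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(genotypes.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
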