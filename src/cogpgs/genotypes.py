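"""Genotype container and file I/O.

The central in-memory object is :class:`GenotypeMatrix`, a samples x variants
table of effect-allele dosages (0, 1, 2 or missing) together with the variant
annotations (id, chromosome, 1-based position, effect allele, other allele)
needed for scoring, clumping and QC.  Genotypes are read from VCF (via cyvcf2,
``GT`` field) or from a plain tab-separated dosage matrix, and written back to
either format.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2}`` or ``NaN`` for missing genotypes.  Dosages count copies
        of the *effect allele* (``a1`` in ``variants``), which for VCF input
        is the ALT allele.
    samples
        Sample identifiers, one per row.
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2`` (one row per
        dosage column).  Positions are 1-based.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        self.samples = [str(s) for s in self.samples]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns {missing_cols}")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant count does not match dosage columns")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        if (self.variants["pos"].astype(int) < 0).any():
            raise ValueError("negative variant position")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return int(idx[0])

    # -- per-variant / per-sample statistics ------------------------------

    def effect_allele_freq(self) -> np.ndarray:
        """Frequency of the effect allele among non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant (min of p and 1-p)."""
        p = self.effect_allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """Hard-call counts per variant: columns (n_AA, n_Aa, n_aa).

        ``AA`` is homozygous for the *other* allele (dosage 0) and ``aa``
        homozygous for the effect allele (dosage 2).
        """
        out = np.empty((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosages == g, axis=0)
        return out

    def is_autosomal(self) -> np.ndarray:
        return np.array(
            [_norm_chrom(c) in _AUTOSOMES for c in self.variants["chrom"]], dtype=bool
        )

    # -- subsetting -------------------------------------------------------

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            d = d[sample_mask, :]
            samples = [s for s, k in zip(self.samples, sample_mask) if k] \
                if sample_mask.dtype == bool else [self.samples[i] for i in sample_mask]
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            d = d[:, variant_mask]
            variants = variants.loc[variant_mask] if variant_mask.dtype == bool \
                else variants.iloc[variant_mask]
        return GenotypeMatrix(d.copy(), list(samples), variants.reset_index(drop=True))

    def select_variants(self, ids) -> "GenotypeMatrix":
        order = [self.variant_index(v) for v in ids]
        return self.subset(variant_mask=np.array(order, dtype=int))

    # -- I/O --------------------------------------------------------------

    def to_dosage_tsv(self, path: str | os.PathLike) -> None:
        """Write a dosage TSV: variant annotation columns then one column per
        sample; missing dosages written as ``NA``."""
        with open(path, "w") as fh:
            fh.write("\t".join(VARIANT_COLUMNS + self.samples) + "\n")
            for i in range(self.n_variants):
                row = self.variants.iloc[i]
                vals = [
                    "NA" if np.isnan(v) else str(int(v)) for v in self.dosages[:, i]
                ]
                fh.write(
                    "\t".join(
                        [str(row["id"]), str(row["chrom"]), str(int(row["pos"])),
                         str(row["a1"]), str(row["a2"])] + vals
                    )
                    + "\n"
                )

    @classmethod
    def from_dosage_tsv(cls, path: str | os.PathLike) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: dosage TSV missing columns {missing}")
        samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
        dosages = df[samples].to_numpy(dtype=float).T
        return cls(dosages, samples, df[VARIANT_COLUMNS])

    def to_vcf(self, path: str | os.PathLike) -> None:
        """Write an uncompressed VCF with GT calls.

        The effect allele (``a1``) is written as ALT and the other allele as
        REF, so a dosage of 2 becomes ``1/1``.
        """
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(self.variants["chrom"].astype(str))
        for c in chroms:
            buf.write(f"##contig=<ID={c}>\n")
        buf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples) + "\n"
        )
        for i in range(self.n_variants):
            row = self.variants.iloc[i]
            calls = [
                "./." if np.isnan(v) else gt_map[v] for v in self.dosages[:, i]
            ]
            buf.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['a2']}\t"
                f"{row['a1']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "GenotypeMatrix":
        """Read GT genotypes from a VCF; ALT is taken as the effect allele.

        Multi-allelic records are rejected (the QC module expects biallelic
        input; split such records upstream with ``bcftools norm``).
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows = []
        dosage_rows = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"{path}: multi-allelic record {rec.ID or rec.POS} not supported"
                )
            # gts012=True: 0/1/2 = ALT dosage, 3 = unknown
            g = rec.gt_types.astype(float)
            g[g == 3] = np.nan
            dosage_rows.append(g)
            rows.append(
                {
                    "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                    "chrom": str(rec.CHROM),
                    "pos": int(rec.POS),
                    "a1": rec.ALT[0],
                    "a2": rec.REF,
                }
            )
        if not rows:
            raise ValueError(f"{path}: no variant records")
        variants = pd.DataFrame(rows)
        dup = variants["id"].duplicated()
        if dup.any():
            raise ValueError(
                f"{path}: duplicate variant ids {variants['id'][dup].tolist()[:5]}"
            )
        dosages = np.vstack(dosage_rows).T
        return cls(dosages, samples, variants)


def read_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` -> VCF reader, otherwise dosage TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return GenotypeMatrix.from_vcf(p)
    return GenotypeMatrix.from_dosage_tsv(p)
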