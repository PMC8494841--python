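import numpy as np
import pandas as pd
import pytest

from cogpgs import GenotypeMatrix, SimulationConfig, simulate_study


def make_geno(dosages, chrom=None, pos=None, ids=None, a1=None, a2=None,
              samples=None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array (samples x variants)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "id": ids or [f"v{j + 1}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": pos or [1000 * (j + 1) for j in range(m)],
            "a1": a1 or ["G"] * m,
            "a2": a2 or ["A"] * m,
        }
    )
    return GenotypeMatrix(d, samples or [f"s{i + 1}" for i in range(n)], variants)


def make_records(geno: GenotypeMatrix, beta, p) -> pd.DataFrame:
    """Summary-stat frame matching a genotype matrix's variants."""
    recs = geno.variants.copy()
    recs["beta"] = np.asarray(beta, dtype=float)
    recs["p"] = np.asarray(p, dtype=float)
    return recs


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=150, n_variants=40, n_direct=6, n_mediated=4,
        ld_block_size=5, include_apoe=False, seed=7,
    )
    return simulate_study(cfg)
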