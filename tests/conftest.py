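import numpy as np
import pandas as pd
import pytest

from mqtlnet import SimConfig, simulate_genotypes, simulate_metabolome
from mqtlnet.data import GenotypeMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated study (genotypes + phenotypes + truth)."""
    cfg = SimConfig(
        n_lines=60,
        n_families=6,
        n_snps=300,
        n_traits=6,
        qtl_map=[("m01", 10, 1.0)],
        dag_edges=[("m01", "m02", 0.8)],
        seed=42,
    )
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_metabolome(geno, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture
def toy_geno():
    """3 lines x 2 SNPs with hand-checkable dosages."""
    dosage = np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
    return GenotypeMatrix(["a", "b", "c"], ["s1", "s2"], dosage)


def exact_corr_pair(n: int, rho: float, seed: int = 0) -> pd.DataFrame:
    """Two variables whose SAMPLE correlation is exactly rho.

    Built from an orthonormalized random basis, so tests of correlation
    arithmetic have a closed-form expected value.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, 2))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    x = q[:, 0]
    y = rho * q[:, 0] + np.sqrt(1 - rho**2) * q[:, 1]
    return pd.DataFrame({"x": x, "y": y})
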