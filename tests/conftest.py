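import numpy as np
import pandas as pd
import pytest

from methqtl.core import GenotypeTable
from methqtl.preprocess import quantile_normalize
from methqtl.simulate import SimConfig, simulate_genotypes, simulate_methylation


@pytest.fixture(scope="session")
def planted_dataset():
    """64-sample dataset with strong planted cis effects and regional spans."""
    cfg = SimConfig(
        n_samples=64,
        n_probes=400,
        n_snps=500,
        region_length=400_000,
        causal_fraction=0.25,
        effect_size=1.5,
        regional_effect_span=1500,
        seed=42,
    )
    geno = simulate_genotypes(cfg)
    beta, manifest, truth = simulate_methylation(geno, cfg)
    norm = quantile_normalize(beta)
    return {"cfg": cfg, "geno": geno, "beta": beta, "manifest": manifest,
            "truth": truth, "norm": norm}


@pytest.fixture
def tiny_geno():
    """Hand-built 8-sample, 3-SNP genotype table."""
    rng = np.random.default_rng(0)
    dosages = pd.DataFrame(
        rng.integers(0, 3, size=(8, 3)).astype(float),
        index=[f"s{i}" for i in range(8)],
        columns=["snpA", "snpB", "snpC"],
    )
    snps = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [100, 2500, 9000]},
        index=pd.Index(["snpA", "snpB", "snpC"], name="snp_id"),
    )
    return GenotypeTable(dosages, snps)
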