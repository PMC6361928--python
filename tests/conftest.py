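import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gweis import (
    SimConfig,
    simulate_covariates,
    simulate_exposure,
    simulate_genotypes,
    simulate_phenotype,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 600 x 300 cohort with additive + GxE architecture."""
    cfg = SimConfig(
        n_samples=600,
        n_snps=300,
        n_causal_additive=30,
        n_causal_gxe=30,
        var_additive=0.15,
        var_gxe=0.05,
        seed=11,
    )
    panel = simulate_genotypes(cfg)
    exposure = simulate_exposure(panel, cfg)
    covariates = simulate_covariates(cfg)
    truth = simulate_phenotype(panel, exposure.counts, covariates, cfg)
    return {
        "config": cfg,
        "panel": panel,
        "exposure": exposure,
        "covariates": covariates,
        "truth": truth,
    }


@pytest.fixture()
def tiny_panel():
    """Deterministic 10-sample, 2-SNP panel for closed-form checks."""
    from gweis import GenotypePanel

    rng = np.random.default_rng(5)
    dosages = rng.integers(0, 3, size=(10, 2)).astype(float)
    meta = pd.DataFrame(
        {
            "snp_id": ["s1", "s2"],
            "chrom": "1",
            "pos": [1000, 2000],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypePanel(dosages, meta)
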