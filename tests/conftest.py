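import numpy as np
import pandas as pd
import pytest

import snpsem as ss


@pytest.fixture(scope="session")
def kare_corr():
    """Published covariate-adjusted phenotype correlation matrix (n=8792)."""
    return ss.kare_phenotype_correlations()


@pytest.fixture(scope="session")
def small_cohort():
    """Two planted SNP groups with detectable effects; n=3000."""
    cfg = ss.SimConfig(
        n_subjects=3000, seed=11,
        snp_groups=[ss.SNPGroup("G1", 4, (0.2, 0.4), 0.5),
                    ss.SNPGroup("G2", 3, (0.2, 0.4), 0.5)],
        factor_effects={"G1": ("SUB", 0.25), "G2": ("BMI", 0.2)})
    return ss.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic, cascade, or covariate effects: everything independent."""
    cfg = ss.SimConfig(
        n_subjects=2000, seed=5,
        snp_groups=[ss.SNPGroup("G1", 6, (0.1, 0.5), 0.0)],
        factor_effects={},
        cascade={k: 0.0 for k in ss.simulate.CASCADE_KEYS},
        covariate_effects={})
    return ss.generate_cohort(cfg)


@pytest.fixture(scope="session")
def chain_data():
    """Mediation chain x -> m -> y with a=0.5, b=0.4, n=3000."""
    rng = np.random.default_rng(42)
    n = 3000
    x = rng.standard_normal(n)
    m = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    y = 0.4 * m + np.sqrt(1 - 0.16) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
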