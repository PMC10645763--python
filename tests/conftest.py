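import numpy as np
import pytest
from hypothesis import settings

from fetomod.io_formats import ExpressionMatrix
from fetomod.synthetic import SimulationParams, simulate_cohort

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """300-gene, 200-sample cohort with two planted modules and eQTLs."""
    params = SimulationParams(seed=42, n_genes=300, module_sizes=(40, 30),
                              n_snps=200, n_exposure_samples=200,
                              eqtl_frac=0.5, eqtl_beta_sd=1.0)
    geno, expr, truth = simulate_cohort(params)
    return params, geno, expr, truth


@pytest.fixture()
def toy_expression():
    rng = np.random.default_rng(7)
    values = rng.gamma(2.0, 2.0, size=(20, 10))
    return ExpressionMatrix([f"g{i}" for i in range(20)],
                            [f"s{i}" for i in range(10)], values)
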