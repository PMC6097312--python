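import numpy as np
import pytest

from sirevar import SimConfig, SireDHGLM, assemble_responses, simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study: 120 sires, ~40 progeny each, 80 SNPs on 2 chromosomes."""
    return SimConfig(
        n_sires=120,
        progeny_min=20,
        progeny_max=80,
        n_chr=2,
        snps_per_chr=40,
        n_cg=12,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture(scope="session")
def fitted_pair(small_study):
    """DHGLM fits (free and zero-correlation) on the small study."""
    _, _, pheno = small_study
    model = SireDHGLM(pheno)
    return model.fit(mode="rmv_free"), model.fit(mode="rmv_zero")


@pytest.fixture(scope="session")
def response_set(fitted_pair):
    fit_free, fit_zero = fitted_pair
    return assemble_responses(fit_free, fit_zero)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
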