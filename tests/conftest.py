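import numpy as np
import pandas as pd
import pytest

from txdrivers.synthetic import ComboSpec, GeneratorConfig, generate_bundle

SMALL_GENERATOR = dict(
    n_persistent_modules=2,
    n_pre_only_modules=1,
    n_post_only_modules=1,
    module_size=40,
    n_assisting=10,
    n_impeding=20,
    n_mediators=20,
    n_de_only=200,
    base_log2_mean=8.0,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(**SMALL_GENERATOR)


@pytest.fixture(scope="session")
def clean_bundle(small_config):
    """Planted-truth recovery bundle: deterministic counts (rounded latent
    means), modest latent variability (log2 sd 0.3, which bounds spurious
    expression-sensitivity correlations at ~0.29 across 11 lines), zero
    assay noise."""
    return generate_bundle(
        n_lines=11,
        n_genes=500,
        config=small_config,
        seed=11,
        expression_noise_sd=0.3,
        viability_noise_sd=0.0,
        deterministic=True,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def dose_grid() -> np.ndarray:
    from txdrivers.synthetic import DEFAULT_CONCENTRATIONS

    return np.asarray(DEFAULT_CONCENTRATIONS)
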