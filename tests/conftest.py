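import numpy as np
import pytest

from domphoto.synthetic_data import GeneratorConfig, build_formula_library, synthesize_study


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Desk-scale study used by most integration tests (fast, seeded)."""
    return GeneratorConfig(seed=7, n_lakes=4, formulas_per_lake=150, library_size=2000)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return synthesize_study(small_cfg)


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return build_formula_library(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
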