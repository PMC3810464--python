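import numpy as np
import pytest

from reintro import ModelParams, SingleSexParams


@pytest.fixture(scope="session")
def canonical() -> ModelParams:
    """Symmetric reference parameter set, well inside the spreading regime."""
    return ModelParams(r=0.5, mu_f=0.05, mu_m=0.05, D_f=1.0, D_m=1.0, sigma=1.0)


@pytest.fixture(scope="session")
def canonical_single(canonical) -> SingleSexParams:
    return canonical.to_single_sex()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231028)


def coarse_dx(params: ModelParams, points_per_ell: int = 12) -> float:
    """Grid spacing for PDE-heavy tests: a fixed fraction of the diffusion length."""
    return params.diffusion_length() / points_per_ell
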