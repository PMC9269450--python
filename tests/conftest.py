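import warnings

import numpy as np
import pytest

import oscbaseline as ob


@pytest.fixture
def default_params() -> ob.OscillatorParams:
    return ob.OscillatorParams()


@pytest.fixture
def constant_profile() -> ob.ModulationProfile:
    return ob.ModulationProfile(kind="constant")


@pytest.fixture
def gaussian_profile() -> ob.ModulationProfile:
    return ob.ModulationProfile(
        kind="inverted_gaussian", depth=0.8, center=0.5, sigma_left=0.1, sigma_right=0.2
    )


@pytest.fixture
def small_population(gaussian_profile) -> ob.PopulationConfig:
    """Desk-scale population: N=200, no noise, 1-s epochs."""
    return ob.PopulationConfig(
        n_oscillators=200,
        phases=ob.PhaseConfig(mu0=0.0, kappa=1.0, seed=11),
        modulation=gaussian_profile,
        pink_sigma=0.0,
        white_sigma=0.0,
        n_epochs=5,
    )


def quiet_bsi(*args, **kwargs):
    """compute_bsi with short-trace warnings silenced (test fixtures are short)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ob.compute_bsi(*args, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
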