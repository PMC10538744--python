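import pytest

from ecobehav import ModelParams, params_from_differentials


@pytest.fixture
def default_params() -> ModelParams:
    """A generic symmetric parameter set with mild feedback."""
    return ModelParams(gamma_A=1.0, delta_A=0.5, tau=0.1, ell=0.1, l_A=0.7)


@pytest.fixture
def bistable_params() -> ModelParams:
    """Costly active behavior under strong pressure: two stable equilibria."""
    return params_from_differentials(-0.25, 0.3, tau=0.1, ell=0.1, l_A=0.7)


@pytest.fixture
def cycle_params() -> ModelParams:
    """Intermediate sensitivity-impact product, slow environment: limit cycle."""
    return params_from_differentials(-0.5, 0.25, tau=1.0, ell=0.1, l_A=0.7)


@pytest.fixture
def assessment_only_params() -> ModelParams:
    """No social encounters (kappa = 0): assessment-driven dynamics only."""
    return ModelParams(gamma_A=1.0, delta_A=0.5, tau=1.0, ell=0.1, l_A=0.7,
                       kappa=0.0)
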