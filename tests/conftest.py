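import numpy as np
import pytest

from vasoconduct import default_group_params, default_protocol, generate_vessel
from vasoconduct.synthetic import GroupParams, noiseless


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


def make_params(**overrides) -> GroupParams:
    """A small, fully deterministic single-group parameter set; overrides
    are applied on top of noise-free Cx45-WT-like defaults."""
    base = dict(
        group_label="test", n_vessels=3,
        true_local_constriction=0.23, true_length_constant=455.0,
        baseline_diameter_mean=30.0, baseline_diameter_sd=0.0,
        traceable_length_min=200.0, traceable_length_max=400.0,
        constriction_onset_tau=0.0, recovery_tau=5.0,
        vasomotion_sd=0.0, measurement_noise_sd=0.0,
    )
    base.update(overrides)
    return GroupParams(**base)


@pytest.fixture
def noiseless_params():
    return make_params()


@pytest.fixture
def noiseless_vessel(protocol, noiseless_params):
    return generate_vessel(noiseless_params, protocol, seed=7)


@pytest.fixture
def default_noise_params():
    """Cx45 WT defaults as used in the simulation study."""
    return default_group_params("Cx45 WT")


def exact_decay_points(a: float, lam: float, xs=None) -> np.ndarray:
    """(N, 2) points lying exactly on y = a * exp(-x / lam)."""
    if xs is None:
        xs = np.arange(0.0, 401.0, 50.0)
    xs = np.asarray(xs, float)
    return np.column_stack([xs, a * np.exp(-xs / lam)])
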