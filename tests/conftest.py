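import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water():
    from carbotherm.phsc import load_components

    return load_components("Water")[0]


@pytest.fixture(scope="session")
def glucose():
    from carbotherm.phsc import load_components

    return load_components("D-Glucose")[0]


@pytest.fixture(scope="session")
def water_eos(water):
    from carbotherm.phsc import PhscEos

    return PhscEos([water])


@pytest.fixture(scope="session")
def glucose_water_eos(glucose, water):
    from carbotherm.phsc import PhscEos

    return PhscEos([glucose, water])


@pytest.fixture(scope="session")
def glucose_solution(glucose, water):
    from carbotherm.phsc.properties import BinarySolution

    return BinarySolution(glucose, water)


@pytest.fixture(scope="session")
def noiseless_glucose_dataset(glucose):
    """20-point noiseless synthetic osmotic curve from the packaged glucose
    parameters at 298.15 K (the regression truth fixture)."""
    from carbotherm.synthetic import SyntheticSpec, generate_pseudo_dataset

    spec = SyntheticSpec(sugar=glucose, noise_sd=0.0, n_points=20)
    return generate_pseudo_dataset(spec)


@pytest.fixture(scope="session")
def printed_weights():
    from carbotherm.ann import load_printed_weights

    return load_printed_weights()


@pytest.fixture()
def x05():
    return np.array([0.05, 0.95])
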