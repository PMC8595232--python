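import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tevarsim as tv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wall():
    return tv.YEOH_DISSECTED_AORTA


@pytest.fixture(scope="session")
def nitinol():
    return tv.NITINOL_VALIANT


@pytest.fixture(scope="session")
def default_vessel():
    return tv.generate_vessel()


@pytest.fixture(scope="session")
def prestress_result(default_vessel):
    return tv.prestress_fixed_point(default_vessel)


@pytest.fixture(scope="session")
def prestressed_vessel(default_vessel, prestress_result):
    return default_vessel.with_prestress(prestress_result.sigma0_field)


@pytest.fixture(scope="session")
def deployments(prestressed_vessel):
    """A/B/C deployment results on the default synthetic patient."""
    sg = tv.StentGraft()
    return {
        v: tv.deploy(sg, prestressed_vessel, tv.DeploymentConfig(variant=v)) for v in "ABC"
    }


@pytest.fixture(scope="session")
def dissection_labels(deployments):
    ends = deployments["C"].ends
    return list(ends.loc[ends["section"] == "dissection", "label"])
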