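import numpy as np
import pytest

from mvelastica import ValveMeasurements, identify_preop


@pytest.fixture(scope="session")
def reference_case():
    return ValveMeasurements.reference_case()


@pytest.fixture(scope="session")
def reference_preop(reference_case):
    """Identified preoperative state of the reference patient (shared)."""
    return identify_preop(reference_case, seed=1, mode="best", max_iter=600,
                          symmetric=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
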