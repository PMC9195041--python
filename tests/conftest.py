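import numpy as np
import pytest

from dcekinetics import AcquisitionSchedule, SigmoidParams, simulate_curve


@pytest.fixture
def schedule():
    return AcquisitionSchedule()


@pytest.fixture
def idc_params():
    """Group-mean parameters of the malignant (IDC) cohort."""
    return SigmoidParams(a=1.5, b=19.6, c=0.3, d=-3.7e-4, si0=1.0)


@pytest.fixture
def benign_params():
    """Group-mean parameters of the benign cohort."""
    return SigmoidParams(a=1.4, b=31.5, c=0.1, d=2.2e-4, si0=1.0)


@pytest.fixture
def idc_curve(idc_params):
    return simulate_curve(idc_params)


def rand_valid_params(rng: np.random.Generator) -> SigmoidParams:
    """A random parameter set from the physiologically plausible box."""
    return SigmoidParams(
        a=rng.uniform(0.5, 3.0),
        b=rng.uniform(5.0, 50.0),
        c=rng.uniform(0.05, 1.0),
        d=rng.uniform(-30e-4, 30e-4),
        si0=1.0,
    )
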