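import numpy as np
import pytest

from latentcause.core import ModelParams, Trial


@pytest.fixture
def params():
    return ModelParams()


def make_trial(time, us=1.0, x=(1.0,), phase="other", psi=None):
    return Trial(
        time=float(time),
        features=np.asarray(x, dtype=float),
        outcome=us,
        phase=phase,
        psi=psi,
    )


def acquisition(n=3, us=1.0, start=0.0):
    """n CS-US pairings at unit ITI."""
    return [make_trial(start + i, us=us, phase="acquisition") for i in range(n)]


@pytest.fixture
def acq3():
    return acquisition(3)
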