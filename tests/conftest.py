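import numpy as np
import pytest

from oscillab import HillRepression, SequestrationRepression

# published operating points for the two repression mechanisms
HT_PARAMS = dict(n=11, k_H=0.136)
PS_PARAMS = dict(A=0.0659, k_d=1e-5)

# Synthetic segmentation-clock parameter set (constructed for the test
# suite; it places the pair of cells in an oscillatory regime with a clean
# simple Hopf bifurcation in the transcription rate nu1 near 0.184).
SEGCLOCK_SYNTHETIC = dict(
    nu1=0.22, nu2=0.26, nu3=1.32, nu4=0.59, nu5=0.37, nu6=0.48, nu7=0.13,
    nu8=0.21, k1=0.35, k2=0.33, k4=0.32, k6=0.20, k7=0.50, k8=0.49,
    n=6, h=6, nu_c=0.02, sigma=1.05,
)


@pytest.fixture(scope="session")
def ht():
    return HillRepression(**HT_PARAMS)


@pytest.fixture(scope="session")
def ps():
    return SequestrationRepression(**PS_PARAMS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210423)
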