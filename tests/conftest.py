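import numpy as np
import pytest

from aratile.kernels import KernelParams

# Fig-4-style kernels (narrow vs wide terrace)
NARROW_TERRACE = KernelParams(F0=5000.0, Fr=-5000.0, Fa=500.0,
                              R0=0.14, R1=0.55, R2=0.58)
WIDE_TERRACE = KernelParams(F0=5000.0, Fr=-4000.0, Fa=500.0,
                            R0=0.14, R1=0.55, R2=0.88)

# Unit-strength kernel for quadrature cross-checks: O(1) forces keep the
# convolution/direct-summation comparison at the round-off floor.
UNIT_KERNEL = KernelParams(F0=5.0, Fr=-5.0, Fa=1.0, R0=0.35, R1=0.55, R2=0.7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
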