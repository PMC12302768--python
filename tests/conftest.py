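import numpy as np
import pytest

from nexifit.forward import TissueParams
from nexifit.scheme import AcquisitionScheme, build_protocol, sphere_directions


@pytest.fixture(scope="session")
def c2_scheme():
    return build_protocol("C2", 64)


@pytest.fixture(scope="session")
def c1_scheme():
    return build_protocol("C1", 32)


@pytest.fixture
def gm_params():
    """A cortex-like parameter set (moderate exchange, dispersed sticks)."""
    return TissueParams(f=0.35, dn=2.5, de=0.9, rn=0.04, p2=0.3)


@pytest.fixture(scope="session")
def mini_scheme():
    """Small hand-built 2-time, 2-shell scheme with 24 directions per shell."""
    dirs = sphere_directions(24)
    b_list, t_list, dir_list = [0.0], [13.0], [np.zeros(3)]
    for t in (13.0, 30.0):
        for b in (2.3, 6.5):
            for d in dirs:
                b_list.append(b)
                t_list.append(t)
                dir_list.append(d)
    n = len(b_list)
    return AcquisitionScheme(
        b=np.array(b_list),
        t=np.array(t_list),
        delta=np.full(n, 6.0),
        ramp=np.full(n, 0.83),
        directions=np.vstack(dir_list),
        gmax=500.0,
        name="mini",
    )
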