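import numpy as np
import pytest

from hepatoqst.liver_core import ConstantExposure, simulate
from hepatoqst.params import PhysiologyParams, default_tocilizumab


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def tcz():
    return default_tocilizumab()


@pytest.fixture(scope="session")
def invitro_control():
    """Drug-free in-vitro-like run, 10 days (shared control reference)."""
    return simulate(mode="invitro", duration_days=10.0)


@pytest.fixture(scope="session")
def invitro_tcz_runs(tcz):
    """Tocilizumab in-vitro-like runs at the two interstitial anchors."""
    out = {}
    for conc in (52.4, 166.3):
        out[conc] = simulate(
            drugs=[tcz],
            exposures={"tocilizumab": ConstantExposure(interstitial=conc,
                                                       media=0.0)},
            mode="invitro", duration_days=10.0)
    return out


@pytest.fixture(scope="session")
def baseline_12wk():
    """Drug-free clinical run over the full 12-week protocol horizon."""
    return simulate(duration_days=84.0)
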