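import numpy as np
import pytest

from oralpbpk.core import OralPhysiology
from oralpbpk.pbpk import SimulationGrid

MID_RANGE = dict(
    V_S=0.8,
    Q_S=0.4,
    A_SM=4.0,
    A_SB=2.0,
    A_SP=0.05,
    Gamma_max=10.0,
    k_ads=0.5,
    k_des=0.05,
    P_SM=5e-5,
    K_p_T=5.0,
    V_T=0.075,
    CL_local=0.05,
    D_eff=3e-7,
    k_bind=2e-4,
    L_B=0.02,
    A_BP=0.1,
    V_P=1.0,
    Q_GCF=0.3,
    R_in=0.0,
)


@pytest.fixture
def physiology() -> OralPhysiology:
    """Mid-range physiology; every parameter inside its typical range."""
    return OralPhysiology(**MID_RANGE)


@pytest.fixture
def closed_physiology() -> OralPhysiology:
    """No outflows or sinks: salivary flow, GCF, tissue clearance and biofilm
    binding all zero, so total drug mass is conserved exactly."""
    return OralPhysiology(
        **{**MID_RANGE, "Q_S": 0.0, "Q_GCF": 0.0, "CL_local": 0.0, "k_bind": 0.0}
    )


@pytest.fixture
def fast_grid() -> SimulationGrid:
    """Coarse grid for quick unit-level simulations."""
    return SimulationGrid(t_end=60.0, dt_out=1.0, n_x=40)
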