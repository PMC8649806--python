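import numpy as np
import pytest

from porocell.materials import PoroelasticMaterial, RampLoad
from porocell.solver import (
    BoundaryConditionSet,
    GeometrySpec,
    SolverConfig,
    solve_linear_biot,
)

#: the poroelastic property set used for the simulation studies
MAT = PoroelasticMaterial(E=1.0, nu=0.3, D=10.0)


@pytest.fixture(scope="session")
def mat():
    return MAT


@pytest.fixture(scope="session")
def bcs_free():
    """Traction-free drained surfaces (the standard osmotic condition)."""
    return BoundaryConditionSet(bottom_mech="no_slip", drained_traction="none")


@pytest.fixture(scope="session")
def column_step_run(bcs_free):
    """Laterally confined column under a step load: the 1D oracle setting."""
    cfg = SolverConfig(end_time=20.0, dt_init=0.002, growth=1.1, max_dt=0.1,
                       nx=2, nz=24)
    return solve_linear_biot(
        GeometrySpec(kind="column1d", H=5.5, R=2.0), MAT, bcs_free,
        RampLoad(0.05, 0.0), cfg,
    )


@pytest.fixture(scope="session")
def column_ramp_run(bcs_free):
    cfg = SolverConfig(end_time=20.0, dt_init=0.01, growth=1.1, max_dt=0.1,
                       nx=2, nz=24)
    return solve_linear_biot(
        GeometrySpec(kind="column1d", H=5.5, R=2.0), MAT, bcs_free,
        RampLoad(0.05, 1.0), cfg,
    )


@pytest.fixture(scope="session")
def disk_runs(bcs_free):
    """Disk swelling runs for the three (P_eff, t_r) scenarios."""
    cfg = SolverConfig(end_time=15.0, dt_init=0.01, growth=1.15, max_dt=0.2,
                       nx=16, nz=7)
    out = {}
    for P, t_r in [(0.03, 0.6), (0.05, 1.0), (0.05, 0.6)]:
        out[(P, t_r)] = solve_linear_biot(
            GeometrySpec(kind="disk"), MAT, bcs_free, RampLoad(P, t_r), cfg
        )
    return out
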