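"""Axisymmetric transient solvers for effective-pressure-driven swelling."""

from .geometry import BoundaryConditionSet, GeometrySpec, Mesh, build_mesh
from .biot import (
    ConvergenceError,
    FieldSnapshot,
    SolveResult,
    SolverConfig,
    solve_linear_biot,
)
from .hyper import solve_porohyperelastic
from .postprocess import (
    collapse_check,
    mass_balance_report,
    mesh_convergence_study,
    time_to_plateau,
)

__all__ = [
    "BoundaryConditionSet",
    "GeometrySpec",
    "Mesh",
    "build_mesh",
    "ConvergenceError",
    "FieldSnapshot",
    "SolveResult",
    "SolverConfig",
    "solve_linear_biot",
    "solve_porohyperelastic",
    "collapse_check",
    "mass_balance_report",
    "mesh_convergence_study",
    "time_to_plateau",
]


def solve(geom, mat, bcs, load, cfg=None):
    """Dispatch to the linear or porohyperelastic solver per the config."""
    from .biot import SolverConfig

    cfg = cfg or SolverConfig()
    if cfg.constitutive == "neo_hookean":
        return solve_porohyperelastic(geom, mat, bcs, load, cfg)
    if cfg.constitutive == "linear":
        return solve_linear_biot(geom, mat, bcs, load, cfg)
    raise ValueError(f"unknown constitutive model {cfg.constitutive!r}")
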