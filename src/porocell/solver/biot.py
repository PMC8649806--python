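"""Transient axisymmetric linear Biot poroelasticity.

Mixed u-p formulation with quadratic serendipity displacements and
bilinear pore pressure (an inf-sup stable pairing), backward-Euler time
stepping, incompressible constituents and Biot coefficient 1 — the soft,
fully saturated limit appropriate for cytoplasm.  Sign conventions:
total stress ``sigma = sigma'(u) - p I``; a positive boundary pore
pressure drives fluid in and swells the domain.

The osmotic forcing enters through the drained surfaces: the boundary
pore pressure follows the ramp ``P_eff(t)`` and, with the
``match_pressure`` traction realization, an equal outward normal surface
tension is applied there as well (see
:class:`~porocell.solver.geometry.BoundaryConditionSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..curves import DisplacementCurve
from ..materials import LayeredMaterial, PoroelasticMaterial, RampLoad
from .fem import ElementBasis
from .geometry import BoundaryConditionSet, GeometrySpec, Mesh, build_mesh, locate_probes

__all__ = ["SolverConfig", "FieldSnapshot", "SolveResult", "solve_linear_biot"]

_DEFAULT_MESH = {"disk": (24, 10), "cell_cap": (20, 8), "column1d": (2, 24)}


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries diagnostics in ``args``."""


@dataclass
class SolverConfig:
    """Run controls for the transient solvers.

    ``dt_init = None`` auto-selects ``t_r / 20`` (or 0.01 s for a step
    load).  The step grows geometrically by ``growth`` per accepted step
    (capped at 2x), never exceeding ``max_dt``; a step landing across the
    end of the ramp is shortened to hit ``t_r`` exactly.
    """

    constitutive: str = "linear"
    end_time: float = 30.0
    dt_init: float | None = None
    adaptive: bool = True
    growth: float = 1.3
    max_dt: float | None = None
    nx: int | None = None
    nz: int | None = None
    newton_tol: float = 1e-9
    newton_max_iter: int = 25
    n_snapshots: int = 5
    store_history: bool = False

    def __post_init__(self) -> None:
        if self.end_time <= 0:
            raise ValueError("end_time must be positive")
        if not (1.0 < self.growth <= 2.0):
            raise ValueError("growth must be in (1, 2]")

    def resolved_mesh(self, kind: str):
        nx0, nz0 = _DEFAULT_MESH[kind]
        return self.nx or nx0, self.nz or nz0

    def time_grid_params(self, load: RampLoad):
        dt0 = self.dt_init
        if dt0 is None:
            dt0 = load.t_r / 20.0 if load.t_r > 0 else 0.01
        dt_max = self.max_dt if self.max_dt is not None else self.end_time / 30.0
        return dt0, dt_max


@dataclass
class FieldSnapshot:
    """Full-field state at one output time."""

    time: float
    u: np.ndarray  # (n_nodes, 2) displacements, um
    p: np.ndarray  # (n_p,) pore pressure at pressure nodes, kPa
    darcy_flux: np.ndarray  # (n_elem, 2) -k grad p at element centroids, um/s
    boundary: np.ndarray  # deformed boundary polyline (m, 2)


@dataclass
class SolveResult:
    curves: dict
    snapshots: list
    mesh: Mesh
    geom: GeometrySpec
    times: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    u_history: np.ndarray | None = None
    p_history: np.ndarray | None = None

    def probe(self, label: str) -> DisplacementCurve:
        return self.curves[label]


# -- assembly -----------------------------------------------------------------


def _material_of(mat) -> PoroelasticMaterial:
    return mat.bulk if isinstance(mat, LayeredMaterial) else mat


def _element_permeability(geom: GeometrySpec, mesh: Mesh, mat) -> np.ndarray:
    """Per-element Darcy permeability; membrane layer gets the membrane D."""
    bulk = _material_of(mat)
    k = np.full(mesh.n_elems, bulk.k_perm)
    th = 0.0
    if isinstance(mat, LayeredMaterial):
        th = mat.membrane_thickness
    elif geom.membrane_thickness > 0:
        th = geom.membrane_thickness
    if isinstance(mat, LayeredMaterial) and th > 0:
        c = mesh.elem_centroids
        top = geom.surface_height(c[:, 0])
        in_membrane = c[:, 1] > top - th
        k[in_membrane] = mat.membrane.k_perm
    return k


class _LinearOperators:
    """Constant FE matrices of the linear Biot problem."""

    def __init__(self, geom, mesh, mat, basis: ElementBasis):
        self.basis = basis
        bulk = _material_of(mat)
        coords = mesh.nodes[mesh.elems]  # (E, 8, 2)
        detJ, grad8, grad4, r_gp = basis.jacobians(coords)
        if np.any(detJ <= 0):
            raise ValueError("mesh quality check failed: non-positive jacobian")
        w = detJ * basis.gw[None, :] * r_gp  # (E, g) quadrature weight incl. r

        E_, g = mesh.n_elems, basis.gw.size
        # B: strains [e_rr, e_zz, e_tt, g_rz] from 16 local u dofs (a, comp)
        B = np.zeros((E_, g, 4, 8, 2))
        B[:, :, 0, :, 0] = grad8[..., 0]
        B[:, :, 1, :, 1] = grad8[..., 1]
        B[:, :, 2, :, 0] = basis.N8[None, :, :] / r_gp[..., None]
        B[:, :, 3, :, 0] = grad8[..., 1]
        B[:, :, 3, :, 1] = grad8[..., 0]
        B = B.reshape(E_, g, 4, 16)
        self.B = B
        self.w = w
        self.grad4 = grad4
        lam, G = bulk.lam, bulk.G
        Dmat = np.array(
            [
                [lam + 2 * G, lam, lam, 0],
                [lam, lam + 2 * G, lam, 0],
                [lam, lam, lam + 2 * G, 0],
                [0, 0, 0, G],
            ]
        )
        Kel = np.einsum("egim,ij,egjn,eg->emn", B, Dmat, B, w, optimize=True)
        Bvol = B[:, :, 0, :] + B[:, :, 1, :] + B[:, :, 2, :]  # (E, g, 16)
        Qel = np.einsum("egm,gb,eg->emb", Bvol, basis.N4, w, optimize=True)
        k_e = _element_permeability(geom, mesh, mat)
        Hel = np.einsum("e,egai,egbi,eg->eab", k_e, grad4, grad4, w, optimize=True)
        self.k_elem = k_e

        udof = (mesh.elems[:, :, None] * 2 + np.arange(2)[None, None, :]).reshape(E_, 16)
        pdof = mesh.p_index[mesh.elems[:, :4]]  # (E, 4)
        n_u, n_p = 2 * mesh.n_nodes, mesh.n_p

        def coo(el, rows, cols, shape):
            r = np.broadcast_to(rows[:, :, None], el.shape).ravel()
            c = np.broadcast_to(cols[:, None, :], el.shape).ravel()
            return sp.coo_matrix((el.ravel(), (r, c)), shape=shape).tocsr()

        self.K = coo(Kel, udof, udof, (n_u, n_u))
        self.Q = coo(Qel, udof, pdof, (n_u, n_p))
        self.H = coo(Hel, pdof, pdof, (n_p, n_p))
        self.n_u, self.n_p = n_u, n_p


def _edge_load_vector(mesh: Mesh, basis: ElementBasis, n_u: int) -> np.ndarray:
    """Unit-pressure outward normal load over the drained edges.

    Returns ``F`` such that the consistent nodal force for surface
    tension ``P`` is ``P * F`` (axisymmetric, per radian).
    """
    F = np.zeros(n_u)
    for name in ("top", "rim"):
        edges = mesh.edge_sets.get(name)
        if edges is None or edges.size == 0:
            continue
        if name == "rim" and not _rim_is_drained(mesh):
            continue
        sign = 1.0 if name == "top" else -1.0
        xy = mesh.nodes[edges]  # (ne, 3, 2)
        # tangent d(r,z)/ds at edge Gauss points
        tang = np.einsum("ga,nai->ngi", basis.dNl, xy)  # (ne, g, 2)
        r_g = np.einsum("ga,na->ng", basis.Nl, xy[:, :, 0])
        # unnormalized outward normal * arc-length jacobian
        normal = sign * np.stack([-tang[..., 1], tang[..., 0]], axis=-1)
        contrib = np.einsum("ga,ngi,ng,g->nai", basis.Nl, normal, r_g, basis.edge_w)
        np.add.at(F, edges[:, :, None] * 2 + np.arange(2)[None, None, :], contrib)
    return F


def _rim_is_drained(mesh: Mesh) -> bool:
    rim = mesh.node_sets["rim"]
    return np.isin(rim, mesh.node_sets["drained"]).all()


def _dirichlet_dofs(mesh: Mesh, bcs: BoundaryConditionSet, geom: GeometrySpec):
    fixed = [mesh.node_sets["axis"] * 2]  # u_r = 0 on the symmetry axis
    bottom = mesh.node_sets["bottom"]
    fixed.append(bottom * 2 + 1)  # u_z = 0 on the substrate
    if bcs.bottom_mech == "no_slip":
        fixed.append(bottom * 2)
    if geom.kind == "column1d":
        fixed.append(mesh.node_sets["rim"] * 2)  # lateral confinement
    fixed_u = np.unique(np.concatenate(fixed))
    drained_p = np.unique(mesh.p_index[mesh.node_sets["drained"]])
    drained_p = drained_p[drained_p >= 0]
    return fixed_u, drained_p


def _time_steps(load: RampLoad, cfg: SolverConfig):
    dt0, dt_max = cfg.time_grid_params(load)
    times = [0.0]
    dt = dt0
    t = 0.0
    while t < cfg.end_time - 1e-12:
        step = min(dt, cfg.end_time - t)
        if load.t_r > 0 and t < load.t_r - 1e-12 and t + step > load.t_r:
            step = load.t_r - t  # land exactly on the end of the ramp
        t += step
        times.append(t)
        if cfg.adaptive:
            dt = min(dt * cfg.growth, dt_max)
    return np.asarray(times)


def _snapshot(ops, mesh, basis, t, u, p) -> FieldSnapshot:
    gradp = np.einsum(
        "egai,ea->egi", ops.grad4, p[mesh.p_index[mesh.elems[:, :4]]]
    ).mean(axis=1)
    flux = -ops.k_elem[:, None] * gradp
    order = _boundary_order(mesh)
    boundary = mesh.nodes[order] + u.reshape(-1, 2)[order]
    return FieldSnapshot(time=t, u=u.reshape(-1, 2).copy(), p=p.copy(),
                         darcy_flux=flux, boundary=boundary)


def _boundary_order(mesh: Mesh) -> np.ndarray:
    """Boundary nodes ordered bottom (axis->rim), rim (up), top (rim->axis)."""
    nodes = mesh.nodes
    bottom = mesh.node_sets["bottom"][np.argsort(nodes[mesh.node_sets["bottom"], 0])]
    rim = mesh.node_sets["rim"][np.argsort(nodes[mesh.node_sets["rim"], 1])]
    top = mesh.node_sets["top"][np.argsort(-nodes[mesh.node_sets["top"], 0])]
    return np.concatenate([bottom, rim[1:], top[1:]])


def solve_linear_biot(
    geom: GeometrySpec,
    mat,
    bcs: BoundaryConditionSet,
    load: RampLoad,
    cfg: SolverConfig | None = None,
) -> SolveResult:
    """Transient linear Biot solve; returns probe curves and field snapshots."""
    cfg = cfg or SolverConfig()
    nx, nz = cfg.resolved_mesh(geom.kind)
    mesh = build_mesh(geom, nx, nz)
    basis = ElementBasis()
    ops = _LinearOperators(geom, mesh, mat, basis)
    fixed_u, drained_p = _dirichlet_dofs(mesh, bcs, geom)
    F_unit = np.zeros(ops.n_u)
    if bcs.drained_traction == "match_pressure":
        F_unit = _edge_load_vector(mesh, basis, ops.n_u)

    times = _time_steps(load, cfg)
    n_u, n_p = ops.n_u, ops.n_p
    free_u = np.setdiff1d(np.arange(n_u), fixed_u)
    free_p = np.setdiff1d(np.arange(n_p), drained_p)

    probes = locate_probes(geom, mesh)
    from .fem import q8_shape

    probe_N = {lbl: (el, q8_shape(np.array([[xi, eta]]))[0][0]) for lbl, el, xi, eta in probes}

    u = np.zeros(n_u)
    p = np.zeros(n_p)
    traces = {lbl: [0.0] for lbl in probe_N}
    snap_times = np.linspace(0, cfg.end_time, cfg.n_snapshots + 1)[1:]
    snapshots = [_snapshot(ops, mesh, basis, 0.0, u, p)]
    next_snap = 0
    u_hist = [u.copy()] if cfg.store_history else None
    p_hist = [p.copy()] if cfg.store_history else None

    # block system: [K, -Q; Q^T, dt H]; Dirichlet handled by elimination
    K, Q, H = ops.K, ops.Q, ops.H
    last_dt = None
    lu = None
    for n in range(1, times.size):
        t_new = times[n]
        dt = t_new - times[n - 1]
        P_now = float(load.pressure_at(t_new))
        if last_dt is None or abs(dt - last_dt) > 1e-14:
            A = sp.bmat([[K, -Q], [Q.T, dt * H]], format="csr")
            idx = np.concatenate([free_u, n_u + free_p])
            A_ff = A[idx][:, idx].tocsc()
            A_fc = A[idx][:, np.concatenate([fixed_u, n_u + drained_p])].tocsc()
            lu = spla.splu(A_ff)
            last_dt = dt

        rhs = np.concatenate([P_now * F_unit, Q.T @ u])
        xc = np.concatenate([np.zeros(fixed_u.size), np.full(drained_p.size, P_now)])
        b = rhs[np.concatenate([free_u, n_u + free_p])] - A_fc @ xc
        x = lu.solve(b)
        u_new = np.zeros(n_u)
        p_new = np.zeros(n_p)
        u_new[free_u] = x[: free_u.size]
        p_new[free_p] = x[free_u.size:]
        p_new[drained_p] = P_now
        u, p = u_new, p_new

        uz_elems = u.reshape(-1, 2)[mesh.elems, 1]  # (E, 8)
        for lbl, (el, N) in probe_N.items():
            traces[lbl].append(float(N @ uz_elems[el]))
        if cfg.store_history:
            u_hist.append(u.copy())
            p_hist.append(p.copy())
        if next_snap < snap_times.size and t_new >= snap_times[next_snap] - 1e-9:
            snapshots.append(_snapshot(ops, mesh, basis, t_new, u, p))
            while next_snap < snap_times.size and snap_times[next_snap] <= t_new + 1e-9:
                next_snap += 1

    curves = {}
    meta_base = {
        "model": "linear_biot",
        "geometry": geom.kind,
        "H_um": geom.H,
        "R_um": geom.R,
        "E_kPa": _material_of(mat).E,
        "nu": _material_of(mat).nu,
        "D_um2_s": _material_of(mat).D,
        "P_eff_kPa": load.P_eff,
        "t_r_s": load.t_r,
        "bottom_mech": bcs.bottom_mech,
        "drained_traction": bcs.drained_traction,
        "nx": nx,
        "nz": nz,
    }
    for lbl in probe_N:
        delta = np.asarray(traces[lbl])
        curves[lbl] = DisplacementCurve(
            times, delta, delta_inf=float(delta[-1]),
            meta=dict(meta_base, probe=lbl),
        )
    plateaued = {
        lbl: abs(c.delta[-1] - c.delta[-2]) <= 1e-4 * max(abs(c.delta[-1]), 1e-12)
        for lbl, c in curves.items()
    }
    return SolveResult(
        curves=curves,
        snapshots=snapshots,
        mesh=mesh,
        geom=geom,
        times=times,
        diagnostics={"plateaued": plateaued, "n_steps": times.size - 1},
        u_history=np.asarray(u_hist) if cfg.store_history else None,
        p_history=np.asarray(p_hist) if cfg.store_history else None,
    )
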