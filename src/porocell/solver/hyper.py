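"""Finite-strain neo-Hookean porohyperelasticity (axisymmetric).

Total-Lagrangian kinematics with the balance laws evaluated on the
deformed configuration; incompressible constituents, so the fluid content
added per unit reference volume is ``J - 1`` and mass balance reads
``dJ/dt = Div(J F^-1 q)`` with spatial Darcy flux ``q = -k grad_x p``.

Constitutive model (compressible neo-Hookean, volumetric/deviatoric
split):

    sigma' = (2 C10 / J) dev(b_bar) + (2 / D1) (J - 1) I,   b_bar = J^(-2/3) F F^T

with ``C10 = G/2`` and ``D1 = 2 / K_bulk`` derived from the drained
``(E, nu)`` so the small-strain limit recovers linear elasticity exactly.
Total stress ``sigma = sigma' - p I``.  Backward-Euler in time; Newton
iterations with a finite-difference consistent tangent assembled
element-wise (all elements and all dof perturbations evaluated in one
vectorized batch).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..curves import DisplacementCurve
from ..materials import LayeredMaterial, PoroelasticMaterial, RampLoad
from .biot import (
    ConvergenceError,
    SolveResult,
    SolverConfig,
    FieldSnapshot,
    _boundary_order,
    _dirichlet_dofs,
    _material_of,
    _time_steps,
)
from .fem import ElementBasis, q8_shape
from .geometry import BoundaryConditionSet, GeometrySpec, build_mesh, locate_probes

__all__ = ["solve_porohyperelastic"]

_EPS_FD = 1e-6  # finite-difference step for the consistent tangent (um / kPa)


class _HyperModel:
    """Vectorized residual machinery; leading batch axis for FD tangents."""

    def __init__(self, geom, mesh, mat: PoroelasticMaterial, bcs, basis: ElementBasis):
        if isinstance(mat, LayeredMaterial):
            raise NotImplementedError("layered materials are supported by the linear solver only")
        self.mesh = mesh
        self.basis = basis
        self.mat = mat
        self.bcs = bcs
        self.X = mesh.nodes[mesh.elems]  # (E, 8, 2)
        detJ0, grad8_0, _, r0 = basis.jacobians(self.X)
        if np.any(detJ0 <= 0):
            raise ValueError("mesh quality check failed: non-positive jacobian")
        self.detJ0, self.grad8_0, self.r0 = detJ0, grad8_0, r0
        self.w0 = detJ0 * basis.gw[None, :] * r0
        self.pdof = mesh.p_index[mesh.elems[:, :4]]
        self.udof = (mesh.elems[:, :, None] * 2 + np.arange(2)).reshape(mesh.n_elems, 16)
        self.k = mat.k_perm
        # drained edges for the follower load
        self.edges = []
        if bcs.drained_traction == "match_pressure":
            for name, sign in (("top", 1.0), ("rim", -1.0)):
                edges = mesh.edge_sets.get(name)
                if edges is None or edges.size == 0:
                    continue
                if name == "rim" and not np.isin(
                    mesh.node_sets["rim"], mesh.node_sets["drained"]
                ).all():
                    continue
                self.edges.append((edges, sign))

    # -- kinematics + constitutive --------------------------------------------

    def _stress(self, F2d, Ftt, J, p_gp):
        """Cauchy stress components (rr, zz, tt, rz) from deformation state."""
        C10, D1v = self.mat.C10, self.mat.D1_vol
        b_rr = F2d[..., 0, 0] ** 2 + F2d[..., 0, 1] ** 2
        b_zz = F2d[..., 1, 0] ** 2 + F2d[..., 1, 1] ** 2
        b_rz = F2d[..., 0, 0] * F2d[..., 1, 0] + F2d[..., 0, 1] * F2d[..., 1, 1]
        b_tt = Ftt**2
        Jm23 = J ** (-2.0 / 3.0)
        tr_bar = Jm23 * (b_rr + b_zz + b_tt)
        c = 2.0 * C10 / J
        s_vol = (2.0 / D1v) * (J - 1.0)
        s_rr = c * (Jm23 * b_rr - tr_bar / 3.0) + s_vol - p_gp
        s_zz = c * (Jm23 * b_zz - tr_bar / 3.0) + s_vol - p_gp
        s_tt = c * (Jm23 * b_tt - tr_bar / 3.0) + s_vol - p_gp
        s_rz = c * Jm23 * b_rz
        return s_rr, s_zz, s_tt, s_rz

    def residual(self, u_loc, p_loc, J_old, dt, P_now):
        """Element residuals.

        ``u_loc``: (..., E, 8, 2); ``p_loc``: (..., E, 4); returns
        (..., E, 20) ordered as 16 u-dofs then 4 p-dofs.
        """
        basis, mesh = self.basis, self.mesh
        x = self.X + u_loc  # deformed coordinates
        detJx, gradx8, gradx4, rx = basis.jacobians(x)
        wx = detJx * basis.gw * rx

        # deformation gradient: F_ij = d x_i / d X_j
        F2d = np.einsum("egaj,...eai->...egij", self.grad8_0, x)
        Ftt = rx / self.r0
        J = (F2d[..., 0, 0] * F2d[..., 1, 1] - F2d[..., 0, 1] * F2d[..., 1, 0]) * Ftt

        p_gp = np.einsum("ga,...ea->...eg", basis.N4, p_loc)
        # inverted elements (J <= 0) poison the residual with NaN so the
        # stepper rejects the iterate and retries with a smaller dt
        J = np.where(J > 0, J, np.nan)
        s_rr, s_zz, s_tt, s_rz = self._stress(F2d, Ftt, J, p_gp)

        N8_over_r = basis.N8[:, :] / rx[..., None]
        Ru = np.empty(u_loc.shape)
        Ru[..., 0] = np.einsum(
            "...eg,...ega->...ea", s_rr * wx, gradx8[..., 0]
        ) + np.einsum("...eg,...ega->...ea", s_rz * wx, gradx8[..., 1]) + np.einsum(
            "...eg,...ega->...ea", s_tt * wx, N8_over_r
        )
        Ru[..., 1] = np.einsum(
            "...eg,...ega->...ea", s_rz * wx, gradx8[..., 0]
        ) + np.einsum("...eg,...ega->...ea", s_zz * wx, gradx8[..., 1])

        # mass balance: (J - J_old)/dt on reference volume + Darcy on deformed
        gradp = np.einsum("...egai,...ea->...egi", gradx4, p_loc)
        Rp = np.einsum("...eg,ga->...ea", (J - J_old) / dt * self.w0, basis.N4)
        Rp += self.k * np.einsum("...egi,...egai,...eg->...ea", gradp, gradx4, wx)

        return np.concatenate([Ru.reshape(Ru.shape[:-2] + (16,)), Rp], axis=-1)

    def edge_residual(self, ue_loc, edges, sign, P_now):
        """Follower-pressure load residual on deformed drained edges.

        ``ue_loc``: (..., ne, 3, 2).  Returns (..., ne, 3, 2) nodal forces
        (to be subtracted from the internal residual).
        """
        basis = self.basis
        xe = self.mesh.nodes[edges] + ue_loc
        tang = np.einsum("ga,...nai->...ngi", basis.dNl, xe)
        r_g = np.einsum("ga,...na->...ng", basis.Nl, xe[..., 0])
        normal = sign * np.stack([-tang[..., 1], tang[..., 0]], axis=-1)
        return P_now * np.einsum(
            "ga,...ngi,...ng,g->...nai", basis.Nl, normal, r_g, basis.edge_w
        )

    def compute_J(self, u_loc):
        x = self.X + u_loc
        F2d = np.einsum("egaj,eai->egij", self.grad8_0, x)
        rx = np.einsum("ga,ea->eg", self.basis.N8, x[..., 0])
        return (F2d[..., 0, 0] * F2d[..., 1, 1] - F2d[..., 0, 1] * F2d[..., 1, 0]) * (
            rx / self.r0
        )


def _assemble_system(model, u, p, J_old, dt, P_now, n_u, n_p):
    """Residual vector and FD-consistent tangent as sparse CSR."""
    mesh = model.mesh
    u_loc = u.reshape(-1, 2)[mesh.elems]  # (E, 8, 2)
    p_loc = p[model.pdof]

    base = model.residual(u_loc, p_loc, J_old, dt, P_now)  # (E, 20)

    # batched perturbations: 20 local dofs
    B = 20
    u_b = np.broadcast_to(u_loc, (B,) + u_loc.shape).copy()
    p_b = np.broadcast_to(p_loc, (B,) + p_loc.shape).copy()
    for j in range(16):
        u_b[j, :, j // 2, j % 2] += _EPS_FD
    for j in range(4):
        p_b[16 + j, :, j] += _EPS_FD
    pert = model.residual(u_b, p_b, J_old, dt, P_now)  # (20, E, 20)
    Kel = (pert - base[None]) / _EPS_FD  # (20_j, E, 20_i): dR_i/dU_j
    Kel = np.moveaxis(Kel, 0, 2)  # (E, 20_i, 20_j)

    ldof = np.concatenate([model.udof, model.pdof + n_u], axis=1)  # (E, 20)
    R = np.zeros(n_u + n_p)
    np.add.at(R, ldof, base)
    rows = np.repeat(ldof[:, :, None], 20, axis=2)
    cols = np.repeat(ldof[:, None, :], 20, axis=1)
    K = sp.coo_matrix(
        (Kel.ravel(), (rows.ravel(), cols.ravel())), shape=(n_u + n_p, n_u + n_p)
    ).tocsr()

    # follower surface load and its tangent
    for edges, sign in model.edges:
        ue = u.reshape(-1, 2)[edges]
        base_e = model.edge_residual(ue, edges, sign, P_now)  # (ne, 3, 2)
        Be = 6
        ue_b = np.broadcast_to(ue, (Be,) + ue.shape).copy()
        for j in range(6):
            ue_b[j, :, j // 2, j % 2] += _EPS_FD
        pert_e = model.edge_residual(ue_b, edges, sign, P_now)
        Kedge = (pert_e - base_e[None]) / _EPS_FD  # (6_j, ne, 3, 2)
        Kedge = np.moveaxis(Kedge.reshape(6, -1, 6), 0, 2)  # (ne, 6_i, 6_j)
        edof = (edges[:, :, None] * 2 + np.arange(2)).reshape(-1, 6)
        np.add.at(R, edof, -base_e.reshape(-1, 6))
        er = np.repeat(edof[:, :, None], 6, axis=2)
        ec = np.repeat(edof[:, None, :], 6, axis=1)
        K -= sp.coo_matrix(
            (Kedge.ravel(), (er.ravel(), ec.ravel())), shape=(n_u + n_p, n_u + n_p)
        ).tocsr()
    return R, K


def solve_porohyperelastic(
    geom: GeometrySpec,
    mat: PoroelasticMaterial,
    bcs: BoundaryConditionSet,
    load: RampLoad,
    cfg: SolverConfig | None = None,
) -> SolveResult:
    """Transient finite-strain porohyperelastic solve.

    For loads producing small strains (|P_eff| H / M below a couple of
    percent) the probe traces agree with :func:`solve_linear_biot` to
    within ~2%; at cell-scale loads the geometric and constitutive
    nonlinearity stiffens the response and breaks the swelling/deswelling
    mirror symmetry of the linear model.
    """
    cfg = cfg or SolverConfig(constitutive="neo_hookean")
    nx, nz = cfg.resolved_mesh(geom.kind)
    mesh = build_mesh(geom, nx, nz)
    basis = ElementBasis()
    model = _HyperModel(geom, mesh, _material_of(mat), bcs, basis)
    fixed_u, drained_p = _dirichlet_dofs(mesh, bcs, geom)

    n_u, n_p = 2 * mesh.n_nodes, mesh.n_p
    free = np.setdiff1d(np.arange(n_u + n_p), np.concatenate([fixed_u, n_u + drained_p]))

    probes = locate_probes(geom, mesh)
    probe_N = {lbl: (el, q8_shape(np.array([[xi, eta]]))[0][0]) for lbl, el, xi, eta in probes}

    u = np.zeros(n_u)
    p = np.zeros(n_p)
    J_old = np.ones((mesh.n_elems, basis.gw.size))
    # residual scale: applied load if present, else a small fraction of the
    # elastic force scale (keeps the zero-load case from chasing roundoff)
    mat0 = _material_of(mat)
    force_scale = max(abs(load.P_eff), 1e-3 * mat0.E) * geom.R * geom.H
    tol = max(cfg.newton_tol, 1e-10) * force_scale

    times = _time_steps(load, cfg)
    traces = {lbl: [0.0] for lbl in probe_N}
    out_times = [0.0]
    snap_times = np.linspace(0, cfg.end_time, cfg.n_snapshots + 1)[1:]
    snapshots = [_hyper_snapshot(model, mesh, basis, 0.0, u, p)]
    next_snap = 0
    u_hist = [u.copy()] if cfg.store_history else None
    p_hist = [p.copy()] if cfg.store_history else None

    t = 0.0
    i_step = 1
    dt_next = None
    n_newton_total = 0
    while i_step < times.size:
        dt = (times[i_step] - t) if dt_next is None else dt_next
        t_new = t + dt
        P_now = float(load.pressure_at(t_new))
        # predictor: previous state; drained pressure set to current ramp value
        u_try, p_try = u.copy(), p.copy()
        p_try[drained_p] = P_now
        ok = False
        res_norm = np.inf
        for it in range(cfg.newton_max_iter):
            R, K = _assemble_system(model, u_try, p_try, J_old, dt, P_now, n_u, n_p)
            if not np.all(np.isfinite(R)):
                break  # inverted element during iteration: retry smaller dt
            res_norm = np.linalg.norm(R[free], ord=np.inf)
            if res_norm < tol:
                ok = True
                n_newton_total += it
                break
            K_ff = K[free][:, free].tocsc()
            dx = spla.spsolve(K_ff, -R[free])
            if not np.all(np.isfinite(dx)):
                break
            u_try_flat = np.concatenate([u_try, p_try])
            u_try_flat[free] += dx
            u_try, p_try = u_try_flat[:n_u], u_try_flat[n_u:]
            if np.max(np.abs(dx)) < 1e-12 * max(geom.H, 1.0):
                ok = True  # stagnated at machine precision: accept
                n_newton_total += it + 1
                break
        if not ok:
            dt_next = dt / 2.0
            if dt_next < 1e-7:
                raise ConvergenceError(
                    f"Newton failed to converge at t={t_new:.4g}s "
                    f"(last residual {res_norm:.3g}, dt={dt:.3g})"
                )
            continue
        # accepted
        u, p, t = u_try, p_try, t_new
        J_old = model.compute_J(u.reshape(-1, 2)[mesh.elems])
        if np.any(J_old <= 0):
            raise ConvergenceError(f"element inversion (J <= 0) at t={t:.4g}s")
        uz_elems = u.reshape(-1, 2)[mesh.elems, 1]
        for lbl, (el, N) in probe_N.items():
            traces[lbl].append(float(N @ uz_elems[el]))
        out_times.append(t)
        if cfg.store_history:
            u_hist.append(u.copy())
            p_hist.append(p.copy())
        if next_snap < snap_times.size and t >= snap_times[next_snap] - 1e-9:
            snapshots.append(_hyper_snapshot(model, mesh, basis, t, u, p))
            while next_snap < snap_times.size and snap_times[next_snap] <= t + 1e-9:
                next_snap += 1
        dt_next = None
        while i_step < times.size and times[i_step] <= t + 1e-12:
            i_step += 1

    out_times = np.asarray(out_times)
    curves = {}
    meta_base = {
        "model": "porohyperelastic_neo_hookean",
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
            out_times, delta, delta_inf=float(delta[-1]), meta=dict(meta_base, probe=lbl)
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
        times=out_times,
        diagnostics={"plateaued": plateaued, "n_steps": out_times.size - 1,
                     "newton_iterations": n_newton_total},
        u_history=np.asarray(u_hist) if cfg.store_history else None,
        p_history=np.asarray(p_hist) if cfg.store_history else None,
    )


def _hyper_snapshot(model, mesh, basis, t, u, p) -> FieldSnapshot:
    u2 = u.reshape(-1, 2)
    x = model.X + u2[mesh.elems]
    _, _, gradx4, _ = basis.jacobians(x)
    gradp = np.einsum("egai,ea->egi", gradx4, p[model.pdof]).mean(axis=1)
    flux = -model.k * gradp
    order = _boundary_order(mesh)
    return FieldSnapshot(time=t, u=u2.copy(), p=p.copy(), darcy_flux=flux,
                         boundary=mesh.nodes[order] + u2[order])
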