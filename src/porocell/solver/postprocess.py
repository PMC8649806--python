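"""Post-processing of transient solves: plateau times, curve collapse,
mesh convergence, and mass-balance verification."""

from __future__ import annotations

import numpy as np

from ..curves import DisplacementCurve, NotPlateaued, time_to_plateau
from ..analytic import tau_figure_normalization
from ..materials import PoroelasticMaterial

__all__ = [
    "collapse_check",
    "mesh_convergence_study",
    "mass_balance_report",
    "time_to_plateau",
    "NotPlateaued",
]


def collapse_check(curves, collapse_tol: float = 0.02):
    """Maximum pairwise sup-norm distance between normalized curves.

    Each curve is rescaled to ``delta/delta_inf`` against the dimensionless
    time ``4 D t / (pi H^2)``; the material ``D`` and thickness ``H`` are
    taken from each curve's metadata (keys ``D_um2_s`` and ``H_um``).
    Curves overlay ("collapse") when every pairwise sup-norm distance on
    the common dimensionless-time window is below ``collapse_tol``.

    Returns ``(max_distance, collapsed)``.
    """
    if len(curves) < 2:
        return 0.0, True
    normed = []
    for c in curves:
        D = c.meta["D_um2_s"]
        H = c.meta["H_um"]
        mat = PoroelasticMaterial(E=1.0, nu=0.0, D=D)
        tau = tau_figure_normalization(c.t, mat, H)
        scale = c.delta_inf if c.delta_inf is not None else c.delta[-1]
        if scale == 0:
            raise ValueError("cannot normalize a curve with zero plateau")
        normed.append((tau, c.delta / scale))
    lo = max(t[0] for t, _ in normed)
    hi = min(t[-1] for t, _ in normed)
    grid = np.linspace(lo, hi, 400)
    vals = np.stack([np.interp(grid, t, y) for t, y in normed])
    dist = 0.0
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            dist = max(dist, float(np.max(np.abs(vals[i] - vals[j]))))
    return dist, dist < collapse_tol


def mesh_convergence_study(geom, mat, bcs, load, cfg, levels: int = 3, probe: str = "P1"):
    """Successive uniform refinements; reports plateau displacement per level.

    Returns a list of dicts with mesh size, plateau, and the relative
    change from the previous level; ``converged`` is true when the last
    change is below 0.1%.  Non-monotone divergence (changes growing) is
    flagged.
    """
    from .biot import SolverConfig, solve_linear_biot
    from .hyper import solve_porohyperelastic
    from dataclasses import replace

    if levels < 2:
        raise ValueError("need at least 2 refinement levels")
    nx0, nz0 = cfg.resolved_mesh(geom.kind)
    rows = []
    prev = None
    for lvl in range(levels):
        f = 2**lvl
        cfg_l = replace(cfg, nx=nx0 * f, nz=nz0 * f)
        solve = (
            solve_porohyperelastic if cfg.constitutive == "neo_hookean" else solve_linear_biot
        )
        res = solve(geom, mat, bcs, load, cfg_l)
        d = float(res.probe(probe).delta[-1])
        change = abs(d - prev) / max(abs(d), 1e-300) if prev is not None else None
        rows.append(
            {"level": lvl, "nx": nx0 * f, "nz": nz0 * f, "n_elems": res.mesh.n_elems,
             "delta_inf": d, "rel_change": change}
        )
        prev = d
    changes = [r["rel_change"] for r in rows[1:]]
    diverging = len(changes) >= 2 and changes[-1] > changes[-2] > 0.005
    return {
        "table": rows,
        "converged": changes[-1] < 1e-3,
        "diverging": bool(diverging),
    }


def mass_balance_report(result) -> dict:
    """Fluid mass conservation check for a (linear) transient solve.

    Compares the domain volume change computed from the displacement field
    (integral of the small-strain dilatation) against the time-integrated
    Darcy influx through the whole boundary, both per radian of
    revolution.  Requires the solve to have been run with
    ``store_history=True``.  Returns the two time series and their
    relative mismatch (normalized by the final volume change).
    """
    from .fem import ElementBasis, line3_shape

    if result.u_history is None:
        raise ValueError("run the solver with store_history=True for a mass balance check")
    mesh = result.mesh
    basis = ElementBasis()
    coords = mesh.nodes[mesh.elems]
    detJ, grad8, grad4, r_gp = basis.jacobians(coords)
    w = detJ * basis.gw[None, :] * r_gp

    # volume change from dilatation: int (e_rr + e_zz + e_tt) r dOmega
    u_hist = result.u_history  # (T, n_u)
    T = u_hist.shape[0]
    u_loc = u_hist.reshape(T, -1, 2)[:, mesh.elems]  # (T, E, 8, 2)
    dil = (
        np.einsum("ega,tea->teg", grad8[..., 0], u_loc[..., 0])
        + np.einsum("ega,tea->teg", grad8[..., 1], u_loc[..., 1])
        + np.einsum("ga,eg,tea->teg", basis.N8, 1.0 / r_gp, u_loc[..., 0])
    )
    dV = np.einsum("teg,eg->t", dil, w)

    # Darcy influx through all boundary edges: int k grad p . n dGamma
    from .biot import _element_permeability

    p_hist = result.p_history  # (T, n_p)
    influx = np.zeros(T)
    # evaluate grad p on boundary edges via the owning element's basis
    for name, sign, owner in _boundary_edge_owners(mesh):
        xy = mesh.nodes[mesh.edge_sets[name]]
        tang = np.einsum("ga,nai->ngi", basis.dNl, xy)
        r_g = np.einsum("ga,na->ng", basis.Nl, xy[:, :, 0])
        normal = sign * np.stack([-tang[..., 1], tang[..., 0]], axis=-1)  # outward * |J|
        # local coords of edge gauss points inside the owning element
        loc = _edge_gauss_local(name, basis.edge_s)
        from .fem import q4_shape

        _, dN4 = q4_shape(loc)
        # jacobian of owning elements at those points
        from .fem import q8_shape

        _, dN8 = q8_shape(loc)
        cown = mesh.nodes[mesh.elems[owner]]
        J = np.einsum("gak,nai->ngik", dN8, cown)
        det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        invJ = np.empty_like(J)
        invJ[..., 0, 0] = J[..., 1, 1]
        invJ[..., 1, 1] = J[..., 0, 0]
        invJ[..., 0, 1] = -J[..., 0, 1]
        invJ[..., 1, 0] = -J[..., 1, 0]
        invJ /= det[..., None, None]
        g4 = np.einsum("gak,ngki->ngai", dN4, invJ)
        k_e = _element_permeability(result.geom, mesh, _geom_mat(result))[owner]
        p_loc = p_hist[:, mesh.p_index[mesh.elems[owner][:, :4]]]  # (T, n, 4)
        gradp = np.einsum("ngai,tna->tngi", g4, p_loc)
        influx += np.einsum(
            "tngi,ngi,ng,g,n->t", gradp, normal, r_g, basis.edge_w, k_e
        )

    dt = np.diff(result.times)
    cum_in = np.concatenate([[0.0], np.cumsum(influx[1:] * dt)])  # backward Euler flux
    scale = max(abs(dV[-1]), 1e-300)
    mismatch = np.abs(dV - cum_in) / scale
    return {
        "volume_change": dV,
        "cumulative_influx": cum_in,
        "relative_mismatch": mismatch,
        "max_relative_mismatch": float(mismatch.max()),
    }


def _geom_mat(result):
    from ..materials import PoroelasticMaterial

    m = result.curves["P1"].meta
    return PoroelasticMaterial(E=m["E_kPa"], nu=m["nu"], D=m["D_um2_s"])


def _boundary_edge_owners(mesh):
    """(edge set name, outward sign, owning element ids) per boundary."""
    nx, nz = mesh.nx, mesh.nz
    top_owner = np.array([i * nz + (nz - 1) for i in range(nx)])
    bot_owner = np.array([i * nz for i in range(nx)])
    rim_owner = np.array([(nx - 1) * nz + j for j in range(nz)])
    return [("top", 1.0, top_owner), ("bottom", -1.0, bot_owner), ("rim", -1.0, rim_owner)]


def _edge_gauss_local(name, s):
    """Element-local (xi, eta) coordinates of edge Gauss points."""
    if name == "top":
        return np.column_stack([s, np.ones_like(s)])
    if name == "bottom":
        return np.column_stack([s, -np.ones_like(s)])
    return np.column_stack([np.ones_like(s), s])  # rim
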