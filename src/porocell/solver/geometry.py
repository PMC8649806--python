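"""Axisymmetric geometries, meshing, and boundary-condition descriptions.

Three geometries are supported, all axisymmetric about r = 0:

``disk``
    A thin cylinder (cell idealized as a pancake) of thickness ``H`` and
    radius ``R`` sitting on a substrate.  Drained surfaces: top and the
    lateral wall.
``cell_cap``
    An elliptical cap ``z(r) = H sqrt(1 - (r/R)^2)`` (adherent-cell
    profile).  Drained surface: the curved membrane.  The mesh truncates
    the contact line at a small rim height to keep elements well shaped.
``column1d``
    A laterally confined column (zero radial displacement and no radial
    flow on the outer wall) drained only through the top: the geometry
    whose exact response is the 1D consolidation series, used as the
    solver's analytic oracle.

Meshes are structured grids of 8-node serendipity quadrilaterals
(quadratic displacements) with bilinear pressure on the corner nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometrySpec", "BoundaryConditionSet", "Mesh", "build_mesh"]

_DEFAULT_PROBES = {
    # disk probes on the top surface at r = 0, R/2, 0.9 R
    "disk": lambda H, R: [("P1", 0.0, H), ("P2", 0.5 * R, H), ("P3", 0.9 * R, H)],
    # cap probes on the curved surface at heights 5.5, 4, 2.5 (scaled to H)
    "cell_cap": lambda H, R: [
        ("P1", 0.0, H),
        ("P2", R * np.sqrt(max(0.0, 1 - (4.0 / 5.5) ** 2)), H * 4.0 / 5.5),
        ("P3", R * np.sqrt(max(0.0, 1 - (2.5 / 5.5) ** 2)), H * 2.5 / 5.5),
    ],
    "column1d": lambda H, R: [("P1", 0.0, H)],
}


@dataclass(frozen=True)
class GeometrySpec:
    """Axisymmetric domain: kind, apex height/thickness H, radius R (um)."""

    kind: str = "disk"
    H: float = 5.5
    R: float = 15.0
    membrane_thickness: float = 0.0  # um; 0 = single layer
    probe_points: tuple = ()  # ((label, r, z), ...); default set per kind
    rim_height: float = 0.35  # um; cell_cap contact-line truncation height

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "cell_cap", "column1d"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.H <= 0 or self.R <= 0:
            raise ValueError("H and R must be positive")
        if not self.probe_points:
            object.__setattr__(
                self,
                "probe_points",
                tuple(_DEFAULT_PROBES[self.kind](self.H, self.R)),
            )
        for label, r, z in self.probe_points:
            if not (0 <= r <= self.R) or not (0 <= z <= self.H):
                raise ValueError(f"probe {label} at (r={r}, z={z}) outside domain")

    def surface_height(self, r) -> np.ndarray:
        """Top-surface height above the substrate at radius r."""
        r = np.asarray(r, dtype=float)
        if self.kind == "cell_cap":
            return self.H * np.sqrt(np.clip(1.0 - (r / self.R) ** 2, 0.0, None))
        return np.full_like(r, self.H)


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Per-surface conditions.

    ``bottom_mech``: ``no_slip`` (constrained swelling, u = 0) or
    ``free_slip`` (free swelling, u_z = 0 only).  The bottom is always
    impermeable.  Drained surfaces (set by the geometry kind) carry a
    prescribed boundary pore pressure following the active ramp load and
    are mechanically traction-free when ``drained_traction="none"``; with
    ``drained_traction="match_pressure"`` they additionally carry an
    outward normal surface tension equal to the instantaneous effective
    pressure, i.e. the osmotic imbalance both sets the boundary pore
    pressure and pushes/pulls on the boundary itself.
    """

    bottom_mech: str = "no_slip"
    drained_traction: str = "match_pressure"

    def __post_init__(self) -> None:
        if self.bottom_mech not in ("no_slip", "free_slip"):
            raise ValueError(f"bottom_mech must be no_slip|free_slip, got {self.bottom_mech!r}")
        if self.drained_traction not in ("none", "match_pressure"):
            raise ValueError(
                f"drained_traction must be none|match_pressure, got {self.drained_traction!r}"
            )


@dataclass
class Mesh:
    """Structured Q8/Q4 axisymmetric mesh.

    ``nodes``: (n_node, 2) r-z coordinates.  ``elems``: (n_elem, 8)
    serendipity connectivity (corners 0-3 counter-clockwise from
    bottom-left, then midsides bottom/right/top/left).  ``corner_ids``
    maps each element's 4 corners into the pressure numbering
    (``p_nodes`` lists the node ids that carry a pressure dof).
    """

    nodes: np.ndarray
    elems: np.ndarray
    p_nodes: np.ndarray  # node ids carrying a pressure dof (element corners)
    p_index: np.ndarray  # node id -> pressure dof (or -1)
    node_sets: dict  # name -> node id array: bottom, axis, top, rim, drained
    edge_sets: dict  # name -> (n_edge, 3) node triples on that boundary
    nx: int
    nz: int
    xi_corners: np.ndarray = None  # radial corner parameters in [0, xi_max]
    eta_corners: np.ndarray = None  # vertical corner parameters in [0, 1]
    elem_centroids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.elem_centroids = self.nodes[self.elems[:, :4]].mean(axis=1)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def n_p(self) -> int:
        return self.p_nodes.size


def _graded_params(n: int, grade: float) -> np.ndarray:
    """Corner parameters on [0, 1], clustered toward 1 for grade > 1."""
    s = np.linspace(0.0, 1.0, n + 1)
    return 1.0 - (1.0 - s) ** grade


def build_mesh(geom: GeometrySpec, nx: int, nz: int) -> Mesh:
    """Structured mesh of ``nx`` x ``nz`` Q8 elements on the mapped domain."""
    if nx < 1 or nz < 1:
        raise ValueError("need at least one element per direction")

    if geom.kind == "cell_cap":
        # truncate the contact line where the cap height reaches rim_height
        rim_frac = min(geom.rim_height / geom.H, 0.5)
        xi_max = float(np.sqrt(1.0 - rim_frac**2))
        xi_c = xi_max * _graded_params(nx, 1.6)
    else:
        xi_max = 1.0
        xi_c = _graded_params(nx, 1.0)
    eta_c = np.linspace(0.0, 1.0, nz + 1)

    # full parameter grids including midside positions (parameter midpoints)
    xi_g = np.empty(2 * nx + 1)
    xi_g[::2] = xi_c
    xi_g[1::2] = 0.5 * (xi_c[:-1] + xi_c[1:])
    eta_g = np.empty(2 * nz + 1)
    eta_g[::2] = eta_c
    eta_g[1::2] = 0.5 * (eta_c[:-1] + eta_c[1:])

    n_i, n_j = 2 * nx + 1, 2 * nz + 1
    node_id = -np.ones((n_i, n_j), dtype=int)
    coords = []
    nid = 0
    for i in range(n_i):
        for j in range(n_j):
            if i % 2 == 1 and j % 2 == 1:
                continue  # serendipity: no interior center nodes
            r = xi_g[i] * geom.R
            z = eta_g[j] * float(geom.surface_height(r))
            node_id[i, j] = nid
            coords.append((r, z))
            nid += 1
    nodes = np.asarray(coords, dtype=float)

    elems = np.empty((nx * nz, 8), dtype=int)
    e = 0
    for i in range(nx):
        for j in range(nz):
            I, J = 2 * i, 2 * j
            elems[e] = [
                node_id[I, J], node_id[I + 2, J], node_id[I + 2, J + 2], node_id[I, J + 2],
                node_id[I + 1, J], node_id[I + 2, J + 1], node_id[I + 1, J + 2], node_id[I, J + 1],
            ]
            e += 1

    corner_mask = np.zeros(nodes.shape[0], dtype=bool)
    corner_mask[elems[:, :4].ravel()] = True
    p_nodes = np.flatnonzero(corner_mask)
    p_index = -np.ones(nodes.shape[0], dtype=int)
    p_index[p_nodes] = np.arange(p_nodes.size)

    bottom = node_id[:, 0][node_id[:, 0] >= 0]
    top = node_id[:, n_j - 1][node_id[:, n_j - 1] >= 0]
    axis = node_id[0, :][node_id[0, :] >= 0]
    rim = node_id[n_i - 1, :][node_id[n_i - 1, :] >= 0]

    def _edges_along(ii, jj, horizontal: bool):
        out = []
        if horizontal:
            for i in range(nx):
                out.append([node_id[2 * i, jj], node_id[2 * i + 1, jj], node_id[2 * i + 2, jj]])
        else:
            for j in range(nz):
                out.append([node_id[ii, 2 * j], node_id[ii, 2 * j + 1], node_id[ii, 2 * j + 2]])
        return np.asarray(out, dtype=int)

    edge_sets = {
        "top": _edges_along(None, n_j - 1, True),
        "bottom": _edges_along(None, 0, True),
        "rim": _edges_along(n_i - 1, None, False),
    }

    if geom.kind == "disk":
        drained = np.unique(np.concatenate([top, rim]))
        drained_edges = np.vstack([edge_sets["top"], edge_sets["rim"]])
    elif geom.kind == "cell_cap":
        drained = np.unique(np.concatenate([top, rim]))
        drained_edges = np.vstack([edge_sets["top"], edge_sets["rim"]])
    else:  # column1d: drained through the top only
        drained = top
        drained_edges = edge_sets["top"]
    edge_sets["drained"] = drained_edges

    node_sets = {
        "bottom": bottom,
        "top": top,
        "axis": axis,
        "rim": rim,
        "drained": drained,
    }
    return Mesh(
        nodes=nodes,
        elems=elems,
        p_nodes=p_nodes,
        p_index=p_index,
        node_sets=node_sets,
        edge_sets=edge_sets,
        nx=nx,
        nz=nz,
        xi_corners=xi_c,
        eta_corners=eta_c,
    )


def locate_probes(geom: GeometrySpec, mesh: Mesh):
    """Element index and local (xi, eta) coordinates for each probe point.

    Probes are assumed to lie on or inside the domain; points on the top
    surface map to eta_local = +1 of the top element row.
    """
    xi_corners = mesh.xi_corners
    eta_corners = mesh.eta_corners
    out = []
    for label, r, z in geom.probe_points:
        xi = min(r / geom.R, xi_corners[-1])
        col = int(np.clip(np.searchsorted(xi_corners, xi, side="right") - 1, 0, mesh.nx - 1))
        xi0, xi1 = xi_corners[col], xi_corners[col + 1]
        xi_loc = 2.0 * (xi - xi0) / (xi1 - xi0) - 1.0
        h = float(geom.surface_height(xi * geom.R))
        eta = 1.0 if h == 0 else min(z / h, 1.0)
        row = int(np.clip(np.searchsorted(eta_corners, eta, side="right") - 1, 0, mesh.nz - 1))
        eta0, eta1 = eta_corners[row], eta_corners[row + 1]
        eta_loc = 2.0 * (eta - eta0) / (eta1 - eta0) - 1.0
        elem = col * mesh.nz + row
        out.append((label, elem, np.clip(xi_loc, -1, 1), np.clip(eta_loc, -1, 1)))
    return out
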