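"""Element machinery for axisymmetric Q8 (displacement) / Q4 (pressure) FEM.

All element-level quantities are computed vectorized across elements (and
optionally across a leading batch axis, used for finite-difference
tangents): arrays are shaped ``(..., n_elem, n_gauss, ...)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gauss_2d",
    "gauss_1d",
    "q8_shape",
    "q4_shape",
    "line3_shape",
    "ElementBasis",
]

# Q8 serendipity node local coordinates: corners then midsides
_Q8_XI = np.array([-1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0, -1.0])
_Q8_ETA = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, 0.0, 1.0, 0.0])


def gauss_1d(n: int = 3):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def gauss_2d(n: int = 3):
    """Tensor-product Gauss points: returns (pts (n*n, 2), weights (n*n,))."""
    x, w = np.polynomial.legendre.leggauss(n)
    xi, eta = np.meshgrid(x, x, indexing="ij")
    wts = np.outer(w, w)
    return np.column_stack([xi.ravel(), eta.ravel()]), wts.ravel()


def q8_shape(points: np.ndarray):
    """Serendipity quadratic shape functions.

    Returns ``N`` with shape (npts, 8) and derivatives ``dN`` with shape
    (npts, 8, 2) w.r.t. (xi, eta).
    """
    pts = np.atleast_2d(points)
    xi, eta = pts[:, 0:1], pts[:, 1:2]
    N = np.empty((pts.shape[0], 8))
    dN = np.empty((pts.shape[0], 8, 2))
    for a in range(8):
        xa, ea = _Q8_XI[a], _Q8_ETA[a]
        if xa != 0.0 and ea != 0.0:  # corner
            N[:, a] = 0.25 * (1 + xa * xi[:, 0]) * (1 + ea * eta[:, 0]) * (
                xa * xi[:, 0] + ea * eta[:, 0] - 1
            )
            dN[:, a, 0] = 0.25 * xa * (1 + ea * eta[:, 0]) * (
                2 * xa * xi[:, 0] + ea * eta[:, 0]
            )
            dN[:, a, 1] = 0.25 * ea * (1 + xa * xi[:, 0]) * (
                xa * xi[:, 0] + 2 * ea * eta[:, 0]
            )
        elif xa == 0.0:  # midside on eta = +-1
            N[:, a] = 0.5 * (1 - xi[:, 0] ** 2) * (1 + ea * eta[:, 0])
            dN[:, a, 0] = -xi[:, 0] * (1 + ea * eta[:, 0])
            dN[:, a, 1] = 0.5 * ea * (1 - xi[:, 0] ** 2)
        else:  # midside on xi = +-1
            N[:, a] = 0.5 * (1 + xa * xi[:, 0]) * (1 - eta[:, 0] ** 2)
            dN[:, a, 0] = 0.5 * xa * (1 - eta[:, 0] ** 2)
            dN[:, a, 1] = -eta[:, 0] * (1 + xa * xi[:, 0])
    return N, dN


def q4_shape(points: np.ndarray):
    """Bilinear shape functions on the 4 corner nodes."""
    pts = np.atleast_2d(points)
    xi, eta = pts[:, 0], pts[:, 1]
    N = 0.25 * np.column_stack(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )
    dN = np.empty((pts.shape[0], 4, 2))
    dN[:, 0, 0], dN[:, 0, 1] = -0.25 * (1 - eta), -0.25 * (1 - xi)
    dN[:, 1, 0], dN[:, 1, 1] = 0.25 * (1 - eta), -0.25 * (1 + xi)
    dN[:, 2, 0], dN[:, 2, 1] = 0.25 * (1 + eta), 0.25 * (1 + xi)
    dN[:, 3, 0], dN[:, 3, 1] = -0.25 * (1 + eta), 0.25 * (1 - xi)
    return N, dN


def line3_shape(s: np.ndarray):
    """Quadratic 3-node line shape functions on s in [-1, 1] (end, mid, end)."""
    s = np.atleast_1d(s)
    N = np.column_stack([0.5 * s * (s - 1), 1 - s**2, 0.5 * s * (s + 1)])
    dN = np.column_stack([s - 0.5, -2 * s, s + 0.5])
    return N, dN


class ElementBasis:
    """Pre-evaluated shape data shared by the linear and nonlinear solvers."""

    def __init__(self, n_gauss: int = 3):
        self.gp, self.gw = gauss_2d(n_gauss)
        self.N8, self.dN8 = q8_shape(self.gp)  # (g,8), (g,8,2)
        self.N4, self.dN4 = q4_shape(self.gp)  # (g,4), (g,4,2)
        s1, w1 = gauss_1d(n_gauss)
        self.edge_s, self.edge_w = s1, w1
        self.Nl, self.dNl = line3_shape(s1)  # (g,3)

    # -- geometric quantities -------------------------------------------------

    def jacobians(self, coords: np.ndarray):
        """Jacobian data on (possibly batched) element coordinates.

        ``coords``: (..., E, 8, 2) nodal r-z positions.
        Returns ``detJ`` (..., E, g), ``grad8`` (..., E, g, 8, 2) physical
        gradients of the Q8 functions, ``grad4`` (..., E, g, 4, 2) for Q4,
        and ``r_gp`` (..., E, g) radial positions of the Gauss points.
        """
        # J[..., e, g, i, j] = d x_i / d xi_j
        J = np.einsum("gak,...eai->...egik", self.dN8, coords)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        invJ = np.empty_like(J)
        invJ[..., 0, 0] = J[..., 1, 1]
        invJ[..., 1, 1] = J[..., 0, 0]
        invJ[..., 0, 1] = -J[..., 0, 1]
        invJ[..., 1, 0] = -J[..., 1, 0]
        invJ = invJ / detJ[..., None, None]
        grad8 = np.einsum("gak,...egki->...egai", self.dN8, invJ)
        grad4 = np.einsum("gak,...egki->...egai", self.dN4, invJ)
        r_gp = np.einsum("ga,...ea->...eg", self.N8, coords[..., 0])
        return detJ, grad8, grad4, r_gp
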