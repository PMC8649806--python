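"""Closed-form 1D linear-poroelastic swelling/deswelling solutions.

A thin poroelastic layer of thickness ``H`` sits on an impermeable rigid
substrate, is laterally confined (only vertical strain), and exchanges
fluid through its top surface where the bath chemical potential — lumped
here into an effective pressure ``P_eff`` — changes at t = 0.  The pore
pressure then obeys a pure diffusion equation with coefficient ``D`` and
the surface displacement follows the classical consolidation series.

Two distinct dimensionless times appear and are deliberately exposed
under different names: the consolidation time ``tau = D t / (4 H^2)``
that enters the series solutions, and the figure-normalization time
``4 D t / (pi H^2)`` used when overlaying curves; their ratio is the
constant 16/pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DisplacementCurve
from .materials import PoroelasticMaterial, RampLoad

__all__ = [
    "Slab1D",
    "delta_infinity",
    "finite_thickness_response",
    "self_similar_response",
    "chemical_potential_profile",
    "ramp_response",
    "tau_consolidation",
    "tau_figure_normalization",
]

#: absolute tail bound for adaptive series truncation
_SERIES_TOL = 1e-12
#: never use fewer odd terms than this
_SERIES_MIN_TERMS = 100
#: hard cap on the largest odd index (guards memory for tau -> 0)
_SERIES_MAX_N = 200_001


@dataclass(frozen=True)
class Slab1D:
    """Laterally confined poroelastic layer of thickness ``H`` (um)."""

    H: float

    def __post_init__(self) -> None:
        if not self.H > 0:
            raise ValueError(f"layer thickness must be positive, got H={self.H}")


def _odd_indices(tau_min: float) -> np.ndarray:
    """Odd summation indices needed so the truncated tail is < _SERIES_TOL.

    The terms are bounded by ``(8/pi^2) exp(-n^2 pi^2 tau) / n^2``; for the
    smallest positive tau we keep terms until the exponential alone drops
    below the tolerance, with a floor of ``_SERIES_MIN_TERMS`` odd terms.
    """
    if tau_min > 0:
        n_needed = int(np.sqrt(-np.log(_SERIES_TOL) / tau_min) / np.pi) + 2
    else:
        n_needed = _SERIES_MAX_N
    n_max = max(2 * _SERIES_MIN_TERMS - 1, min(n_needed | 1, _SERIES_MAX_N))
    return np.arange(1, n_max + 1, 2, dtype=float)


def _series_sum(coeff_fn, tau: np.ndarray) -> np.ndarray:
    """Sum ``coeff(n) * exp(-n^2 pi^2 tau)`` over odd n, blocked over n."""
    tau = np.asarray(tau, dtype=float)
    pos = tau[tau > 0]
    n = _odd_indices(pos.min() if pos.size else 1.0)
    out = np.zeros(tau.shape, dtype=float)
    flat_tau = tau.reshape(-1)
    flat_out = out.reshape(-1)
    block = max(1, int(4e6 // max(flat_tau.size, 1)))
    for start in range(0, n.size, block):
        nb = n[start : start + block]
        expo = np.exp(-np.outer(flat_tau, nb**2 * np.pi**2))
        flat_out += expo @ coeff_fn(nb)
    return out if tau.ndim else flat_out.reshape(())


def tau_consolidation(t, mat: PoroelasticMaterial, H: float):
    """Consolidation dimensionless time ``D t / (4 H^2)``."""
    return np.asarray(t, dtype=float) * mat.D / (4.0 * H**2)


def tau_figure_normalization(t, mat: PoroelasticMaterial, H: float):
    """Figure-overlay dimensionless time ``4 D t / (pi H^2)``.

    Distinct from :func:`tau_consolidation`; the ratio between the two is
    exactly 16/pi for any input.
    """
    return 4.0 * mat.D * np.asarray(t, dtype=float) / (np.pi * H**2)


def delta_infinity(mat: PoroelasticMaterial, load: RampLoad, slab: Slab1D) -> float:
    """Plateau displacement of the confined layer, um (signed).

    ``delta_inf = P_eff * H * (1 - 2 nu) / (2 G (1 - nu)) = P_eff * H / M``
    where ``M`` is the oedometric modulus.  Positive means upward motion
    of the top surface (swelling); the sign follows ``P_eff``.  The rise
    time does not enter: the plateau is a drained equilibrium.
    """
    return load.P_eff * slab.H / mat.M_oed


def finite_thickness_response(tau) -> np.ndarray:
    """Normalized step displacement ``delta(t)/delta_inf`` of the finite layer.

    ``1 - sum_{n odd} (8 / n^2 pi^2) exp(-n^2 pi^2 tau)`` for the
    consolidation time ``tau = D t / (4 H^2)``.  Maps [0, inf) to [0, 1),
    monotone non-decreasing; the series sums to exactly 1 at tau = 0.
    Output is clipped to [0, 1] against truncation residue.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("dimensionless time tau must be >= 0")
    s = _series_sum(lambda n: 8.0 / (n**2 * np.pi**2), tau)
    out = np.clip(1.0 - s, 0.0, 1.0)
    # the full series sums to exactly 1 at tau = 0; enforce it past truncation
    out = np.where(tau == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def self_similar_response(t, mat: PoroelasticMaterial, slab: Slab1D) -> np.ndarray:
    """Early-time half-space law ``delta(t)/delta_inf = (2/H) sqrt(D t / pi)``.

    Valid only while the diffusion front has not felt the substrate
    (tau = D t / 4 H^2 <~ 0.01); the caller owns the domain of validity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return (2.0 / slab.H) * np.sqrt(mat.D * t / np.pi)


def chemical_potential_profile(
    z, t, mat: PoroelasticMaterial, slab: Slab1D, mode: str = "finite"
):
    """Normalized potential ``(mu(z,t) - mu_bar) / (mu_0 - mu_bar)``.

    Coordinates: the drained top surface sits at ``z = 0`` and the
    impermeable substrate at ``z = -H``.  The value is 1 at the initial
    equilibrium and 0 once the boundary value has fully propagated.

    ``mode="finite"`` evaluates the odd-harmonic series
    ``-sum_{n odd} (4/(n pi)) sin(n pi z / (2H)) exp(-n^2 pi^2 tau)``;
    ``mode="semi_infinite"`` evaluates the half-space error-function law
    ``erf(-z / sqrt(4 D t))``, which is 0 at the drained surface and 1 in
    the undisturbed far field — the normalization used throughout here.
    """
    from scipy.special import erf

    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if np.any(z > 0) or np.any(z < -slab.H):
        raise ValueError(f"z must lie within the slab [-H, 0], H={slab.H}")
    if mode == "finite":
        tau = tau_consolidation(t, mat, slab.H)
        tau_b, z_b = np.broadcast_arrays(tau, z)
        n = _odd_indices(float(tau_b[tau_b > 0].min()) if (tau_b > 0).any() else 1.0)
        out = np.zeros(tau_b.shape, dtype=float)
        flat_tau = tau_b.reshape(-1)
        flat_z = z_b.reshape(-1)
        flat_out = out.reshape(-1)
        block = max(1, int(4e6 // max(flat_tau.size, 1)))
        for start in range(0, n.size, block):
            nb = n[start : start + block]
            expo = np.exp(-np.outer(flat_tau, nb**2 * np.pi**2))
            sines = np.sin(np.outer(flat_z, nb * np.pi / (2.0 * slab.H)))
            flat_out += -np.sum((4.0 / (nb * np.pi)) * sines * expo, axis=1)
        out = np.clip(out, 0.0, 1.0)
        # at t = 0 every interior point is at the initial equilibrium
        out = np.where((tau_b == 0.0) & (z_b < 0.0), 1.0, out)
        return out if out.ndim else float(out)
    if mode == "semi_infinite":
        t_b, z_b = np.broadcast_arrays(t, z)
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = np.where(t_b > 0, -z_b / np.sqrt(4.0 * mat.D * np.where(t_b > 0, t_b, 1.0)), np.inf)
        arg = np.where((t_b == 0) & (z_b == 0), 0.0, arg)
        out = erf(arg)
        return out if out.ndim else float(out)
    raise ValueError(f"mode must be 'finite' or 'semi_infinite', got {mode!r}")


def ramp_response(
    t_grid, mat: PoroelasticMaterial, load: RampLoad, slab: Slab1D
) -> DisplacementCurve:
    """Displacement response of the confined layer to a finite-rise ramp.

    The 1D model is linear and time-invariant, so the ramp response is
    the convolution of the step response with the normalized loading
    rate, ``delta(t) = (1/t_r) * int_0^min(t, t_r) delta_step(t - s) ds``.
    Each exponential series term integrates in closed form, so the
    convolution is evaluated exactly (no quadrature error):

    for ``t <= t_r``:  ``(1/t_r) [ t - sum_n a_n (1 - e^{-l_n t}) / l_n ]``
    for ``t >  t_r``:  ``(1/t_r) [ t_r - sum_n a_n (e^{-l_n (t-t_r)} - e^{-l_n t}) / l_n ]``

    with ``a_n = 8/(n^2 pi^2)`` and decay rates ``l_n = n^2 pi^2 D/(4H^2)``.
    Degenerates to the step response exactly as ``t_r -> 0``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be >= 0")
    d_inf = delta_infinity(mat, load, slab)
    if load.t_r == 0.0:
        shape = finite_thickness_response(tau_consolidation(t, mat, slab.H))
    else:
        shape = ramp_shape(t, mat.D, slab.H, load.t_r)
    curve = DisplacementCurve(
        t,
        d_inf * shape,
        delta_inf=d_inf,
        meta={
            "model": "analytic_1d_ramp",
            "E_kPa": mat.E,
            "nu": mat.nu,
            "D_um2_s": mat.D,
            "H_um": slab.H,
            "P_eff_kPa": load.P_eff,
            "t_r_s": load.t_r,
        },
    )
    return curve


def ramp_shape(t, D: float, H: float, t_r: float) -> np.ndarray:
    """Normalized ramp response ``delta(t)/delta_inf`` (dimensionless).

    Exact term-wise integral of the consolidation series over a linear
    ramp of duration ``t_r`` (see :func:`ramp_response`).  ``t_r = 0``
    falls back to the step series.
    """
    t = np.asarray(t, dtype=float)
    if t_r == 0.0:
        return finite_thickness_response(t * D / (4.0 * H**2))
    rate = np.pi**2 * D / (4.0 * H**2)  # l_n = rate * n^2
    t_pos = t[t > 0]
    tau_min = float(t_pos.min()) * D / (4.0 * H**2) if t_pos.size else 1.0
    n = _odd_indices(min(tau_min, t_r * D / (4.0 * H**2)))
    a = 8.0 / (n**2 * np.pi**2)
    lam = rate * n**2
    flat_t = t.reshape(-1)
    out = np.empty_like(flat_t)
    during = flat_t <= t_r
    block = max(1, int(4e6 // max(flat_t.size, 1)))
    s_during = np.zeros(during.sum())
    s_after = np.zeros((~during).sum())
    for start in range(0, n.size, block):
        ab = a[start : start + block]
        lb = lam[start : start + block]
        if s_during.size:
            td = flat_t[during]
            s_during += np.sum(ab / lb * (1.0 - np.exp(-np.outer(td, lb))), axis=1)
        if s_after.size:
            ta = flat_t[~during]
            ea = np.exp(-np.outer(ta - t_r, lb)) - np.exp(-np.outer(ta, lb))
            s_after += np.sum(ab / lb * ea, axis=1)
    out[during] = (flat_t[during] - s_during) / t_r
    out[~during] = (t_r - s_after) / t_r
    return np.clip(out.reshape(t.shape), 0.0, 1.0)
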