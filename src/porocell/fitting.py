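"""Staged inverse estimation of (P_eff, D, t_r) from displacement curves.

The procedure mirrors how poroelastic parameters are extracted from
swelling/deswelling experiments: the drained elastic modulus E comes from
indentation (fixed per direction), the Poisson ratio is fixed at 0.3, and
only the effective pressure, the poroelastic diffusion constant, and the
loading rise time are fitted, on the first 40 s of the curve (beyond
which cytoskeletal remodeling invalidates the purely poroelastic model):

* stage 1 — fit (P_eff, D) with an instantaneous load (t_r = 0);
* stage 2 — scan t_r upward in 0.1 s increments, re-optimizing (P_eff, D)
  locally at each candidate, and keep the global best by RMS error
  (smallest t_r wins ties: parsimony).

The default forward model is the analytic 1D ramp response at the bead
height scaled by an empirical geometry factor calibrated against the
axisymmetric cell-cap solver (see ``cap_geometry_factor``); because the
response is linear in P_eff, the optimal pressure at fixed (D, t_r) is a
closed-form projection, which keeps the two outer optimizations
one-dimensional.  Exact (slow) forward modes run the transient solver per
candidate instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .analytic import Slab1D, delta_infinity, ramp_shape
from .curves import DisplacementCurve
from .materials import PoroelasticMaterial, RampLoad

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_curve",
    "batch_fit",
    "cap_geometry_factor",
    "calibrate_geometry_factor",
]

# Plateau ratio cap-solver / 1D-column at a probe on the cap surface, per
# relative probe height h/H_apex.  Computed once from the linear cell-cap
# solver (traction-free drained surface, no-slip bottom, H=5.5, R=15,
# nx=20, nz=8; see calibrate_geometry_factor, which regenerates it).
_CAP_FACTOR_TABLE = (
    (0.455, 0.715),
    (0.727, 0.879),
    (1.000, 0.948),
)


def cap_geometry_factor(height_fraction: float) -> float:
    """Interpolated cap/1D plateau ratio at relative height ``h / H_apex``."""
    hs = np.array([h for h, _ in _CAP_FACTOR_TABLE])
    fs = np.array([f for _, f in _CAP_FACTOR_TABLE])
    return float(np.interp(height_fraction, hs, fs))


def calibrate_geometry_factor(
    height_fraction: float = 1.0,
    H_apex: float = 5.5,
    R: float = 15.0,
    E: float = 0.975,
    nu: float = 0.3,
    D: float = 3.0,
) -> float:
    """Recompute the cap/1D plateau ratio by running the linear cap solver."""
    from .solver import (
        BoundaryConditionSet,
        GeometrySpec,
        SolverConfig,
        solve_linear_biot,
    )

    h = height_fraction * H_apex
    r = R * float(np.sqrt(max(0.0, 1.0 - height_fraction**2)))
    geom = GeometrySpec(kind="cell_cap", H=H_apex, R=R,
                        probe_points=(("PF", r, h),))
    mat = PoroelasticMaterial(E=E, nu=nu, D=D)
    bcs = BoundaryConditionSet(bottom_mech="no_slip", drained_traction="none")
    cfg = SolverConfig(end_time=25.0 * H_apex**2 / D, dt_init=0.02, growth=1.15,
                       max_dt=H_apex**2 / D / 4.0, nx=20, nz=8)
    res = solve_linear_biot(geom, mat, bcs, RampLoad(0.01, 1.0), cfg)
    plateau = float(res.probe("PF").delta[-1])
    return plateau / delta_infinity(mat, RampLoad(0.01), Slab1D(h))


@dataclass(frozen=True)
class FitConfig:
    """Controls for the staged inverse fit.

    ``E_swelling`` / ``E_deswelling`` are the fixed drained moduli used
    depending on the sign of the curve (averages of indentation
    measurements on control + swelled, resp. control + shrunk cells).
    """

    window: float = 40.0  # s of data used
    nu: float = 0.3
    E_swelling: float = 0.975  # kPa
    E_deswelling: float = 1.15  # kPa
    t_r_step: float = 0.1  # s
    t_r_max: float = 10.0  # s
    P_bounds: tuple = (0.01, 5.0)  # kPa (magnitude)
    D_bounds: tuple = (0.1, 50.0)  # um^2/s
    n_D_coarse: int = 25  # stage-1 coarse grid points (log-spaced)
    forward_model: str = "analytic_ramp"  # | solver_disk | solver_cell_cap
    geometry_factor: float | None = None  # None: per-height cap table
    cap_height: float = 5.5  # um, template apex height for the factor

    def __post_init__(self) -> None:
        if self.window <= 0 or self.t_r_step <= 0:
            raise ValueError("window and t_r_step must be positive")
        if not (0 < self.D_bounds[0] < self.D_bounds[1] < np.inf):
            raise ValueError("D bounds must be finite, positive, increasing")
        if not (0 < self.P_bounds[0] < self.P_bounds[1] < np.inf):
            raise ValueError("P bounds must be finite, positive, increasing")


@dataclass
class FitResult:
    P_eff: float  # kPa, signed
    D: float  # um^2/s
    t_r: float  # s
    residual_rms: float  # um
    direction: str  # swelling | deswelling
    converged: bool
    stages: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "P_eff_kPa": self.P_eff,
            "D_um2_s": self.D,
            "t_r_s": self.t_r,
            "residual_rms_um": self.residual_rms,
            "direction": self.direction,
            "converged": self.converged,
        }


class _Forward:
    """Unit-pressure forward model delta(t; D, t_r) for a given bead height."""

    def __init__(self, t: np.ndarray, H: float, cfg: FitConfig, E: float):
        self.t = t
        self.H = H
        self.cfg = cfg
        self.E = E
        if cfg.geometry_factor is not None:
            self.g = cfg.geometry_factor
        elif cfg.forward_model == "analytic_ramp":
            self.g = cap_geometry_factor(min(H / cfg.cap_height, 1.0))
        else:
            self.g = 1.0

    def shape(self, D: float, t_r: float) -> np.ndarray:
        """Displacement for unit P_eff (um per kPa)."""
        cfg = self.cfg
        if cfg.forward_model == "analytic_ramp":
            mat = PoroelasticMaterial(E=self.E, nu=cfg.nu, D=D)
            amp = delta_infinity(mat, RampLoad(1.0), Slab1D(self.H))
            return self.g * amp * ramp_shape(self.t, D, self.H, t_r)
        return self._solver_shape(D, t_r)

    def _solver_shape(self, D: float, t_r: float) -> np.ndarray:
        from .solver import (
            BoundaryConditionSet,
            GeometrySpec,
            SolverConfig,
            solve_linear_biot,
        )

        cfg = self.cfg
        kind = "disk" if cfg.forward_model == "solver_disk" else "cell_cap"
        H_apex = cfg.cap_height if kind == "cell_cap" else self.H
        frac = min(self.H / H_apex, 1.0)
        r = 15.0 * float(np.sqrt(max(0.0, 1.0 - frac**2))) if kind == "cell_cap" else 0.0
        geom = GeometrySpec(kind=kind, H=H_apex, R=15.0,
                            probe_points=(("PF", r, frac * H_apex),))
        mat = PoroelasticMaterial(E=self.E, nu=cfg.nu, D=D)
        bcs = BoundaryConditionSet(bottom_mech="no_slip", drained_traction="none")
        scfg = SolverConfig(end_time=float(self.t[-1]) + 1e-6, dt_init=None,
                            growth=1.2, max_dt=max(float(self.t[-1]) / 60.0, 0.05),
                            nx=12, nz=5)
        res = solve_linear_biot(geom, mat, bcs, RampLoad(1.0, t_r), scfg)
        c = res.probe("PF")
        return self.g * np.interp(self.t, c.t, c.delta)


def _best_P(y: np.ndarray, m: np.ndarray, bounds) -> float:
    """Closed-form least-squares amplitude, clipped to the bounds."""
    denom = float(m @ m)
    if denom == 0:
        return bounds[0]
    return float(np.clip(y @ m / denom, *bounds))


def fit_curve(curve: DisplacementCurve, H: float, cfg: FitConfig | None = None) -> FitResult:
    """Staged (P_eff, D, t_r) fit of one displacement curve.

    ``H`` is the bead height (um): the diffusion length that links the
    curve's timescale to D.  The curve is truncated to the first
    ``cfg.window`` seconds.  Deterministic given the config and curve.
    """
    cfg = cfg or FitConfig()
    if H <= 0:
        raise ValueError("bead height H must be positive")
    keep = curve.t <= cfg.window + 1e-9
    t, y = curve.t[keep], curve.delta[keep]
    if t.size < 5:
        raise ValueError("curve too short for fitting")

    late = y[t >= 0.5 * t[-1]]
    direction = "swelling" if np.mean(late) >= 0 else "deswelling"
    sign = 1.0 if direction == "swelling" else -1.0
    E = cfg.E_swelling if direction == "swelling" else cfg.E_deswelling
    y_mag = sign * y  # fit magnitudes; sign restored at the end

    fwd = _Forward(t, H, cfg, E)
    lo, hi = np.log10(cfg.D_bounds[0]), np.log10(cfg.D_bounds[1])

    def rms_at(D: float, t_r: float):
        m = fwd.shape(D, t_r)
        P = _best_P(y_mag, m, cfg.P_bounds)
        r = float(np.sqrt(np.mean((P * m - y_mag) ** 2)))
        return r, P

    def best_D(t_r: float, D_init: float | None):
        # coarse log grid on the first pass, then bounded local refinement
        if D_init is None:
            grid = np.logspace(lo, hi, cfg.n_D_coarse)
            errs = [rms_at(D, t_r)[0] for D in grid]
            i = int(np.argmin(errs))
            a = grid[max(i - 1, 0)]
            b = grid[min(i + 1, grid.size - 1)]
        else:
            a, b = D_init / 2.0, D_init * 2.0
        a = max(a, cfg.D_bounds[0])
        b = min(b, cfg.D_bounds[1])
        if a >= b:
            a, b = cfg.D_bounds
        sol = minimize_scalar(
            lambda x: rms_at(10.0**x, t_r)[0],
            bounds=(np.log10(a), np.log10(b)),
            method="bounded",
            options={"xatol": 1e-5},
        )
        D = float(10.0**sol.x)
        r, P = rms_at(D, t_r)
        return D, P, r

    # stage 1: instantaneous load
    D1, P1, r1 = best_D(0.0, None)
    stages = {"stage1": {"P_eff": P1, "D": D1, "t_r": 0.0, "rms": r1}}

    # stage 2: scan t_r in fixed increments with local (P, D) re-optimization
    best = (r1, 0.0, D1, P1)
    n_steps = int(round(cfg.t_r_max / cfg.t_r_step))
    D_warm = D1
    scan = []
    for k in range(1, n_steps + 1):
        t_r = k * cfg.t_r_step
        try:
            D_k, P_k, r_k = best_D(t_r, D_warm)
        except Exception:
            scan.append((t_r, np.nan))
            continue  # forward-model failure: discard candidate
        scan.append((t_r, r_k))
        D_warm = D_k
        # strict improvement required: ties go to the smaller t_r
        if r_k < best[0] * (1.0 - 1e-9):
            best = (r_k, t_r, D_k, P_k)
    r_best, t_r_best, D_best, P_best = best
    stages["stage2"] = {"t_r_scan": scan, "best_t_r": t_r_best, "rms": r_best}

    if not np.isfinite(r_best):
        raise RuntimeError("all fit candidates failed")
    return FitResult(
        P_eff=sign * P_best,
        D=D_best,
        t_r=t_r_best,
        residual_rms=r_best,
        direction=direction,
        converged=True,
        stages=stages,
    )


def batch_fit(curves_with_heights, cfg: FitConfig | None = None):
    """Fit many curves; aggregate mean and sample SD per direction.

    ``curves_with_heights``: iterable of (DisplacementCurve, H) pairs.
    Returns ``(results, aggregates)`` where results is a list of
    per-curve dicts (including a ``flagged`` entry for curves whose sign
    is ambiguous beyond noise — excluded from the aggregates) and
    aggregates maps direction -> {param: {mean, sd, n}} (sd absent for a
    single curve).
    """
    cfg = cfg or FitConfig()
    results = []
    for curve, H in curves_with_heights:
        keep = curve.t <= cfg.window + 1e-9
        y = curve.delta[keep]
        noise_scale = np.std(np.diff(y)) / np.sqrt(2.0) if y.size > 3 else 0.0
        tail = y[-max(3, y.size // 5):]
        flagged = abs(np.mean(tail)) < 3.0 * noise_scale  # no clear direction
        row = {"H_um": H, "flagged": bool(flagged)}
        if not flagged:
            fit = fit_curve(curve, H, cfg)
            row.update(fit.as_dict())
        results.append(row)
    aggregates = {}
    for direction in ("swelling", "deswelling"):
        rows = [r for r in results if not r["flagged"] and r.get("direction") == direction]
        if not rows:
            continue
        agg = {}
        for key in ("P_eff_kPa", "D_um2_s", "t_r_s"):
            vals = np.array([r[key] for r in rows])
            agg[key] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
                "n": int(vals.size),
            }
        aggregates[direction] = agg
    return results, aggregates
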