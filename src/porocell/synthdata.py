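"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its spec and seed (bit-identical on
regeneration) and returns the ground truth alongside the data, so every
downstream stage can be scored on synthetic inputs with known answers.

Defaults emulate the measurement conditions of the study this package
models: 100 ms frame spacing, ~10 nm displacement tracking noise, 100 nm
calibration z-steps, confocal stacks of 40 slices at 0.2 um spacing, and
ring images with Poisson photon noise (~1000 counts at the ring peak)
plus Gaussian read noise (sigma = 5 counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .analytic import Slab1D, delta_infinity, ramp_response
from .curves import DisplacementCurve
from .imaging.trajectory import FrameImage
from .materials import PoroelasticMaterial, RampLoad

__all__ = [
    "CurveSpec",
    "RingImageSpec",
    "ConfocalSpec",
    "gen_displacement_curve",
    "gen_defocus_series",
    "gen_calibration_stack",
    "gen_confocal_stack",
    "render_defocus_frame",
]


# -- displacement curves -------------------------------------------------------


@dataclass(frozen=True)
class CurveSpec:
    """Ground truth for a synthetic bead displacement curve.

    The forward model is the analytic 1D ramp response at the bead height
    ``H`` scaled by ``geometry_factor`` (1.0 = pure 1D column).  Noise is
    additive Gaussian with ``noise_um`` standard deviation (default 10 nm,
    the tracking resolution of the defocusing method).
    """

    P_eff: float = 0.8  # kPa
    D: float = 2.4  # um^2/s
    t_r: float = 4.0  # s
    H: float = 3.9  # um (bead height)
    E: float = 0.975  # kPa
    nu: float = 0.3
    noise_um: float = 0.01
    dt: float = 0.1  # s (100 ms frames)
    duration: float = 60.0  # s
    geometry_factor: float = 1.0


def gen_displacement_curve(spec: CurveSpec, seed: int = 0):
    """Synthetic delta(t) curve plus its ground-truth record."""
    rng = np.random.default_rng(seed)
    mat = PoroelasticMaterial(E=spec.E, nu=spec.nu, D=spec.D)
    load = RampLoad(spec.P_eff, spec.t_r)
    slab = Slab1D(spec.H)
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    clean = ramp_response(t, mat, load, slab)
    delta = spec.geometry_factor * clean.delta
    if spec.noise_um > 0:
        delta = delta + rng.normal(0.0, spec.noise_um, size=delta.shape)
    truth = dict(asdict(spec), seed=seed,
                 delta_inf=spec.geometry_factor * float(clean.delta_inf))
    curve = DisplacementCurve(t, delta, delta_inf=truth["delta_inf"],
                              meta={"synthetic": True, **truth})
    return curve, truth


# -- defocused ring images -----------------------------------------------------


@dataclass(frozen=True)
class RingImageSpec:
    """Rendering parameters for synthetic defocused bead frames.

    The bead is drawn as a central Gaussian blob plus an annular-Gaussian
    outer ring whose radius follows the linear calibration law
    ``radius = (z - intercept) / slope``; ring amplitude decays weakly
    with defocus (brightness spreads over a larger ring).  This is an
    empirical stand-in for the diffraction pattern: the pipeline's
    contract is only the linear radius-z law.
    """

    shape: tuple = (96, 96)
    center: tuple = (47.3, 48.6)  # deliberately off-grid (sub-pixel)
    pixel_size: float = 0.1  # um/px
    cal_slope: float = 0.05  # um of z per px of ring radius
    cal_intercept: float = 0.2  # um
    blob_amp: float = 400.0  # photon counts at blob centre (dimmer than the ring)
    blob_sigma: float = 2.0  # px
    ring_width: float = 2.0  # px
    ring_peak: float = 1000.0  # photon counts at ring crest (reference radius)
    baseline: float = 20.0  # camera offset counts
    read_noise: float = 5.0  # counts
    photon_noise: bool = True


def ring_radius_of_z(z: float, spec: RingImageSpec) -> float:
    """Invert the calibration law: outer-ring radius (px) at height z (um)."""
    return (z - spec.cal_intercept) / spec.cal_slope


def render_defocus_frame(z: float, spec: RingImageSpec, rng=None, timestamp: float = 0.0):
    """Render one frame at bead height ``z`` (um); noiseless if rng is None."""
    r_ring = ring_radius_of_z(z, spec)
    ny, nx = spec.shape
    max_r = min(spec.center[0], spec.center[1], nx - 1 - spec.center[0], ny - 1 - spec.center[1])
    if r_ring + 3 * spec.ring_width > max_r:
        raise ValueError(
            f"ring radius {r_ring:.1f} px exceeds the frame (max {max_r:.1f} px)"
        )
    if r_ring <= 0:
        raise ValueError("z below the calibration focal offset: no ring")
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(xx - spec.center[0], yy - spec.center[1])
    blob = spec.blob_amp * np.exp(-(d**2) / (2 * spec.blob_sigma**2))
    # ring amplitude decays with defocus as the light spreads over a larger
    # ring (weak sqrt law keeps the crest brighter than the central blob
    # across the working range, as in the empirical ring images)
    r_ref = 0.5 * max_r
    amp = spec.ring_peak * np.sqrt(r_ref / r_ring)
    ring = amp * np.exp(-((d - r_ring) ** 2) / (2 * spec.ring_width**2))
    counts = blob + ring + spec.baseline
    if rng is not None:
        if spec.photon_noise:
            counts = rng.poisson(counts).astype(float)
        if spec.read_noise > 0:
            counts = counts + rng.normal(0.0, spec.read_noise, size=counts.shape)
    return FrameImage(intensity=counts, pixel_size=spec.pixel_size, timestamp=timestamp)


def gen_defocus_series(z_trajectory, spec: RingImageSpec = RingImageSpec(), seed: int = 0):
    """Frame sequence following ``z_trajectory`` = (times, z values in um).

    Returns ``(frames, truth)`` where truth records the calibration law
    and the exact per-frame z and ring radii.
    """
    rng = np.random.default_rng(seed)
    times, zs = map(np.asarray, z_trajectory)
    frames = [
        render_defocus_frame(z, spec, rng=rng, timestamp=t) for t, z in zip(times, zs)
    ]
    truth = {
        "cal_slope": spec.cal_slope,
        "cal_intercept": spec.cal_intercept,
        "center": tuple(spec.center),
        "t": times.tolist(),
        "z": zs.tolist(),
        "ring_radius_px": [ring_radius_of_z(z, spec) for z in zs],
        "seed": seed,
    }
    return frames, truth


def gen_calibration_stack(
    spec: RingImageSpec = RingImageSpec(),
    z_start: float = 0.8,
    n_steps: int = 15,
    step: float = 0.1,
    seed: int = 0,
):
    """Calibration acquisition: images at ``n_steps`` stage heights 100 nm apart."""
    zs = z_start + step * np.arange(n_steps)
    return gen_defocus_series((np.arange(n_steps) * 1.0, zs), spec, seed=seed)


# -- confocal stacks -----------------------------------------------------------


@dataclass(frozen=True)
class ConfocalSpec:
    """Synthetic GFP confocal stack of an ellipsoidal cell.

    ``shape="cap"`` is a half-ellipsoid sitting on the substrate
    (adherent cell, volume 2/3 pi a b c); ``shape="ellipsoid"`` is the
    full ellipsoid (4/3 pi a b c).  ``volume_ratio`` rescales all
    semi-axes isotropically and raises the interior intensity by the
    inverse ratio, emulating GFP concentration increase as water leaves.
    """

    semi_axes: tuple = (10.0, 8.0, 4.0)  # (a, b, c) um; c is vertical
    shape: str = "cap"
    volume_ratio: float = 1.0
    n_slices: int = 40
    dz: float = 0.2  # um
    pixel_size: float = 0.2  # um (y and x)
    ny: int = 128
    nx: int = 128
    intensity: float = 120.0  # interior counts at volume_ratio 1
    background: float = 10.0
    noise: float = 4.0  # gaussian background noise sigma, counts


def gen_confocal_stack(spec: ConfocalSpec = ConfocalSpec(), seed: int = 0):
    """Render the stack; returns ``(stack, truth)`` with the analytic volume."""
    if spec.shape not in ("cap", "ellipsoid"):
        raise ValueError("shape must be 'cap' or 'ellipsoid'")
    rng = np.random.default_rng(seed)
    s = spec.volume_ratio ** (1.0 / 3.0)
    a, b, c = (x * s for x in spec.semi_axes)
    z = (np.arange(spec.n_slices) + 0.5) * spec.dz
    y = (np.arange(spec.ny) - spec.ny / 2 + 0.5) * spec.pixel_size
    x = (np.arange(spec.nx) - spec.nx / 2 + 0.5) * spec.pixel_size
    if spec.shape == "cap":
        zc = 0.0  # cell sits on the substrate (z = 0 plane), upper half only
        vol = 2.0 / 3.0 * np.pi * a * b * c
        z_eff = z
    else:
        zc = z.mean()
        vol = 4.0 / 3.0 * np.pi * a * b * c
        z_eff = z - zc
    zz, yy, xx = np.meshgrid(z_eff, y, x, indexing="ij")
    inside = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0
    if spec.shape == "cap":
        inside &= zz >= 0
    if not inside.any():
        stack = np.full((spec.n_slices, spec.ny, spec.nx), spec.background)
    else:
        if inside[:, 0, :].any() or inside[:, -1, :].any() or inside[:, :, 0].any() or inside[:, :, -1].any():
            raise ValueError("cell does not fit inside the stack")
        stack = np.where(inside, spec.intensity / spec.volume_ratio + spec.background,
                         spec.background).astype(float)
    if spec.noise > 0:
        stack = stack + rng.normal(0.0, spec.noise, size=stack.shape)
    truth = {
        "volume_um3": float(vol) if inside.any() else 0.0,
        "semi_axes_um": (a, b, c),
        "shape": spec.shape,
        "volume_ratio": spec.volume_ratio,
        "voxel_um": (spec.dz, spec.pixel_size, spec.pixel_size),
        "seed": seed,
    }
    return stack, truth
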