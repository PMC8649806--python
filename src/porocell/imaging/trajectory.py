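"""Frame-by-frame bead z-tracking through the defocused-ring pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibrate import Calibration
from .centroid import CentroidError, find_centroid
from .ring import RingDetectionError, outer_ring_radius, radial_projection

__all__ = ["FrameImage", "BeadTrajectory", "track_trajectory"]


@dataclass
class FrameImage:
    """One 2D intensity frame with its acquisition metadata."""

    intensity: np.ndarray
    pixel_size: float  # um / px
    timestamp: float  # s

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("frame contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class BeadTrajectory:
    """z(t) track of one bead; ``z`` is the height change relative to the
    first successfully tracked frame (``z[0] == 0``)."""

    t: np.ndarray
    z: np.ndarray  # um, NaN where detection failed
    ring_radius: np.ndarray  # px, NaN where detection failed
    ok: np.ndarray  # per-frame success flag
    reliable: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def failure_fraction(self) -> float:
        return 1.0 - float(np.mean(self.ok))

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("t_s,z_um,radius_px,ok_flag\n")
            for ti, zi, ri, oi in zip(self.t, self.z, self.ring_radius, self.ok):
                fh.write(f"{ti:.17g},{zi:.17g},{ri:.17g},{int(oi)}\n")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "BeadTrajectory":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        ok = data[:, 3].astype(bool)
        return cls(t=data[:, 0], z=data[:, 1], ring_radius=data[:, 2], ok=ok,
                   reliable=bool(np.mean(ok) >= 0.8))


def track_trajectory(
    frames,
    seed: tuple,
    cal: Calibration,
    delta: float = 1.0,
    threshold: float = 0.05,
    min_radius: float = 0.0,
    window: int = 10,
    max_failed_fraction: float = 0.2,
) -> BeadTrajectory:
    """Track a bead through a defocused frame sequence.

    Per frame: sub-pixel centroid (seeded from the previous success),
    radial projection with annulus interval ``delta``, outer-ring
    detection at ``threshold``, and the calibration map to z.  Frames are
    processed in timestamp order regardless of input order.  Failed frames
    are flagged (NaN), never interpolated; a trajectory with more than
    ``max_failed_fraction`` failures is marked unreliable.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to track")
    order = np.argsort([f.timestamp for f in frames], kind="stable")
    t = np.array([frames[i].timestamp for i in order])
    n = len(frames)
    radius = np.full(n, np.nan)
    z_abs = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    current_seed = seed
    for out_i, i in enumerate(order):
        img = frames[i].intensity
        try:
            cen = find_centroid(img, current_seed, window=window)
            prof = radial_projection(img, (cen.x, cen.y), delta=delta)
            rad = outer_ring_radius(prof, threshold=threshold, min_radius=min_radius)
            z_abs[out_i] = cal.z_of_radius(rad)
            radius[out_i] = rad
            ok[out_i] = True
            current_seed = (cen.x, cen.y)
        except (CentroidError, RingDetectionError, ValueError):
            pass  # flagged below; seed stays at the last success
    if not ok.any():
        raise RuntimeError("tracking failed on every frame")
    z0 = z_abs[np.flatnonzero(ok)[0]]
    z = z_abs - z0
    reliable = (1.0 - float(np.mean(ok))) <= max_failed_fraction
    return BeadTrajectory(
        t=t, z=z, ring_radius=radius, ok=ok, reliable=reliable,
        meta={"delta_px": delta, "threshold": threshold,
              "cal_slope_um_per_px": cal.slope, "cal_intercept_um": cal.intercept},
    )
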