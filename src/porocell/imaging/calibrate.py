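"""Ring-radius to z-position calibration (ordinary least squares line)."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["Calibration", "calibrate"]


@dataclass
class Calibration:
    """Linear map ``z = slope * ring_radius + intercept``.

    ``slope`` is in um of z per px of outer-ring radius (its sign encodes
    which side of focus the experiment operates on), ``fit_residual`` is
    the RMS of the z residuals (um), and ``valid_range`` the radius span
    (px) covered by the calibration pairs; by default :meth:`z_of_radius`
    refuses to extrapolate beyond it.
    """

    slope: float
    intercept: float
    fit_residual: float
    valid_range: tuple

    def z_of_radius(self, radius, extrapolate: bool = False):
        r = np.asarray(radius, dtype=float)
        lo, hi = self.valid_range
        if not extrapolate:
            margin = 0.05 * (hi - lo)
            if np.any(r < lo - margin) or np.any(r > hi + margin):
                raise ValueError(
                    f"radius outside calibration valid_range {self.valid_range}; "
                    "pass extrapolate=True to override"
                )
        out = self.slope * r + self.intercept
        return float(out) if out.ndim == 0 else out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        blob = json.loads(Path(path).read_text())
        blob["valid_range"] = tuple(blob["valid_range"])
        return cls(**blob)


def calibrate(pairs) -> Calibration:
    """Least-squares line through (ring radius px, stage z um) pairs.

    Requires at least 3 pairs spanning a non-degenerate radius range;
    order of the pairs is irrelevant.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (radius, z) pairs")
    radius, z = pairs[:, 0], pairs[:, 1]
    if np.ptp(radius) == 0:
        raise ValueError("calibration is rank-deficient: all radii equal")
    fit = stats.linregress(radius, z)
    resid = z - (fit.slope * radius + fit.intercept)
    return Calibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
        valid_range=(float(radius.min()), float(radius.max())),
    )
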