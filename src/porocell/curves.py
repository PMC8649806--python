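"""Displacement time series: the exchange object between solver, tracker and fitter."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DisplacementCurve", "NotPlateaued", "time_to_plateau"]


class NotPlateaued(RuntimeError):
    """Raised when a curve has not reached the requested plateau fraction."""


@dataclass
class DisplacementCurve:
    """Vertical displacement delta(t) of a probe point.

    Attributes
    ----------
    t : ndarray
        Strictly increasing time grid, s, with ``t[0] >= 0``.
    delta : ndarray
        Vertical displacement at each time, um.  Signed: positive is
        upward motion of the top surface (swelling).
    delta_inf : float or None
        Plateau displacement, um, if known.
    meta : dict
        Free-form parameter record (material, load, geometry, probe...).
    """

    t: np.ndarray
    delta: np.ndarray
    delta_inf: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.delta.shape:
            raise ValueError("t and delta must be 1D arrays of equal length")
        if self.t.size and self.t[0] < 0:
            raise ValueError("time grid must start at t >= 0")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def normalized(self) -> "DisplacementCurve":
        """Curve scaled by its plateau magnitude |delta_inf| (falls back to
        the final sample if no plateau has been recorded)."""
        scale = self.delta_inf if self.delta_inf is not None else self.delta[-1]
        if scale == 0:
            raise ValueError("cannot normalize a curve with zero plateau")
        return DisplacementCurve(
            self.t.copy(), self.delta / abs(scale), delta_inf=np.sign(scale),
            meta=dict(self.meta),
        )

    # -- round-trip I/O: 2-column CSV + JSON sidecar -------------------------

    def write_csv(self, path: str | Path) -> Path:
        """Write ``time_s,delta_um`` CSV plus a ``.json`` parameter sidecar.

        Values are written with 17 significant digits so a read-back
        reproduces the float64 arrays bit for bit.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("time_s,delta_um\n")
            for ti, di in zip(self.t, self.delta):
                fh.write(f"{ti:.17g},{di:.17g}\n")
        sidecar = {"delta_inf_um": self.delta_inf, "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True, default=float)
        )
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "DisplacementCurve":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        delta_inf = None
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            blob = json.loads(sidecar.read_text())
            delta_inf = blob.get("delta_inf_um")
            meta = blob.get("meta", {})
        return cls(data[:, 0], data[:, 1], delta_inf=delta_inf, meta=meta)


def time_to_plateau(curve: DisplacementCurve, fraction: float = 0.98) -> float:
    """First time the displacement magnitude reaches ``fraction`` of plateau.

    The plateau is ``curve.delta_inf`` when recorded, otherwise the final
    sample.  The crossing is located by linear interpolation between
    samples.  Raises :class:`NotPlateaued` if the curve never reaches the
    requested fraction (including ``fraction >= 1`` on a strictly
    increasing curve whose supremum is never attained).
    """
    if not 0 < fraction:
        raise ValueError("fraction must be positive")
    plateau = curve.delta_inf if curve.delta_inf is not None else curve.delta[-1]
    if plateau == 0:
        raise ValueError("curve has zero plateau; time to plateau undefined")
    y = curve.delta * np.sign(plateau)
    target = fraction * abs(plateau)
    above = y >= target
    if not above.any():
        raise NotPlateaued(
            f"curve never reaches {fraction:.3f} of its plateau "
            f"(max {y.max():.4g} vs target {target:.4g})"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.t[0])
    t0, t1 = curve.t[i - 1], curve.t[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))
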