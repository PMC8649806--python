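"""Sub-pixel bead centroid localization by 2D Gaussian fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["CentroidFit", "find_centroid", "CentroidError"]


class CentroidError(RuntimeError):
    """Centroid could not be localized (flat image / failed fit)."""


@dataclass
class CentroidFit:
    """Result of the 2D Gaussian centre fit."""

    x: float
    y: float
    amplitude: float
    sigma_x: float
    sigma_y: float
    background: float
    rms_residual: float
    ok: bool = True


def find_centroid(img: np.ndarray, seed: tuple, window: int = 10) -> CentroidFit:
    """Sub-pixel bead centre by fitting ``A exp(-...) + B`` on a window.

    ``seed``: approximate (x, y) centre in pixels; the fit runs on a
    square window of half-size ``window`` around it (clipped to the
    image).  The default window of 10 px is about four times the extent
    of a typical bead blob and deliberately excludes the outer ring,
    which the Gaussian model does not describe.  Raises :class:`CentroidError` when the window carries no
    signal above the background noise or the fit does not converge.
    """
    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    x0, y0 = seed
    if not (0 <= x0 < nx and 0 <= y0 < ny):
        raise ValueError(f"seed {seed} outside image of shape {img.shape}")
    xlo, xhi = max(0, int(x0) - window), min(nx, int(x0) + window + 1)
    ylo, yhi = max(0, int(y0) - window), min(ny, int(y0) + window + 1)
    sub2d = img[ylo:yhi, xlo:xhi]
    # high-frequency noise from neighbour differences: robust against the
    # bright out-of-focus ring sweeping through the window
    noise = 1.4826 * float(np.median(np.abs(np.diff(sub2d, axis=1)))) / np.sqrt(2.0)
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    # circular mask: corners of the square window reach sqrt(2) further out
    # and are the first place the outer ring contaminates the fit
    mask = np.hypot(xx - x0, yy - y0) <= window
    sub, yy, xx = sub2d[mask], yy[mask], xx[mask]

    bg0 = float(np.median(sub))
    amp0 = float(sub.max() - bg0)
    if amp0 <= 0 or amp0 < 6.0 * max(noise, 1e-12):
        raise CentroidError("no signal above the noise floor in the fit window")

    # start the centre at the seed: moment estimates are biased by the ring
    cx0, cy0 = float(x0), float(y0)

    def model(p):
        A, cx, cy, sx, sy, B = p
        return A * np.exp(-((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2))) + B

    def resid(p):
        return model(p) - sub

    p0 = [amp0, cx0, cy0, 2.0, 2.0, bg0]
    lo = [0.0, xlo, ylo, 0.3, 0.3, -np.inf]
    hi = [np.inf, xhi - 1, yhi - 1, window * 2.0, window * 2.0, np.inf]
    # soft_l1 keeps any remaining ring-tail pixels from steering the fit
    sol = least_squares(
        resid, p0, bounds=(lo, hi), max_nfev=2000,
        loss="soft_l1", f_scale=max(5.0 * noise, 1e-9),
    )
    if not sol.success:
        raise CentroidError("2D Gaussian fit did not converge")
    A, cx, cy, sx, sy, B = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    # flat frames are rejected by the pre-fit signal check; here only guard
    # against the fit collapsing to (near) zero amplitude
    if A < 0.02 * amp0:
        raise CentroidError("fitted amplitude collapsed: no localized peak")
    return CentroidFit(x=float(cx), y=float(cy), amplitude=float(A),
                       sigma_x=float(sx), sigma_y=float(sy),
                       background=float(B), rms_residual=rms)
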