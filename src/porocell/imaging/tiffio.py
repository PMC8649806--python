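"""Thin TIFF helpers (single- and multi-page, integer and float grids)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_tiff", "write_tiff"]


def write_tiff(path, array) -> Path:
    """Write a 2D frame or 3D stack; dtype is preserved."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array))
    return path


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path))
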