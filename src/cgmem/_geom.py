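"""Minimum-image geometry helpers.

The membrane normal (z) is treated as non-periodic throughout: the minimum
image convention is applied laterally (x, y) only, which is the standard
geometry for a bilayer spanning the periodic box in the membrane plane.
"""

from __future__ import annotations

import numpy as np


def min_image(d: np.ndarray, box: np.ndarray, lateral_only: bool = True) -> np.ndarray:
    """Wrap displacement vectors ``d`` (shape (..., 3)) into the minimum image."""
    d = np.array(d, dtype=float, copy=True)
    dims = (0, 1) if lateral_only else (0, 1, 2)
    for k in dims:
        L = float(box[k])
        d[..., k] -= L * np.round(d[..., k] / L)
    return d


def distance_matrix(
    a: np.ndarray,
    b: np.ndarray,
    box: np.ndarray,
    lateral_only_mi: bool = True,
    block: int = 2048,
) -> np.ndarray:
    """Full 3D distances between point sets with lateral minimum imaging."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = np.empty((len(a), len(b)))
    for i0 in range(0, len(a), block):
        d = a[i0 : i0 + block, None, :] - b[None, :, :]
        d = min_image(d, box, lateral_only=lateral_only_mi)
        out[i0 : i0 + block] = np.sqrt((d * d).sum(axis=-1))
    return out


def lateral_distance_matrix(
    a: np.ndarray, b: np.ndarray, box: np.ndarray, block: int = 4096
) -> np.ndarray:
    """In-plane (x, y) minimum-image distances between point sets."""
    a = np.asarray(a, float)[:, :2]
    b = np.asarray(b, float)[:, :2]
    out = np.empty((len(a), len(b)))
    for i0 in range(0, len(a), block):
        d = a[i0 : i0 + block, None, :] - b[None, :, :]
        for k in (0, 1):
            L = float(box[k])
            d[..., k] -= L * np.round(d[..., k] / L)
        out[i0 : i0 + block] = np.sqrt((d * d).sum(axis=-1))
    return out
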