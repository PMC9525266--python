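"""Shared structuring elements and exact windowed filters."""

from __future__ import annotations

import numpy as np

__all__ = ["elliptical_footprint", "binary_median"]


def elliptical_footprint(size: int) -> np.ndarray:
    """Boolean elliptical (here: circular) structuring element of odd ``size``.

    A point (dx, dy) from the center belongs to the footprint when
    (dx/r)^2 + (dy/r)^2 <= 1 with r = size // 2; for size 5 this is the
    familiar cross-plus-diagonals ellipse.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("footprint size must be odd and positive")
    r = size // 2
    if r == 0:
        return np.ones((1, 1), bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx / r) ** 2 + (yy / r) ** 2 <= 1.0 + 1e-12


def binary_median(mask: np.ndarray, size: int) -> np.ndarray:
    """Exact majority-vote median of a boolean mask over a size x size window.

    Borders are handled by edge replication. Counting uses an integral image,
    so the result is exact (no float threshold wobble); for an odd window the
    vote cannot tie.
    """
    if size % 2 == 0:
        raise ValueError("median window size must be odd")
    r = size // 2
    padded = np.pad(mask.astype(np.int64), r, mode="edge")
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), np.int64)
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=ii[1:, 1:])
    h, w = mask.shape
    # window sum at (y, x) covers padded[y : y+size, x : x+size]
    counts = ii[size:, size:] - ii[:-size, size:] - ii[size:, :-size] + ii[:-size, :-size]
    counts = counts[:h, :w]
    return counts * 2 > size * size
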