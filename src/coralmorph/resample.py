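"""Exact nearest-neighbour resampling between image frames.

Frame changes (original acquisition frame <-> fixed model frames) use a
pixel-center nearest-neighbour rule computed in integer arithmetic:
destination index j in a d-long axis reads source index

    floor(((2*j + 1) * s) / (2*d))

for a s-long source axis.  This is the nearest source pixel center under
the continuous convention that pixel i occupies [i, i+1).  Computing it
with integer floor division makes the mapping bit-exact, and the
up-then-down round trip through any frame at least as large as the
original reproduces the original array exactly — which is what keeps
binary masks binary and lets a zero-error backend chain stay a strict
identity end to end.
"""

from __future__ import annotations

import numpy as np

__all__ = ["resize_nearest", "axis_index_map"]


def axis_index_map(src: int, dst: int) -> np.ndarray:
    """Source index for each destination index along one axis."""
    j = np.arange(dst, dtype=np.int64)
    return ((2 * j + 1) * src) // (2 * dst)


def resize_nearest(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize the first two axes of ``arr`` to ``shape`` (rows, cols).

    Works for 2-D masks/grayscale and 3-D channel-last images; dtype is
    preserved.  A same-shape call returns a copy.
    """
    out_h, out_w = int(shape[0]), int(shape[1])
    if out_h <= 0 or out_w <= 0:
        raise ValueError("target shape must be positive")
    in_h, in_w = arr.shape[0], arr.shape[1]
    if (in_h, in_w) == (out_h, out_w):
        return arr.copy()
    rows = axis_index_map(in_h, out_h)
    cols = axis_index_map(in_w, out_w)
    return arr[np.ix_(rows, cols)]
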