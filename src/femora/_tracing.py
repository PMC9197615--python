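"""Ordered boundary extraction for binary section masks.

Moore-neighbour contour following with Jacob's stopping criterion.  No
installed imaging library exposes an *ordered pixel-level* boundary walk
(``skimage.measure.find_contours`` returns sub-pixel crack contours), so the
classic algorithm is implemented here directly.
"""

from __future__ import annotations

import numpy as np

# clockwise Moore neighbourhood, starting north, as (row, col) offsets
_OFFSETS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_DIR_INDEX = {off: i for i, off in enumerate(_OFFSETS)}


def moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the 8-connected object in ``mask``.

    Parameters
    ----------
    mask
        2-D boolean array containing a single 8-connected foreground object.

    Returns
    -------
    ndarray of shape (n, 2)
        Pixel (row, col) coordinates in clockwise order.  Pixels on thin
        spurs may appear more than once; consecutive entries (cyclically)
        are 8-adjacent, so the walk is a closed loop.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask is empty")
    if rows.size == 1:
        return np.array([[rows[0], cols[0]]], dtype=np.intp)

    padded = np.pad(mask, 1)
    # start pixel: topmost, then leftmost -> its W, NW and N neighbours are
    # guaranteed background, so a west backtrack is always valid
    r0 = rows.min()
    c0 = cols[rows == r0].min()
    start = (int(r0) + 1, int(c0) + 1)

    cur = start
    bdir = 6  # direction from ``cur`` to the backtrack (background) cell
    path = [start]
    first_state = None
    for _ in range(8 * rows.size + 8):
        # scan the Moore ring clockwise, starting just after the backtrack
        for k in range(1, 9):
            d = (bdir + k) % 8
            nr = cur[0] + _OFFSETS[d][0]
            nc = cur[1] + _OFFSETS[d][1]
            if padded[nr, nc]:
                break
        else:  # no foreground neighbour: isolated pixel (handled above)
            break
        # cell scanned immediately before the hit is background and becomes
        # the new backtrack; express its direction from the new pixel
        prev_d = (bdir + k - 1) % 8
        bg = (cur[0] + _OFFSETS[prev_d][0], cur[1] + _OFFSETS[prev_d][1])
        nxt = (nr, nc)
        state = (nxt, _DIR_INDEX[(bg[0] - nxt[0], bg[1] - nxt[1])])
        if first_state is None:
            first_state = state
        elif state == first_state:
            break  # deterministic walk re-entered its first state: closed
        path.append(nxt)
        cur, bdir = nxt, state[1]
    else:
        raise RuntimeError("boundary trace failed to terminate")

    out = np.array(path, dtype=np.intp) - 1  # undo padding
    if len(out) > 1 and np.array_equal(out[0], out[-1]):
        out = out[:-1]
    return out


def inner_boundary(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of foreground pixels with a 4-connected background
    neighbour (the one-pixel "surface" layer used for point counting)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return mask & ~interior


def ordered_surface_points(mask: np.ndarray) -> np.ndarray:
    """Ordered (row, col) coordinates of the 4-boundary surface layer.

    The Moore walk is filtered to pixels that expose a 4-connected face to
    the background; for the smooth, speck-free shapes produced by cortical
    segmentation the filtered sequence remains a closed 8-connected loop.
    Spur revisits are dropped (first visit kept).
    """
    trace = moore_trace(mask)
    surf = inner_boundary(mask)
    keep = surf[trace[:, 0], trace[:, 1]]
    pts = trace[keep]
    _, idx = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(idx)]
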