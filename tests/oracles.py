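"""Independent brute-force reference implementations.

Everything here is deliberately written as plain-Python scans and
breadth-first traversals, independent of the scipy-based production
code, so the test suite can cross-check the two routes.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected component labeling by BFS, numbered in row-major discovery order."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    n = 0
    nrow, ncol = mask.shape
    for r0 in range(nrow):
        for c0 in range(ncol):
            if mask[r0, c0] and labels[r0, c0] == 0:
                n += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = n
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrow and 0 <= cc < ncol and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = n
                            queue.append((rr, cc))
    return labels, n


def flood3d(fg: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray:
    """3D flood fill: in-plane 4-neighbours, plus same-position and
    4-neighbour offsets across adjacent slices (in-plane L1 distance <= 1)."""
    fg = np.asarray(fg).astype(bool)
    out = np.zeros(fg.shape, dtype=bool)
    if not fg[seed]:
        return out
    offsets = [(0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for dz in (-1, 1):
        for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
            offsets.append((dz, dr, dc))
    queue = deque([seed])
    out[seed] = True
    ns, nr, nc = fg.shape
    while queue:
        z, r, c = queue.popleft()
        for dz, dr, dc in offsets:
            zz, rr, cc = z + dz, r + dr, c + dc
            if 0 <= zz < ns and 0 <= rr < nr and 0 <= cc < nc and fg[zz, rr, cc] and not out[zz, rr, cc]:
                out[zz, rr, cc] = True
                queue.append((zz, rr, cc))
    return out


def _plus_sum(mask: np.ndarray, r: int, c: int) -> int:
    """Center + 4 orthogonal neighbours, out-of-bounds counting 0."""
    nrow, ncol = mask.shape
    total = 0
    for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < nrow and 0 <= cc < ncol:
            total += int(mask[rr, cc])
    return total


def brute_erode(mask: np.ndarray) -> np.ndarray:
    """One layer removed: pixel kept iff its plus-neighbourhood sums to 5."""
    mask = np.asarray(mask).astype(np.uint8)
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if _plus_sum(mask, r, c) == 5:
                out[r, c] = 1
    return out


def brute_dilate(mask: np.ndarray) -> np.ndarray:
    """One layer added: pixel kept iff its plus-neighbourhood sums to >= 1."""
    mask = np.asarray(mask).astype(np.uint8)
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if _plus_sum(mask, r, c) >= 1:
                out[r, c] = 1
    return out


def brute_constrained_dilate(mask: np.ndarray, original: np.ndarray, steps: int) -> np.ndarray:
    """``steps`` rounds of: boundary pixels annex orthogonal neighbours
    that are foreground in ``original``."""
    current = np.asarray(mask).astype(np.uint8).copy()
    original = np.asarray(original).astype(np.uint8)
    nrow, ncol = current.shape
    for _ in range(steps):
        additions = []
        for r in range(nrow):
            for c in range(ncol):
                if current[r, c] and _plus_sum(current, r, c) < 5:
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrow and 0 <= cc < ncol and original[rr, cc] and not current[rr, cc]:
                            additions.append((rr, cc))
        for r, c in additions:
            current[r, c] = 1
    return current


def lattice_ellipsoid_count(shape, center, semi_axes) -> int:
    """Exhaustive scan counting lattice points inside an ellipsoid."""
    cz, cy, cx = center
    az, ay, ax = semi_axes
    count = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0:
                    count += 1
    return count
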