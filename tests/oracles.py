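"""Naive reference implementations used to cross-check the texture engine.

Everything here is written as plain loops over voxels, independent of the
vectorized builders in the package.
"""

from __future__ import annotations

import numpy as np

DIRS13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _in(grid, p):
    return all(0 <= p[a] < grid.shape[a] for a in range(3)) and grid[p] > 0


def oracle_glcm(grid: np.ndarray, ng: int) -> np.ndarray:
    counts = np.zeros((ng, ng))
    for p in zip(*np.nonzero(grid)):
        for d in DIRS13:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in(grid, q):
                counts[grid[p] - 1, grid[q] - 1] += 1
                counts[grid[q] - 1, grid[p] - 1] += 1
    return counts / counts.sum() if counts.sum() else counts


def oracle_glrlm(grid: np.ndarray, ng: int) -> np.ndarray:
    rmax = max(grid.shape)
    out = np.zeros((ng, rmax))
    for d in DIRS13:
        for p in zip(*np.nonzero(grid)):
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _in(grid, prev) and grid[prev] == grid[p]:
                continue  # not a run start
            length, q = 1, p
            while True:
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                if _in(grid, q) and grid[q] == grid[p]:
                    length += 1
                else:
                    break
            out[grid[p] - 1, length - 1] += 1
    return out


def oracle_glszm(grid: np.ndarray, ng: int) -> np.ndarray:
    smax = int((grid > 0).sum())
    out = np.zeros((ng, smax))
    seen = np.zeros(grid.shape, dtype=bool)
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for p in zip(*np.nonzero(grid)):
        if seen[p]:
            continue
        stack, zone = [p], []
        seen[p] = True
        while stack:
            u = stack.pop()
            zone.append(u)
            for d in offs:
                v = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if _in(grid, v) and not seen[v] and grid[v] == grid[p]:
                    seen[v] = True
                    stack.append(v)
        out[grid[p] - 1, len(zone) - 1] += 1
    return out


def oracle_ngtdm(grid: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    s = np.zeros(ng)
    n = np.zeros(ng)
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for p in zip(*np.nonzero(grid)):
        nbs = [grid[(p[0] + d[0], p[1] + d[1], p[2] + d[2])]
               for d in offs if _in(grid, (p[0] + d[0], p[1] + d[1], p[2] + d[2]))]
        if not nbs:
            continue
        s[grid[p] - 1] += abs(grid[p] - sum(nbs) / len(nbs))
        n[grid[p] - 1] += 1
    return s, n


def random_label_grid(rng: np.random.Generator, max_side: int = 6, ng: int = 8,
                      p_fill: float | None = None) -> np.ndarray:
    """Random small VOI as a dense bin grid (0 outside)."""
    shape = tuple(rng.integers(1, max_side + 1, size=3))
    p = p_fill if p_fill is not None else rng.uniform(0.3, 0.9)
    mask = rng.random(shape) < p
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    grid = np.where(mask, rng.integers(1, ng + 1, size=shape), 0)
    return grid
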