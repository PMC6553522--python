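"""Gray-level quantization and the four 3D texture matrices.

Conventions (config-overridable): the 13 unique lattice directions at
Chebyshev distance 1 for GLCM and GLRLM, aggregation by summation across
directions, 26-connectivity for GLSZM zones and NGTDM neighborhoods.
Out-of-VOI neighbors are excluded, never padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pettex.image import TumorVOI

#: The 13 unique 3D lattice directions at Chebyshev distance 1 (half of the
#: 26-neighborhood; the other half are their negatives).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MatrixConfig:
    """Lattice conventions used by the matrix builders."""

    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
    distance: int = 1
    connectivity: int = 26  # 6 or 26, for GLSZM zones and NGTDM neighborhoods

    def structure(self) -> np.ndarray:
        if self.connectivity == 26:
            return _STRUCT26
        if self.connectivity == 6:
            return _STRUCT6
        raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")


@dataclass
class QuantizedVOI:
    """VOI with per-voxel bin index in [1, Ng] over equally sized bins."""

    coords: np.ndarray  # (N, 3)
    bins: np.ndarray  # (N,) int in [1, Ng]
    Ng: int
    bin_edges: np.ndarray  # (Ng + 1,) uptake values
    spacing: float

    def __len__(self) -> int:
        return len(self.coords)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (bin grid with 0 outside the VOI, offset) over the bounding box."""
        offset = self.coords.min(axis=0)
        shape = self.coords.max(axis=0) - offset + 1
        grid = np.zeros(shape, dtype=int)
        grid[tuple((self.coords - offset).T)] = self.bins
        return grid, offset


@dataclass
class TextureMatrixSet:
    """GLCM, GLRLM, GLSZM and NGTDM built from one quantized VOI."""

    glcm: np.ndarray  # Ng x Ng, normalized to sum 1, symmetric
    glrlm: np.ndarray  # Ng x Rmax counts
    glszm: np.ndarray  # Ng x Smax counts
    ngtdm_s: np.ndarray  # (Ng,) per-level absolute-difference sums
    ngtdm_n: np.ndarray  # (Ng,) per-level contributing-voxel counts
    config: MatrixConfig = field(default_factory=MatrixConfig)


def quantize(voi: TumorVOI, Ng: int = 64) -> QuantizedVOI:
    """Quantize VOI uptake into ``Ng`` equally sized bins over its min-max range.

    bin(x) = min(Ng, 1 + floor(Ng * (x - min) / (max - min))); a constant VOI
    maps every voxel to bin 1.
    """
    if Ng < 2:
        raise ValueError(f"Ng must be >= 2, got {Ng}")
    x = voi.values
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        bins = np.minimum(Ng, 1 + np.floor(Ng * (x - lo) / (hi - lo)).astype(int))
    else:
        bins = np.ones(len(x), dtype=int)
    edges = np.linspace(lo, hi, Ng + 1)
    return QuantizedVOI(coords=voi.coords.copy(), bins=bins, Ng=Ng,
                        bin_edges=edges, spacing=voi.spacing)


def _pair_slices(d: tuple[int, int, int], shape: tuple[int, ...],
                 distance: int = 1):
    """Slices (src, dst) such that grid[dst] sits at offset d*distance from grid[src]."""
    src, dst = [], []
    for step, size in zip(d, shape):
        step = step * distance
        if step > 0:
            src.append(slice(0, size - step))
            dst.append(slice(step, size))
        elif step < 0:
            src.append(slice(-step, size))
            dst.append(slice(0, size + step))
        else:
            src.append(slice(0, size))
            dst.append(slice(0, size))
    return tuple(src), tuple(dst)


def build_glcm(q: QuantizedVOI, config: MatrixConfig | None = None) -> np.ndarray:
    """Symmetrized, direction-aggregated, normalized co-occurrence matrix."""
    config = config or MatrixConfig()
    grid, _ = q.to_dense()
    counts = np.zeros((q.Ng, q.Ng), dtype=float)
    for d in config.directions:
        src, dst = _pair_slices(d, grid.shape, config.distance)
        a, b = grid[src], grid[dst]
        ok = (a > 0) & (b > 0)
        ai, bi = a[ok] - 1, b[ok] - 1
        np.add.at(counts, (ai, bi), 1.0)
        np.add.at(counts, (bi, ai), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurrences: VOI has no neighboring voxel pairs")
    return counts / total


def build_glrlm(q: QuantizedVOI, config: MatrixConfig | None = None) -> np.ndarray:
    """Run-length counts aggregated (summed) over the direction set."""
    config = config or MatrixConfig()
    grid, _ = q.to_dense()
    rmax = max(grid.shape)
    out = np.zeros((q.Ng, rmax), dtype=float)
    inside = grid > 0
    for d in config.directions:
        # a voxel starts a run if its predecessor along d is outside the VOI
        # or carries a different bin
        pred_same = np.zeros(grid.shape, dtype=bool)
        src, dst = _pair_slices(d, grid.shape)
        pred_same[dst] = inside[src] & (grid[src] == grid[dst])
        starts = np.argwhere(inside & ~pred_same)
        if len(starts) == 0:
            continue
        gray = grid[tuple(starts.T)]
        length = np.ones(len(starts), dtype=int)
        pos = starts.copy()
        active = np.arange(len(starts))
        dv = np.array(d)
        while len(active):
            nxt = pos[active] + dv
            ok = np.all((nxt >= 0) & (nxt < grid.shape), axis=1)
            idx = active[ok]
            nxt = nxt[ok]
            same = grid[tuple(nxt.T)] == gray[idx]
            idx = idx[same]
            if len(idx) == 0:
                break
            pos[idx] += dv
            length[idx] += 1
            active = idx
        np.add.at(out, (gray - 1, length - 1), 1.0)
    return out


def build_glszm(q: QuantizedVOI, config: MatrixConfig | None = None) -> np.ndarray:
    """Zone counts: glszm[i, s] = number of connected zones of level i+1, size s+1."""
    config = config or MatrixConfig()
    grid, _ = q.to_dense()
    smax = len(q)
    out = np.zeros((q.Ng, smax), dtype=float)
    structure = config.structure()
    for level in np.unique(q.bins):
        labels, n = ndimage.label(grid == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            out[level - 1, s - 1] += 1.0
    return out


def build_ngtdm(q: QuantizedVOI, config: MatrixConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-level sums s_i of |bin - neighborhood mean| and counts n_i.

    A voxel contributes iff it has at least one in-VOI neighbor; the
    neighborhood mean excludes the voxel itself and out-of-VOI positions.
    """
    config = config or MatrixConfig()
    grid, _ = q.to_dense()
    inside = grid > 0
    kernel = config.structure().astype(float).copy()
    kernel[tuple(s // 2 for s in kernel.shape)] = 0.0
    nb_sum = ndimage.convolve(grid.astype(float) * inside, kernel, mode="constant")
    nb_cnt = ndimage.convolve(inside.astype(float), kernel, mode="constant")
    valid = inside & (nb_cnt > 0.5)
    diffs = np.abs(grid[valid] - nb_sum[valid] / nb_cnt[valid])
    levels = grid[valid] - 1
    s_i = np.bincount(levels, weights=diffs, minlength=q.Ng).astype(float)
    n_i = np.bincount(levels, minlength=q.Ng).astype(float)
    return s_i, n_i


def build_all(q: QuantizedVOI, config: MatrixConfig | None = None) -> TextureMatrixSet:
    """Build all four matrices with one shared convention set."""
    config = config or MatrixConfig()
    s_i, n_i = build_ngtdm(q, config)
    return TextureMatrixSet(
        glcm=build_glcm(q, config),
        glrlm=build_glrlm(q, config),
        glszm=build_glszm(q, config),
        ngtdm_s=s_i,
        ngtdm_n=n_i,
        config=config,
    )
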