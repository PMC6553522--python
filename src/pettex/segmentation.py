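"""Fuzzy, spatially adaptive 3-class Bayesian tumor delineation.

Voxels inside a bounding volume are classified as background, partial-volume
or tumor by a deterministic EM-style scheme: Gaussian intensity classes for
background and tumor, the partial-volume class pinned to a convex mixture
level between them, and a locally adaptive prior computed from each voxel's
26-neighborhood memberships.  The VOI keeps tumor and partial-volume voxels
(only background is discarded), reduced to the largest 26-connected
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from pettex.image import TumorVOI, VoxelGrid

BACKGROUND, PARTIAL_VOLUME, TUMOR = 0, 1, 2
CLASS_NAMES = ("background", "partial_volume", "tumor")

# convex mixture weight of the tumor mean in the partial-volume level
_PV_ALPHA = 0.7
# weight of the 26-neighborhood membership average in the spatial prior
_SPATIAL_BETA = 0.6
_VAR_FLOOR_REL = 1e-3  # stddev floor, relative to intensity range

_KERNEL26 = np.ones((3, 3, 3))
_KERNEL26[1, 1, 1] = 0.0


@dataclass
class BoundingVolume:
    """A VoxelGrid plus an inclusive per-axis index box (0-based)."""

    grid: VoxelGrid
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.box is None:
            self.box = tuple((0, s - 1) for s in self.grid.shape)
        box = tuple(tuple(int(v) for v in ax) for ax in self.box)
        n = 1
        for ax, (lo, hi) in enumerate(box):
            if lo < 0 or hi >= self.grid.shape[ax] or lo > hi:
                raise ValueError(f"box axis {ax} range ({lo}, {hi}) outside grid "
                                 f"of shape {self.grid.shape}")
            n *= hi - lo + 1
        if n < 27:
            raise ValueError(f"bounding box must enclose >= 27 voxels, got {n}")
        self.box = box

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi + 1) for lo, hi in self.box)

    def subvolume(self) -> np.ndarray:
        return self.grid.values[self.slices]


@dataclass
class ClassLabeling:
    """Per-voxel hard class and membership triple over a bounding box."""

    hard_label: np.ndarray  # int in {0, 1, 2}, box-shaped
    memberships: np.ndarray  # (..., 3), rows sum to 1

    def __post_init__(self) -> None:
        sums = self.memberships.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("memberships must sum to 1 per voxel")


def _hard_from_memberships(m: np.ndarray) -> np.ndarray:
    """Argmax class; exact ties resolve to partial_volume."""
    hard = np.argmax(m, axis=-1)
    mx = m.max(axis=-1)
    tied = (np.isclose(m, mx[..., None], rtol=0.0, atol=0.0).sum(axis=-1)) > 1
    hard[tied] = PARTIAL_VOLUME
    return hard


def segment_flab(bv: BoundingVolume, max_iter: int = 100, tol: float = 1e-4) -> ClassLabeling:
    """Classify bounding-volume voxels into background/partial-volume/tumor.

    Deterministic: initialization is a 2-level Otsu threshold, not random.
    Iterates membership updates until the largest change is below ``tol``
    or ``max_iter`` is reached.
    """
    x = bv.subvolume().astype(float)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        raise ValueError("degenerate intensity distribution")
    scale = hi - lo
    var_floor = (_VAR_FLOOR_REL * scale) ** 2

    t0 = threshold_otsu(x)
    m = np.zeros(x.shape + (3,))
    m[..., TUMOR] = 0.9 * (x > t0)
    m[..., BACKGROUND] = 0.9 * (x <= t0)
    m[..., PARTIAL_VOLUME] = 0.1  # keep the class alive at initialization

    ones = np.ones(x.shape)
    nb_norm = ndimage.convolve(ones, _KERNEL26, mode="constant")

    for _ in range(max_iter):
        w = m.sum(axis=(0, 1, 2)) + 1e-12
        mu_b = float((m[..., BACKGROUND] * x).sum() / w[BACKGROUND])
        mu_t = float((m[..., TUMOR] * x).sum() / w[TUMOR])
        if mu_t < mu_b:  # keep tumor as the hot class
            mu_b, mu_t = mu_t, mu_b
            m = m[..., ::-1].copy()
            w = w[::-1]
        mu_pv = _PV_ALPHA * mu_t + (1.0 - _PV_ALPHA) * mu_b
        mus = np.array([mu_b, mu_pv, mu_t])
        # one pooled variance shared by the classes: per-class variances let
        # the hot class inflate and swallow the blur halo
        var = max(
            float(sum(((m[..., c] * (x - mus[c]) ** 2).sum() for c in range(3)))
                  / w.sum()),
            var_floor,
        )

        # locally adaptive prior: blend of global proportions and the
        # 26-neighborhood membership average
        glob = w / w.sum()
        prior = np.empty_like(m)
        for c in range(3):
            nb = ndimage.convolve(m[..., c], _KERNEL26, mode="constant") / nb_norm
            prior[..., c] = (1.0 - _SPATIAL_BETA) * glob[c] + _SPATIAL_BETA * nb
        prior = np.clip(prior, 1e-6, None)
        prior /= prior.sum(axis=-1, keepdims=True)

        # Gaussian log-likelihoods, stabilized before exponentiation
        loglik = np.empty_like(m)
        for c in range(3):
            loglik[..., c] = -0.5 * (x - mus[c]) ** 2 / var
        loglik -= loglik.max(axis=-1, keepdims=True)
        post = prior * np.exp(loglik)
        post /= post.sum(axis=-1, keepdims=True)

        delta = float(np.abs(post - m).max())
        m = post
        if delta < tol:
            break

    m = m / m.sum(axis=-1, keepdims=True)
    return ClassLabeling(hard_label=_hard_from_memberships(m), memberships=m)


def extract_voi(labeling: ClassLabeling, bv: BoundingVolume) -> TumorVOI:
    """VOI = non-background voxels, largest 26-connected component kept.

    Interior background-labeled voxels are reclaimed (hole filling): a
    closed tumor volume is assumed, and stray interior misclassifications
    would otherwise punch holes into the texture lattice.
    """
    keep = labeling.hard_label != BACKGROUND
    if not keep.any():
        raise ValueError("no tumor detected")
    labels, n = ndimage.label(keep, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = labels == (int(np.argmax(sizes)) + 1)
    keep = ndimage.binary_fill_holes(keep)
    coords = np.argwhere(keep)
    offset = np.array([lo for lo, _ in bv.box])
    sub = bv.subvolume()
    return TumorVOI(coords=coords + offset, values=sub[keep], spacing=bv.grid.spacing)
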