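"""Seeded 3D PET tumor phantoms with controllable texture.

A phantom is built in six steps: (1) a lobulated binary tumor mask of a
requested equivalent diameter, (2) a partition of the mask into contiguous
zones whose sizes follow a log-normal with configurable mean and CV,
(3) per-zone uptake levels spanning [0.5, 1.5] x the tumor mean,
(4) uniform background uptake, (5) Gaussian PSF blur, (6) multiplicative
Gaussian noise clamped at zero.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from pettex.image import VoxelGrid, write_image, write_mask

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor phantom.

    ``tumor_equivalent_diameter=None`` draws the diameter uniformly from
    [6, 9] mm, the size range at which flank xenografts are imaged here.
    """

    tumor_equivalent_diameter: float | None = None  # mm
    shape_irregularity: float = 0.3
    n_uptake_classes: int = 4
    zone_size_mean: float = 25.0  # voxels
    zone_size_dispersion: float = 0.5  # CV of zone sizes
    tumor_uptake_mean: float = 16.0  # %ID/g
    background_uptake: float = 2.0  # %ID/g
    psf_fwhm: float = 1.2  # mm
    noise_cv: float = 0.05
    voxel_size: float = 0.6  # mm
    seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    # percent caliper growth used to back out the baseline volume
    growth_pct_mean: float = 430.0
    growth_pct_sd: float = 120.0

    def validate(self) -> None:
        d = self.tumor_equivalent_diameter
        if d is not None and not d > 0:
            raise ValueError(f"tumor_equivalent_diameter must be > 0 mm, got {d}")
        if self.shape_irregularity < 0:
            raise ValueError("shape_irregularity must be >= 0")
        if self.n_uptake_classes < 1:
            raise ValueError("n_uptake_classes must be >= 1")
        if self.zone_size_mean < 1:
            raise ValueError(f"zone_size_mean must be >= 1 voxel, got {self.zone_size_mean}")
        if self.zone_size_dispersion < 0:
            raise ValueError("zone_size_dispersion must be >= 0")
        if not self.tumor_uptake_mean > self.background_uptake:
            raise ValueError("tumor_uptake_mean must exceed background_uptake")
        if self.background_uptake < 0:
            raise ValueError("background_uptake must be >= 0")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0 mm")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0 mm")


@dataclass
class Phantom:
    """A generated phantom: image plus generator ground truth."""

    image: VoxelGrid
    truth_mask: np.ndarray  # bool, tumor voxels before blur/noise
    truth_zone_labels: np.ndarray  # int, zone id per tumor voxel, 0 outside
    group: str = ""
    subject_id: str = ""
    baseline_volume: float = 0.0  # mm^3 (caliper analogue)
    final_volume: float = 0.0  # mm^3
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if not self.truth_mask.any():
            raise ValueError("truth_mask must be nonempty")
        on_mask = self.truth_zone_labels[self.truth_mask]
        off_mask = self.truth_zone_labels[~self.truth_mask]
        if (on_mask == 0).any() or (off_mask != 0).any():
            raise ValueError("truth_zone_labels must be nonzero exactly on truth_mask")

    @property
    def truth_volume_mm3(self) -> float:
        return int(self.truth_mask.sum()) * self.image.voxel_volume

    def zone_sizes(self) -> np.ndarray:
        """Voxel counts of the ground-truth zones."""
        labels = self.truth_zone_labels[self.truth_mask]
        return np.bincount(labels)[1:][np.bincount(labels)[1:] > 0]


def _lobulated_mask(rng: np.random.Generator, shape: tuple[int, int, int],
                    radius_vox: float, irregularity: float) -> np.ndarray:
    """Binary mask of a sphere perturbed by smoothed-noise displacement.

    The mask is thresholded on a normalized radial field so that its voxel
    count matches the target sphere volume; the equivalent diameter is
    therefore honored regardless of irregularity.
    """
    center = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    if irregularity > 0:
        noise = rng.standard_normal(shape)
        field_ = ndimage.gaussian_filter(noise, sigma=max(radius_vox / 2.0, 1.0))
        sd = field_.std()
        if sd > 0:
            field_ = (field_ - field_.mean()) / sd
        local_radius = radius_vox * (1.0 + 0.35 * irregularity * field_)
        local_radius = np.maximum(local_radius, 0.2 * radius_vox)
    else:
        local_radius = np.full(shape, radius_vox)
    rho = dist / local_radius

    target = int(round(4.0 / 3.0 * math.pi * radius_vox ** 3))
    target = max(target, 1)
    flat = np.sort(rho.ravel())
    if target >= flat.size:
        raise ValueError("tumor larger than the grid")
    thresh = flat[target - 1]
    mask = rho <= thresh
    # keep one lesion: largest 26-connected component
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def _draw_zone_sizes(n_voxels: int, mean: float, cv: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Log-normal zone-size targets scaled to sum to ``n_voxels``."""
    sizes: list[float] = []
    if cv <= 0:
        k = max(1, int(round(n_voxels / mean)))
        sizes = [n_voxels / k] * k
    else:
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        total = 0.0
        while total < n_voxels:
            s = float(rng.lognormal(mu, math.sqrt(sigma2)))
            s = max(s, 1.0)
            sizes.append(s)
            total += s
    sizes_arr = np.array(sizes)
    sizes_arr *= n_voxels / sizes_arr.sum()
    return np.maximum(sizes_arr, 1.0)


def _partition_zones(mask: np.ndarray, sizes: np.ndarray,
                     rng: np.random.Generator,
                     n_iter: int = 40, n_sweeps: int = 80) -> np.ndarray:
    """Capacity-balanced power-diagram partition of the mask into zones.

    Seeded additively-weighted Voronoi growth: weights are adapted so each
    zone's voxel count tracks its target size, then deterministic boundary
    sweeps move voxels from over-full zones to adjacent under-full ones
    until the integer targets are met (or no boundary move remains).
    Every mask voxel ends up in exactly one zone.
    """
    coords = np.argwhere(mask)
    n = len(coords)
    k = min(len(sizes), n)
    target = sizes[:k] * n / sizes[:k].sum()
    # integer targets summing to n via largest remainder
    tgt = np.floor(target).astype(int)
    rem = target - tgt
    short = n - int(tgt.sum())
    if short > 0:
        tgt[np.argsort(-rem)[:short]] += 1
    elif short < 0:  # pragma: no cover - floor never over-allocates
        tgt[np.argsort(rem)[:-short]] -= 1

    seeds = coords[rng.choice(n, size=k, replace=False)].astype(float)
    pts = coords.astype(float)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=-1)
    w = np.zeros(k)
    r2 = (3.0 * target / (4.0 * math.pi)) ** (2.0 / 3.0)
    assign = np.argmin(d2, axis=1)
    for it in range(n_iter):
        assign = np.argmin(d2 - w[None, :], axis=1)
        counts = np.bincount(assign, minlength=k)
        w += r2 * (target - counts) / target
        if it in (10, 20):  # Lloyd recentering stabilizes zone shapes
            for z in range(k):
                sel = assign == z
                if sel.any():
                    seeds[z] = pts[sel].mean(axis=0)
            d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=-1)

    labels = np.zeros(mask.shape, dtype=int)
    labels[tuple(coords.T)] = assign + 1
    counts = np.bincount(assign, minlength=k)

    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = np.array(mask.shape)
    for _ in range(n_sweeps):
        err = counts - tgt
        if not (err > 0).any():
            break
        moved = 0
        for p in coords:
            a = labels[tuple(p)] - 1
            if err[a] <= 0:
                continue
            for off in offsets:
                q = p + off
                if (q < 0).any() or (q >= shape).any():
                    continue
                b = labels[tuple(q)] - 1
                if b >= 0 and b != a and err[b] < 0:
                    labels[tuple(p)] = b + 1
                    counts[a] -= 1
                    counts[b] += 1
                    err[a] -= 1
                    err[b] += 1
                    moved += 1
                    break
        if moved == 0:
            break
    return labels


def _zone_adjacency(zones: np.ndarray, mask: np.ndarray) -> dict[int, set[int]]:
    """26-neighborhood adjacency between zone labels."""
    n_zones = int(zones.max())
    adj: dict[int, set[int]] = {z: set() for z in range(1, n_zones + 1)}
    shifts = [(dz, dy, dx) for dz in (0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
              if (dz, dy, dx) > (0, 0, 0)]
    for d in shifts:
        src = tuple(slice(max(0, -s), zones.shape[ax] - max(0, s)) for ax, s in enumerate(d))
        dst = tuple(slice(max(0, s), zones.shape[ax] + min(0, s)) for ax, s in enumerate(d))
        a, b = zones[src], zones[dst]
        ok = (a > 0) & (b > 0) & (a != b)
        for za, zb in zip(a[ok].ravel(), b[ok].ravel()):
            adj[int(za)].add(int(zb))
            adj[int(zb)].add(int(za))
    return adj


def _color_zones(zones: np.ndarray, mask: np.ndarray, n_classes: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Assign each zone an uptake-class index, avoiding equal classes on
    touching zones where the class budget allows.

    Adjacent zones sharing an uptake level would fuse into one iso-intensity
    zone after quantization, destroying the configured size distribution;
    greedy coloring in random order keeps the ground-truth zones observable.
    """
    n_zones = int(zones.max())
    if n_classes == 1:
        return np.zeros(n_zones, dtype=int)
    adj = _zone_adjacency(zones, mask)
    color = -np.ones(n_zones + 1, dtype=int)
    for z in rng.permutation(np.arange(1, n_zones + 1)):
        taken = {color[nb] for nb in adj[int(z)] if color[nb] >= 0}
        free = [c for c in range(n_classes) if c not in taken]
        if free:
            color[z] = free[rng.integers(0, len(free))]
        else:  # no conflict-free class: pick the least-used among neighbors
            counts = np.bincount([color[nb] for nb in adj[int(z)] if color[nb] >= 0],
                                 minlength=n_classes)
            color[z] = int(np.argmin(counts))
    return color[1:]


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom deterministically from its spec (see module doc)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    diameter = spec.tumor_equivalent_diameter
    if diameter is None:
        diameter = float(rng.uniform(6.0, 9.0))
    radius_vox = diameter / 2.0 / spec.voxel_size

    if spec.grid_shape is not None:
        shape = tuple(int(s) for s in spec.grid_shape)
        extent = 2.0 * radius_vox * (1.0 + 0.35 * spec.shape_irregularity)
        for ax, s in enumerate(shape):
            if extent > s:
                raise ValueError(
                    f"tumor extent {extent:.1f} voxels exceeds grid axis {ax} (size {s})")
    else:
        margin = max(5, int(math.ceil(3.0 / spec.voxel_size)))
        side = int(math.ceil(2.0 * radius_vox * (1.0 + 0.35 * spec.shape_irregularity))) + 2 * margin
        shape = (side, side, side)

    mask = _lobulated_mask(rng, shape, radius_vox, spec.shape_irregularity)
    n_vox = int(mask.sum())

    sizes = _draw_zone_sizes(n_vox, spec.zone_size_mean, spec.zone_size_dispersion, rng)
    zones = _partition_zones(mask, sizes, rng)
    n_zones = int(zones.max())

    if spec.n_uptake_classes == 1:
        levels = np.array([spec.tumor_uptake_mean])
    else:
        levels = np.linspace(0.5, 1.5, spec.n_uptake_classes) * spec.tumor_uptake_mean
    zone_class = _color_zones(zones, mask, spec.n_uptake_classes, rng)
    zone_level = levels[zone_class]

    img = np.full(shape, float(spec.background_uptake))
    img[mask] = zone_level[zones[mask] - 1]

    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * _FWHM_TO_SIGMA / spec.voxel_size
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if spec.noise_cv > 0:
        img = img * (1.0 + spec.noise_cv * rng.standard_normal(shape))
    np.clip(img, 0.0, None, out=img)

    final_volume = n_vox * spec.voxel_size ** 3
    growth = float(rng.normal(spec.growth_pct_mean, spec.growth_pct_sd))
    growth = max(growth, -90.0)
    baseline_volume = final_volume / (1.0 + growth / 100.0)

    return Phantom(
        image=VoxelGrid(values=img, spacing=spec.voxel_size),
        truth_mask=mask,
        truth_zone_labels=zones,
        baseline_volume=baseline_volume,
        final_volume=final_volume,
        spec=spec,
    )


def generate_cohort(n_treated: int, n_control: int, treated_spec: PhantomSpec,
                    control_spec: PhantomSpec, seed: int) -> list[Phantom]:
    """Generate a two-arm cohort; per-subject seeds derive from ``seed``."""
    if n_treated < 1 or n_control < 1:
        raise ValueError("both arms need at least one subject")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_treated + n_control)
    phantoms: list[Phantom] = []
    for i in range(n_treated):
        ph = generate_phantom(replace(treated_spec, seed=int(child_seeds[i])))
        ph.group = "treated"
        ph.subject_id = f"T{i + 1:02d}"
        phantoms.append(ph)
    for i in range(n_control):
        ph = generate_phantom(replace(control_spec, seed=int(child_seeds[n_treated + i])))
        ph.group = "control"
        ph.subject_id = f"C{i + 1:02d}"
        phantoms.append(ph)
    return phantoms


def fixture_spec(seed: int = 7) -> PhantomSpec:
    """The repository's reference phantom: 6 mm sphere, 1.2 mm PSF, 5% noise."""
    return PhantomSpec(tumor_equivalent_diameter=6.0, shape_irregularity=0.0,
                       n_uptake_classes=3, zone_size_mean=25.0,
                       zone_size_dispersion=0.5, psf_fwhm=1.2, noise_cv=0.05,
                       seed=seed)


def fine_texture_spec() -> PhantomSpec:
    """Treated-arm analogue: small, uniformly sized uptake zones."""
    return PhantomSpec(tumor_equivalent_diameter=8.0, shape_irregularity=0.0,
                       n_uptake_classes=16, zone_size_mean=4.0,
                       zone_size_dispersion=0.05, psf_fwhm=0.0, noise_cv=0.005)


def coarse_texture_spec() -> PhantomSpec:
    """Control-arm analogue: larger, size-dispersed uptake zones; matched
    volume, shape and mean uptake with :func:`fine_texture_spec`."""
    return PhantomSpec(tumor_equivalent_diameter=8.0, shape_irregularity=0.0,
                       n_uptake_classes=16, zone_size_mean=12.0,
                       zone_size_dispersion=0.5, psf_fwhm=0.0, noise_cv=0.005)


def write_phantom(ph: Phantom, out_dir: str) -> dict[str, str]:
    """Write image + truth mask as NIfTI and a CSV sidecar; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    sid = ph.subject_id or "subject"
    img_path = os.path.join(out_dir, f"{sid}_pet.nii.gz")
    mask_path = os.path.join(out_dir, f"{sid}_truth.nii.gz")
    csv_path = os.path.join(out_dir, f"{sid}_meta.csv")
    write_image(ph.image, img_path)
    write_mask(ph.truth_mask.astype(int), ph.image.spacing, mask_path)
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group", "baseline_volume_mm3",
                    "final_volume_mm3", "seed"])
        w.writerow([sid, ph.group, f"{ph.baseline_volume:.6g}",
                    f"{ph.final_volume:.6g}", ph.spec.seed if ph.spec else ""])
    return {"image": img_path, "mask": mask_path, "sidecar": csv_path}
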