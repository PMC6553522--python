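"""The 114-feature catalog: geometric, fractal, first-, second- and
higher-order texture features of one tumor VOI.

Definitions follow the classical radiomics literature (Haralick co-occurrence
set, Galloway/extended run-length set, Thibault size-zone set, Amadasun-King
gray-tone-difference set).  The roster is pinned in ``data/features.yaml``
and the extractor refuses to emit anything that deviates from it.

Degenerate inputs never yield NaN: correlation-type features on
zero-variance input return 0, coarseness on a flat neighborhood is capped at
1e6, and fractal features of VOIs too small for the scaling fit return 0.
All sentinels are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from pettex.image import TumorVOI
from pettex.matrices import MatrixConfig, QuantizedVOI, build_all, quantize

log = logging.getLogger(__name__)

CATEGORY_COUNTS = {
    "geometric": 15,
    "model_based": 6,
    "first_order": 37,
    "second_order": 21,
    "higher_order": 35,
}

_COARSENESS_CAP = 1e6


def feature_manifest() -> list[dict]:
    """Load the pinned feature roster (name, category, unit)."""
    with resources.files("pettex").joinpath("data/features.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return doc["features"]


@dataclass
class FeatureConfig:
    """Knobs of the extraction pipeline."""

    Ng: int = 64
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    # which GLSZM size-zone-variability form carries the reported name
    szv_reported: str = "glszm_szv_var"  # or "glszm_szv_nu"


@dataclass
class FeatureVector:
    """Ordered 114-entry measurement of one tumor."""

    values: dict[str, float]
    category: dict[str, str]
    units: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.values) != 114:
            raise ValueError(f"expected 114 features, got {len(self.values)}")
        tally: dict[str, int] = {}
        for name in self.values:
            tally[self.category[name]] = tally.get(self.category[name], 0) + 1
        if tally != CATEGORY_COUNTS:
            raise ValueError(f"category partition {tally} != {CATEGORY_COUNTS}")
        bad = [k for k, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# --------------------------------------------------------------------------
# geometric


def _surface_faces(mask: np.ndarray) -> int:
    """Count voxel faces exposed to the outside."""
    faces = 0
    padded = np.pad(mask, 1)
    for ax in range(3):
        for sgn in (1, -1):
            shifted = np.roll(padded, sgn, axis=ax)
            faces += int((padded & ~shifted).sum())
    return faces


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~eroded)


def geometric_features(voi: TumorVOI) -> dict[str, float]:
    """15 morphology descriptors of the VOI voxel set."""
    sp = voi.spacing
    mask, _, _ = voi.to_dense()
    n = len(voi)
    vol = n * sp ** 3
    area = _surface_faces(mask) * sp ** 2
    r_eq = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)

    surf = _surface_voxels(mask)
    centroid = voi.coords.mean(axis=0)
    surf_global = surf + voi.coords.min(axis=0)
    csd = float(np.linalg.norm((surf_global - centroid) * sp, axis=1).mean())

    # maximum pairwise distance between surface voxel centers
    if len(surf) == 1:
        max_diam = 0.0
    else:
        pts = surf_global * sp
        d2max = 0.0
        for i in range(len(pts) - 1):
            d2 = ((pts[i + 1:] - pts[i]) ** 2).sum(axis=1).max()
            d2max = max(d2max, float(d2))
        max_diam = math.sqrt(d2max)

    if n >= 2:
        cov = np.cov((voi.coords * sp).T)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    else:
        eig = np.zeros(3)
    axes = 4.0 * np.sqrt(eig)
    if eig[0] > 0:
        elongation = math.sqrt(eig[1] / eig[0])
        flatness = math.sqrt(eig[2] / eig[0])
    else:
        log.debug("degenerate principal axes; elongation/flatness sentinel 1")
        elongation = flatness = 1.0

    return {
        "vol_met": vol,
        "surface_area": area,
        "surface_to_volume_ratio": area / vol,
        "sphericity": math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area,
        "compactness1": vol / (math.sqrt(math.pi) * area ** 1.5),
        "compactness2": 36.0 * math.pi * vol ** 2 / area ** 3,
        "spherical_disproportion": area / (4.0 * math.pi * r_eq ** 2),
        "max_3d_diameter": max_diam,
        "equivalent_spherical_diameter": 2.0 * r_eq,
        "major_axis_length": float(axes[0]),
        "minor_axis_length": float(axes[1]),
        "least_axis_length": float(axes[2]),
        "elongation": elongation,
        "flatness": flatness,
        "centroid_surface_distance_mean": csd,
    }


# --------------------------------------------------------------------------
# model-based (fractal)


def _fit_slope(log_inv_size: np.ndarray, log_count: np.ndarray) -> float:
    return float(np.polyfit(log_inv_size, log_count, 1)[0])


def _block_reduce(arr: np.ndarray, s: int, how: str) -> np.ndarray:
    """Reduce an array over s^3 blocks (last partial blocks included)."""
    pads = [(0, (-arr.shape[ax]) % s) for ax in range(3)]
    if how == "any":
        a = np.pad(arr, pads, constant_values=False)
    elif how == "max":
        a = np.pad(arr, pads, constant_values=-np.inf)
    else:
        a = np.pad(arr, pads, constant_values=np.inf)
    shp = (a.shape[0] // s, s, a.shape[1] // s, s, a.shape[2] // s, s)
    a = a.reshape(shp)
    op = {"any": np.max, "max": np.max, "min": np.min}[how]
    return op(a, axis=(1, 3, 5))


def mask_fractal_dimension(mask: np.ndarray, sizes=(1, 2, 4, 8)) -> float:
    """Box-counting dimension of the binary mask over the given box sizes.

    Boxes are anchored at the mask's bounding-box corner; anchoring on a
    padded grid would misalign boxes and bias the slope down.
    """
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    mask = mask[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]
    counts = []
    for s in sizes:
        occ = _block_reduce(mask.astype(float), s, "any") > 0
        counts.append(int(occ.sum()))
    return _fit_slope(np.log(1.0 / np.array(sizes, float)), np.log(np.array(counts, float)))


def _dbc_counts(grid: np.ndarray, inside: np.ndarray, s: int, height_scale: float) -> float:
    """Differential box-count N(s): per occupied block, intensity column count."""
    bmax = _block_reduce(np.where(inside, grid, -np.inf), s, "max")
    bmin = _block_reduce(np.where(inside, grid, np.inf), s, "min")
    occ = np.isfinite(bmax)
    h = s * height_scale
    nr = np.floor((bmax[occ] - bmin[occ]) / h) + 1.0
    return float(nr.sum())


def intensity_fractal_dimension(q_grid: np.ndarray, inside: np.ndarray, Ng: int,
                                sizes=(2, 4, 8)) -> float:
    """Differential box-counting dimension of the quantized intensity surface."""
    L = max(q_grid.shape)
    counts = np.array([_dbc_counts(q_grid, inside, s, Ng / L) for s in sizes])
    return _fit_slope(np.log(1.0 / np.array(sizes, float)), np.log(counts))


def _local_fd_map(q_grid: np.ndarray, inside: np.ndarray, Ng: int) -> np.ndarray:
    """Differential box-count FD in every 5^3 window fully inside the VOI."""
    w = 5
    if min(inside.shape) < w:
        return np.array([])
    centers = ndimage.binary_erosion(inside, structure=np.ones((w, w, w)))
    if not centers.any():
        return np.array([])
    wins = sliding_window_view(q_grid.astype(float), (w, w, w))
    sel = wins[centers[2:-2, 2:-2, 2:-2]]  # (M, 5, 5, 5), all voxels in VOI

    sizes = (1, 2, 4)
    edges = {1: [0, 1, 2, 3, 4, 5], 2: [0, 2, 4, 5], 4: [0, 4, 5]}
    logN = []
    for s in sizes:
        h = s * Ng / w
        e = edges[s]
        total = np.zeros(sel.shape[0])
        for a in range(len(e) - 1):
            for b in range(len(e) - 1):
                for c in range(len(e) - 1):
                    blk = sel[:, e[a]:e[a + 1], e[b]:e[b + 1], e[c]:e[c + 1]]
                    rng = blk.max(axis=(1, 2, 3)) - blk.min(axis=(1, 2, 3))
                    total += np.floor(rng / h) + 1.0
        logN.append(np.log(total))
    x = np.log(1.0 / np.array(sizes, float))
    y = np.stack(logN, axis=1)  # (M, 3)
    xc = x - x.mean()
    slopes = (y * xc).sum(axis=1) / (xc ** 2).sum()
    return slopes


def gliding_box_lacunarity(mask: np.ndarray, box: int = 2) -> float:
    """Gliding-box lacunarity E[m^2]/E[m]^2 at the given box size."""
    if min(mask.shape) < box:
        log.debug("VOI bounding box smaller than lacunarity box; sentinel 1")
        return 1.0
    wins = sliding_window_view(mask.astype(float), (box, box, box))
    masses = wins.sum(axis=(-1, -2, -3)).ravel()
    mean = masses.mean()
    if mean == 0:
        return 0.0
    return float((masses ** 2).mean() / mean ** 2)


def fractal_features(voi: TumorVOI, q: QuantizedVOI) -> dict[str, float]:
    """6 fractal/model-based descriptors (box counting and DBC)."""
    mask, _, _ = voi.to_dense()
    q_grid, _ = q.to_dense()
    inside = q_grid > 0

    if min(mask.shape) < 4:
        log.warning("VOI spans < 4 voxels on an axis; fractal sentinels 0")
        fd_mask = fd_int = 0.0
    else:
        fd_mask = mask_fractal_dimension(mask)
        fd_int = intensity_fractal_dimension(q_grid, inside, q.Ng)

    local = _local_fd_map(q_grid, inside, q.Ng)
    if local.size == 0:
        log.warning("no full 5^3 window inside VOI; local FD sentinels 0")
        fd_mean = fd_max = fd_std = 0.0
    else:
        fd_mean = float(local.mean())
        fd_max = float(local.max())
        fd_std = float(local.std())

    return {
        "fd_mask": fd_mask,
        "fd_intensity": fd_int,
        "fd_mean": fd_mean,
        "fd_max": fd_max,
        "fd_std": fd_std,
        "lacunarity": gliding_box_lacunarity(mask),
    }


# --------------------------------------------------------------------------
# first-order


def _hist_probs(q: QuantizedVOI) -> np.ndarray:
    counts = np.bincount(q.bins, minlength=q.Ng + 1)[1:]
    return counts / counts.sum()


def first_order_features(voi: TumorVOI, q: QuantizedVOI) -> dict[str, float]:
    """37 histogram/intensity statistics of the VOI uptake values."""
    x = voi.values.astype(float)
    n = len(x)
    mean = float(x.mean())
    mx, mn = float(x.max()), float(x.min())
    med = float(np.median(x))
    pcts = {p: float(np.percentile(x, p)) for p in (5, 10, 25, 75, 90, 95)}
    sd = float(x.std())
    var = float(x.var())

    m2 = var
    if np.ptp(x) > 0 and m2 > 0:
        skew = float(((x - mean) ** 3).mean() / m2 ** 1.5)
        kurt = float(((x - mean) ** 4).mean() / m2 ** 2) - 3.0
    else:
        log.debug("zero-variance VOI; skewness/kurtosis sentinel 0")
        skew, kurt = 0.0, 0.0

    trimmed = x[(x >= pcts[10]) & (x <= pcts[90])]
    if trimmed.size:
        rmad = float(np.abs(trimmed - trimmed.mean()).mean())
        tmean = float(trimmed.mean())
    else:  # pragma: no cover - percentiles always bracket some values
        rmad, tmean = 0.0, mean

    energy = float((x ** 2).sum())
    voxvol = voi.spacing ** 3

    p = _hist_probs(q)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())
    centers = 0.5 * (q.bin_edges[:-1] + q.bin_edges[1:])
    mode_bin = int(np.argmax(p))
    grad = np.gradient(p.astype(float))

    denom_q = pcts[75] + pcts[25]
    qcd = (pcts[75] - pcts[25]) / denom_q if denom_q != 0 else 0.0
    cov = sd / mean if mean != 0 else 0.0

    return {
        "met_mean": mean,
        "met_max": mx,
        "met_min": mn,
        "met_median": med,
        "percentile_05": pcts[5],
        "percentile_10": pcts[10],
        "percentile_25": pcts[25],
        "percentile_75": pcts[75],
        "percentile_90": pcts[90],
        "percentile_95": pcts[95],
        "interquartile_range": pcts[75] - pcts[25],
        "interdecile_range": pcts[90] - pcts[10],
        "range": mx - mn,
        "standard_deviation": sd,
        "variance": var,
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "median_absolute_deviation": float(np.median(np.abs(x - med))),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_square": math.sqrt(energy / n),
        "energy": energy,
        "total_energy": energy * voxvol,
        "entropy": entropy,
        "uniformity": uniformity,
        "skewness": skew,
        "kurtosis_excess": kurt,
        "coefficient_of_variation": cov,
        "quartile_coefficient_of_dispersion": qcd,
        "histogram_mode": float(centers[mode_bin]),
        "histogram_max_probability": float(p.max()),
        "trimmed_mean_10_90": tmean,
        "mean_median_difference": mean - med,
        "entropy_normalized": entropy / math.log2(q.Ng),
        "histogram_gradient_max": float(grad.max()),
        "histogram_gradient_max_level": float(np.argmax(grad) + 1),
        "histogram_gradient_min": float(grad.min()),
        "histogram_gradient_min_level": float(np.argmin(grad) + 1),
        "total_lesion_metabolism": mean * n * voxvol,
    }


# --------------------------------------------------------------------------
# second-order (GLCM)


def second_order_features(glcm: np.ndarray) -> dict[str, float]:
    """21 Haralick-style features of a normalized symmetric GLCM (log base 2)."""
    P = np.asarray(glcm, dtype=float)
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    nzP = P[P > 0]
    hxy = float(-(nzP * np.log2(nzP)).sum())
    pxi_pxj = np.outer(px, px)
    okm = (P > 0) & (pxi_pxj > 0)
    hxy1 = float(-(P[okm] * np.log2(pxi_pxj[okm])).sum())
    okb = pxi_pxj > 0
    hxy2 = float(-(pxi_pxj[okb] * np.log2(pxi_pxj[okb])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        log.debug("degenerate GLCM marginal; IMC1 sentinel 0")
        imc1 = 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if sigma2 > 0:
        correlation = float(((I - mu) * (J - mu) * P).sum() / sigma2)
    else:
        log.debug("zero-variance GLCM; correlation sentinel 0")
        correlation = 0.0

    # sum/difference marginal distributions
    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(I + J) == k].sum() for k in ks])
    sa = float((ks * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sum_entropy = float(-(nzs * np.log2(nzs)).sum())
    sum_variance = float(((ks - sa) ** 2 * p_sum).sum())

    kd = np.arange(0, ng)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in kd])
    da = float((kd * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    diff_entropy = float(-(nzd * np.log2(nzd)).sum())
    diff_variance = float(((kd - da) ** 2 * p_diff).sum())

    off = I != J
    return {
        "glcm_contrast": float(((I - J) ** 2 * P).sum()),
        "glcm_dissimilarity": float((np.abs(I - J) * P).sum()),
        "glcm_homogeneity": float((P / (1.0 + np.abs(I - J))).sum()),
        "glcm_inverse_difference_moment": float((P / (1.0 + (I - J) ** 2)).sum()),
        "glcm_energy": float((P ** 2).sum()),
        "glcm_entropy": hxy,
        "glcm_correlation": correlation,
        "glcm_autocorrelation": float((I * J * P).sum()),
        "glcm_cluster_shade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "glcm_cluster_prominence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "glcm_cluster_tendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_maximum_probability": float(P.max()),
        "glcm_sum_average": sa,
        "glcm_sum_entropy": sum_entropy,
        "glcm_sum_variance": sum_variance,
        "glcm_difference_entropy": diff_entropy,
        "glcm_difference_variance": diff_variance,
        "glcm_joint_average": mu,
        "glcm_inverse_variance": float((P[off] / (I - J)[off] ** 2).sum()),
    }


# --------------------------------------------------------------------------
# higher-order (GLRLM + GLSZM + NGTDM)


def _glrlm_features(R: np.ndarray) -> dict[str, float]:
    nr = R.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    ng, rmax = R.shape
    i = np.arange(1, ng + 1)[:, None]
    r = np.arange(1, rmax + 1)[None, :]
    p = R / nr
    mu_r = float((p * r).sum())
    mu_i = float((p * i).sum())
    nzp = p[p > 0]
    n_voxel_dirs = float((R * r).sum())  # = voxel count x direction count
    return {
        "glrlm_sre": float((R / r ** 2).sum() / nr),
        "glrlm_lre": float((R * r ** 2).sum() / nr),
        "glrlm_gln": float((R.sum(axis=1) ** 2).sum() / nr),
        "glrlm_rln": float((R.sum(axis=0) ** 2).sum() / nr),
        "glrlm_run_percentage": float(nr / n_voxel_dirs),
        "glrlm_lgre": float((R / i ** 2).sum() / nr),
        "glrlm_hgre": float((R * i ** 2).sum() / nr),
        "glrlm_srlge": float((R / (i ** 2 * r ** 2)).sum() / nr),
        "glrlm_srhge": float((R * i ** 2 / r ** 2).sum() / nr),
        "glrlm_lrlge": float((R * r ** 2 / i ** 2).sum() / nr),
        "glrlm_lrhge": float((R * i ** 2 * r ** 2).sum() / nr),
        "glrlm_run_length_variance": float((p * (r - mu_r) ** 2).sum()),
        "glrlm_run_entropy": float(-(nzp * np.log2(nzp)).sum()),
        "glrlm_gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        "glrlm_run_mean_length": mu_r,
        "glrlm_gray_level_mean": mu_i,
    }


def _glszm_features(Z: np.ndarray) -> dict[str, float]:
    nz = Z.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    ng, smax = Z.shape
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, smax + 1)[None, :]
    p = Z / nz
    n_vox = float((Z * s).sum())
    mu_s = float((p * s).sum())
    mu_i = float((p * i).sum())
    nzp = p[p > 0]
    return {
        "glszm_sze": float((Z / s ** 2).sum() / nz),
        "glszm_lze": float((Z * s ** 2).sum() / nz),
        "glszm_intensity_variability": float((Z.sum(axis=1) ** 2).sum() / nz),
        "glszm_szv_nu": float((Z.sum(axis=0) ** 2).sum() / nz),
        "glszm_szv_var": float((p * (s - mu_s) ** 2).sum()),
        "glszm_zone_percentage": float(nz / n_vox),
        "glszm_lize": float((Z / i ** 2).sum() / nz),
        "glszm_hize": float((Z * i ** 2).sum() / nz),
        "glszm_szlie": float((Z / (i ** 2 * s ** 2)).sum() / nz),
        "glszm_szhie": float((Z * i ** 2 / s ** 2).sum() / nz),
        "glszm_lzlie": float((Z * s ** 2 / i ** 2).sum() / nz),
        "glszm_lzhie": float((Z * i ** 2 * s ** 2).sum() / nz),
        "glszm_zone_size_entropy": float(-(nzp * np.log2(nzp)).sum()),
        "glszm_gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
    }


def _ngtdm_features(s_i: np.ndarray, n_i: np.ndarray) -> dict[str, float]:
    N = n_i.sum()
    if N == 0:
        raise ValueError("empty gray-tone-difference matrix")
    p = n_i / N
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p) + 1).astype(float)
    ps = float((p * s_i).sum())

    coarseness = min(1.0 / ps, _COARSENESS_CAP) if ps > 0 else _COARSENESS_CAP
    if ps == 0:
        log.debug("flat neighborhoods; coarseness capped at %g", _COARSENESS_CAP)

    ip, pp, sp_ = i[present], p[present], s_i[present]
    if ngp > 1:
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * dif2).sum()
                         / (ngp * (ngp - 1))) * float(s_i.sum()) / N
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(ip[:, None] - ip[None, :])
                            * (pp[:, None] * sp_[:, None] + pp[None, :] * sp_[None, :])
                            / (pp[:, None] + pp[None, :])).sum()) / N
        s_tot = float(s_i.sum())
        strength = (float(((pp[:, None] + pp[None, :]) * dif2).sum()) / s_tot
                    if s_tot > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def higher_order_features(glrlm: np.ndarray, glszm: np.ndarray,
                          ngtdm_s: np.ndarray, ngtdm_n: np.ndarray) -> dict[str, float]:
    """35 features: 16 run-length, 14 size-zone, 5 gray-tone-difference."""
    out = _glrlm_features(glrlm)
    out.update(_glszm_features(glszm))
    out.update(_ngtdm_features(ngtdm_s, ngtdm_n))
    return out


# --------------------------------------------------------------------------
# assembly


def extract_all(voi: TumorVOI, config: FeatureConfig | None = None) -> FeatureVector:
    """Quantize, build matrices, and compute the full 114-feature vector."""
    config = config or FeatureConfig()
    q = quantize(voi, config.Ng)
    mats = build_all(q, config.matrix)

    values: dict[str, float] = {}
    values.update(geometric_features(voi))
    values.update(fractal_features(voi, q))
    values.update(first_order_features(voi, q))
    values.update(second_order_features(mats.glcm))
    values.update(higher_order_features(mats.glrlm, mats.glszm,
                                        mats.ngtdm_s, mats.ngtdm_n))

    manifest = feature_manifest()
    names = [e["name"] for e in manifest]
    if set(names) != set(values):
        missing = set(names) - set(values)
        extra = set(values) - set(names)
        raise RuntimeError(f"feature roster mismatch: missing={missing} extra={extra}")
    ordered = {name: float(values[name]) for name in names}
    return FeatureVector(
        values=ordered,
        category={e["name"]: e["category"] for e in manifest},
        units={e["name"]: e["unit"] for e in manifest},
    )
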