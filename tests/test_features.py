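import math

import numpy as np
import pytest

from conftest import qvoi_from_grid, voi_from_values
from pettex.image import TumorVOI, voi_from_mask
from pettex.features import (
    CATEGORY_COUNTS,
    FeatureConfig,
    extract_all,
    feature_manifest,
    first_order_features,
    fractal_features,
    geometric_features,
    gliding_box_lacunarity,
    higher_order_features,
    mask_fractal_dimension,
    second_order_features,
)
from pettex.matrices import quantize
from pettex.phantoms import PhantomSpec, generate_cohort, generate_phantom


def ball_mask(diameter, pad=0):
    n = diameter + 2 * pad
    g = np.indices((n, n, n)).transpose(1, 2, 3, 0) - (n - 1) / 2
    return (g ** 2).sum(-1) <= (diameter / 2) ** 2


def voi_from_grid_mask(mask, values=None, spacing=1.0):
    coords = np.argwhere(mask)
    vals = values[mask] if values is not None else np.ones(len(coords))
    return TumorVOI(coords=coords, values=vals, spacing=spacing)


# --------------------------------------------------------------------------
# roster


def test_manifest_counts():
    manifest = feature_manifest()
    assert len(manifest) == 114
    tally = {}
    for e in manifest:
        tally[e["category"]] = tally.get(e["category"], 0) + 1
    assert tally == CATEGORY_COUNTS


def test_extract_all_census(fixture_voi):
    fv = extract_all(fixture_voi)
    assert len(fv.values) == 114
    tally = {}
    for name in fv.values:
        tally[fv.category[name]] = tally.get(fv.category[name], 0) + 1
    assert tally == {"geometric": 15, "model_based": 6, "first_order": 37,
                     "second_order": 21, "higher_order": 35}


def test_extract_all_deterministic(fixture_voi):
    a, b = extract_all(fixture_voi), extract_all(fixture_voi)
    assert a.values == b.values


def test_rescaling_behavior(fixture_voi):
    fv = extract_all(fixture_voi)
    scaled = TumorVOI(coords=fixture_voi.coords.copy(),
                      values=fixture_voi.values * 2.0,
                      spacing=fixture_voi.spacing)
    fv2 = extract_all(scaled)
    # bin-domain texture features are unchanged
    for name in fv.values:
        if name.startswith(("glcm_", "glrlm_", "glszm_", "ngtdm_")):
            assert fv2[name] == pytest.approx(fv[name], rel=1e-9), name
    # %ID/g-domain features scale accordingly
    assert fv2["met_mean"] == pytest.approx(2 * fv["met_mean"])
    assert fv2["met_max"] == pytest.approx(2 * fv["met_max"])
    assert fv2["energy"] == pytest.approx(4 * fv["energy"])
    assert fv2["vol_met"] == fv["vol_met"]


# --------------------------------------------------------------------------
# geometric


class TestGeometric:
    def test_single_voxel(self):
        voi = TumorVOI(coords=np.array([[0, 0, 0]]), values=np.array([1.0]),
                       spacing=0.6)
        g = geometric_features(voi)
        assert g["vol_met"] == pytest.approx(0.216)
        assert g["surface_area"] == pytest.approx(2.16)
        assert g["surface_to_volume_ratio"] == pytest.approx(10.0)
        assert g["max_3d_diameter"] == 0.0

    def test_cube_2x2x2(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        g = geometric_features(voi_from_grid_mask(mask, spacing=0.6))
        assert g["surface_area"] == pytest.approx(8.64)
        assert g["vol_met"] == pytest.approx(1.728)
        assert g["surface_to_volume_ratio"] == pytest.approx(5.0)
        assert g["elongation"] == pytest.approx(1.0)
        assert g["flatness"] == pytest.approx(1.0)

    def test_sphericity_ball_beats_slab(self):
        ball = geometric_features(voi_from_grid_mask(ball_mask(12)))
        # 1-voxel-thick slab with (approximately) the same voxel count
        n = int(round(math.sqrt(ball_mask(12).sum())))
        slab = np.ones((n, n, 1), dtype=bool)
        slab_g = geometric_features(voi_from_grid_mask(slab))
        assert ball["sphericity"] > slab_g["sphericity"]
        assert ball["compactness2"] > slab_g["compactness2"]

    def test_max_diameter_line(self):
        voi = voi_from_values([1.0, 2.0, 3.0, 4.0], spacing=2.0)
        g = geometric_features(voi)
        assert g["max_3d_diameter"] == pytest.approx(6.0)  # 3 steps x 2 mm

    def test_equivalent_diameter_of_ball(self):
        mask = ball_mask(14)
        g = geometric_features(voi_from_grid_mask(mask))
        expected = 2 * (3 * mask.sum() / (4 * math.pi)) ** (1 / 3)
        assert g["equivalent_spherical_diameter"] == pytest.approx(expected)
        assert 13 < g["equivalent_spherical_diameter"] < 15

    def test_elongated_box_axes(self):
        mask = np.ones((12, 4, 4), dtype=bool)
        g = geometric_features(voi_from_grid_mask(mask))
        assert g["major_axis_length"] > g["minor_axis_length"]
        assert g["minor_axis_length"] == pytest.approx(g["least_axis_length"])
        assert g["elongation"] < 1.0
        assert g["spherical_disproportion"] == pytest.approx(1 / g["sphericity"])


# --------------------------------------------------------------------------
# fractal / model-based


class TestFractal:
    def test_solid_ball_fd_near_three(self):
        # exact box-count slope for this object is 2.675 at sizes {1,2,4,8}
        fd = mask_fractal_dimension(ball_mask(16))
        assert 2.6 <= fd <= 3.0

    def test_plane_fd_near_two(self):
        plane = np.ones((16, 16, 1), dtype=bool)
        fd = mask_fractal_dimension(plane)
        assert 1.8 <= fd <= 2.1

    def test_constant_voi_fd_std_zero(self):
        mask = np.ones((7, 7, 7), dtype=bool)
        voi = voi_from_grid_mask(mask, values=np.full((7, 7, 7), 4.0))
        f = fractal_features(voi, quantize(voi))
        assert f["fd_std"] == pytest.approx(0.0, abs=1e-12)

    def test_lacunarity_solid_cube_is_one(self):
        assert gliding_box_lacunarity(np.ones((6, 6, 6), dtype=bool)) == pytest.approx(1.0)

    def test_lacunarity_sparse_exceeds_solid(self, rng):
        sparse = rng.random((6, 6, 6)) < 0.3
        sparse[0, 0, 0] = True
        assert gliding_box_lacunarity(sparse) > 1.0

    def test_small_voi_sentinels(self):
        voi = voi_from_values([1.0, 2.0, 3.0])
        f = fractal_features(voi, quantize(voi))
        assert all(math.isfinite(v) for v in f.values())


# --------------------------------------------------------------------------
# first order


class TestFirstOrder:
    def test_constant_voi(self):
        voi = voi_from_values([14.22] * 20, spacing=0.6)
        f = first_order_features(voi, quantize(voi))
        assert f["met_mean"] == pytest.approx(14.22)
        assert f["standard_deviation"] == pytest.approx(0.0, abs=1e-12)
        assert f["entropy"] == 0.0
        assert f["skewness"] == 0.0  # documented zero-variance sentinel

    def test_two_level_entropy_one_bit(self):
        voi = voi_from_values([0.0] * 10 + [63.0] * 10)
        q = quantize(voi, Ng=64)
        assert set(q.bins) == {1, 64}
        f = first_order_features(voi, q)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["uniformity"] == pytest.approx(0.5)

    def test_symmetric_skewness_zero(self):
        voi = voi_from_values([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 4.0, 5.0])
        f = first_order_features(voi, quantize(voi))
        assert abs(f["skewness"]) < 1e-9

    def test_against_numpy_oracles(self, rng):
        vals = rng.uniform(2, 30, size=200)
        voi = voi_from_values(vals, spacing=0.6)
        f = first_order_features(voi, quantize(voi))
        assert f["met_max"] == vals.max()
        assert f["met_median"] == pytest.approx(np.median(vals))
        assert f["interquartile_range"] == pytest.approx(
            np.percentile(vals, 75) - np.percentile(vals, 25))
        assert f["variance"] == pytest.approx(vals.var())
        assert f["root_mean_square"] == pytest.approx(np.sqrt((vals ** 2).mean()))
        assert f["total_energy"] == pytest.approx((vals ** 2).sum() * 0.6 ** 3)
        assert f["mean_absolute_deviation"] == pytest.approx(
            np.abs(vals - vals.mean()).mean())
        assert f["coefficient_of_variation"] == pytest.approx(vals.std() / vals.mean())
        assert f["total_lesion_metabolism"] == pytest.approx(
            vals.mean() * len(vals) * 0.6 ** 3)
        # excess kurtosis of ~uniform data is near -1.2
        assert -1.5 < f["kurtosis_excess"] < -0.8

    def test_entropy_against_loop_oracle(self, rng):
        vals = rng.uniform(0, 10, size=150)
        voi = voi_from_values(vals)
        q = quantize(voi, Ng=16)
        f = first_order_features(voi, q)
        counts = [0] * 16
        for b in q.bins:
            counts[b - 1] += 1
        ent = -sum((c / 150) * math.log2(c / 150) for c in counts if c)
        assert f["entropy"] == pytest.approx(ent)


# --------------------------------------------------------------------------
# second order (GLCM)


def glcm_oracle(P):
    """Loop-based evaluation of all 21 co-occurrence features."""
    ng = P.shape[0]
    out = {k: 0.0 for k in ["contrast", "dissimilarity", "homogeneity", "idm",
                            "energy", "entropy", "autocorrelation", "shade",
                            "prominence", "tendency", "maxprob", "joint_average",
                            "inverse_variance"]}
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i][j]
            a, b = i + 1, j + 1
            out["contrast"] += (a - b) ** 2 * p
            out["dissimilarity"] += abs(a - b) * p
            out["homogeneity"] += p / (1 + abs(a - b))
            out["idm"] += p / (1 + (a - b) ** 2)
            out["energy"] += p * p
            if p > 0:
                out["entropy"] -= p * math.log2(p)
            out["autocorrelation"] += a * b * p
            out["shade"] += (a + b - 2 * mu) ** 3 * p
            out["prominence"] += (a + b - 2 * mu) ** 4 * p
            out["tendency"] += (a + b - 2 * mu) ** 2 * p
            out["maxprob"] = max(out["maxprob"], p)
            out["joint_average"] += a * p
            if a != b:
                out["inverse_variance"] += p / (a - b) ** 2
            corr_num += (a - mu) * (b - mu) * p
    out["correlation"] = corr_num / sigma2 if sigma2 > 0 else 0.0
    return out


class TestSecondOrder:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = second_order_features(P)
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_correlation"] == 0.0  # documented sentinel

    def test_two_cell_matrix(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        f = second_order_features(P)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_dissimilarity"] == pytest.approx(1.0)
        assert f["glcm_maximum_probability"] == 0.5
        assert f["glcm_joint_average"] == pytest.approx(1.5)

    def test_against_loop_oracle(self, rng):
        for _ in range(20):
            ng = int(rng.integers(2, 7))
            M = rng.random((ng, ng))
            P = (M + M.T) / (M + M.T).sum()
            f = second_order_features(P)
            o = glcm_oracle(P)
            assert f["glcm_contrast"] == pytest.approx(o["contrast"])
            assert f["glcm_dissimilarity"] == pytest.approx(o["dissimilarity"])
            assert f["glcm_homogeneity"] == pytest.approx(o["homogeneity"])
            assert f["glcm_inverse_difference_moment"] == pytest.approx(o["idm"])
            assert f["glcm_energy"] == pytest.approx(o["energy"])
            assert f["glcm_entropy"] == pytest.approx(o["entropy"])
            assert f["glcm_correlation"] == pytest.approx(o["correlation"])
            assert f["glcm_autocorrelation"] == pytest.approx(o["autocorrelation"])
            assert f["glcm_cluster_shade"] == pytest.approx(o["shade"])
            assert f["glcm_cluster_prominence"] == pytest.approx(o["prominence"])
            assert f["glcm_cluster_tendency"] == pytest.approx(o["tendency"])
            assert f["glcm_maximum_probability"] == pytest.approx(o["maxprob"])
            assert f["glcm_joint_average"] == pytest.approx(o["joint_average"])
            assert f["glcm_inverse_variance"] == pytest.approx(o["inverse_variance"])

    def test_sum_difference_marginals(self, rng):
        ng = 4
        M = rng.random((ng, ng))
        P = (M + M.T) / (M + M.T).sum()
        f = second_order_features(P)
        # oracle via explicit marginal construction
        psum, pdiff = {}, {}
        for i in range(ng):
            for j in range(ng):
                psum[i + j + 2] = psum.get(i + j + 2, 0) + P[i, j]
                pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0) + P[i, j]
        sa = sum(k * v for k, v in psum.items())
        se = -sum(v * math.log2(v) for v in psum.values() if v > 0)
        sv = sum((k - sa) ** 2 * v for k, v in psum.items())
        da = sum(k * v for k, v in pdiff.items())
        de = -sum(v * math.log2(v) for v in pdiff.values() if v > 0)
        dv = sum((k - da) ** 2 * v for k, v in pdiff.items())
        assert f["glcm_sum_average"] == pytest.approx(sa)
        assert f["glcm_sum_entropy"] == pytest.approx(se)
        assert f["glcm_sum_variance"] == pytest.approx(sv)
        assert f["glcm_difference_entropy"] == pytest.approx(de)
        assert f["glcm_difference_variance"] == pytest.approx(dv)

    def test_totality_on_random_glcms(self, rng):
        for _ in range(100):
            ng = int(rng.integers(1, 8))
            M = rng.random((ng, ng)) * (rng.random((ng, ng)) < 0.5)
            if M.sum() == 0:
                M[0, 0] = 1.0
            P = (M + M.T) / (M + M.T).sum()
            f = second_order_features(P)
            assert all(math.isfinite(v) for v in f.values())


# --------------------------------------------------------------------------
# higher order


def line_qvoi(bins, ng):
    grid = np.zeros((1, 1, len(bins)), dtype=int)
    grid[0, 0, :] = bins
    return qvoi_from_grid(grid, ng=ng)


class TestHigherOrder:
    def _features(self, q):
        from pettex.matrices import build_all
        mats = build_all(q)
        return higher_order_features(mats.glrlm, mats.glszm,
                                     mats.ngtdm_s, mats.ngtdm_n)

    def test_alternating_line_sre_one(self):
        f = self._features(line_qvoi([1, 2, 1, 2], ng=2))
        assert f["glrlm_sre"] == pytest.approx(1.0)
        assert f["glrlm_run_mean_length"] == pytest.approx(1.0)

    def test_szv_forms_on_two_equal_zones(self):
        f = self._features(line_qvoi([1, 1, 2, 2], ng=2))
        assert f["glszm_szv_var"] == pytest.approx(0.0)
        assert f["glszm_szv_nu"] == pytest.approx(2.0)

    def test_szv_var_orders_dispersion(self):
        # zones {1, 4} vs {2, 3}: same count, same total, different spread
        f_14 = self._features(line_qvoi([1, 2, 2, 2, 2], ng=2))
        f_23 = self._features(line_qvoi([1, 1, 2, 2, 2], ng=2))
        assert f_14["glszm_szv_var"] > f_23["glszm_szv_var"]
        assert f_14["glszm_szv_var"] == pytest.approx(2.25)
        assert f_23["glszm_szv_var"] == pytest.approx(0.25)

    def test_glrlm_against_loop_oracle(self, rng):
        from pettex.matrices import build_glrlm
        q = qvoi_from_grid(
            np.where(rng.random((4, 4, 4)) < 0.8,
                     rng.integers(1, 5, (4, 4, 4)), 0), ng=4)
        R = build_glrlm(q)
        f = self._features(q)
        nr = R.sum()
        sre = lre = lgre = 0.0
        for i in range(R.shape[0]):
            for r in range(R.shape[1]):
                sre += R[i][r] / (r + 1) ** 2
                lre += R[i][r] * (r + 1) ** 2
                lgre += R[i][r] / (i + 1) ** 2
        assert f["glrlm_sre"] == pytest.approx(sre / nr)
        assert f["glrlm_lre"] == pytest.approx(lre / nr)
        assert f["glrlm_lgre"] == pytest.approx(lgre / nr)
        gln = sum(sum(R[i]) ** 2 for i in range(R.shape[0])) / nr
        rln = sum(sum(R[:, r]) ** 2 for r in range(R.shape[1])) / nr
        assert f["glrlm_gln"] == pytest.approx(gln)
        assert f["glrlm_rln"] == pytest.approx(rln)
        n_vox = (q.bins > 0).sum()
        assert f["glrlm_run_percentage"] == pytest.approx(nr / (13 * n_vox))

    def test_glszm_against_loop_oracle(self, rng):
        from pettex.matrices import build_glszm
        q = qvoi_from_grid(
            np.where(rng.random((4, 4, 4)) < 0.8,
                     rng.integers(1, 5, (4, 4, 4)), 0), ng=4)
        Z = build_glszm(q)
        f = self._features(q)
        nz = Z.sum()
        sze = hize = 0.0
        sizes = []
        for i in range(Z.shape[0]):
            for s in range(Z.shape[1]):
                sze += Z[i][s] / (s + 1) ** 2
                hize += Z[i][s] * (i + 1) ** 2
                sizes += [s + 1] * int(Z[i][s])
        assert f["glszm_sze"] == pytest.approx(sze / nz)
        assert f["glszm_hize"] == pytest.approx(hize / nz)
        assert f["glszm_szv_var"] == pytest.approx(np.var(sizes))
        assert f["glszm_zone_percentage"] == pytest.approx(nz / len(q))

    def test_ngtdm_against_published_formulas(self):
        # Hand-checkable case: line [1, 3, 1]
        f = self._features(line_qvoi([1, 3, 1], ng=3))
        # s = [4, 0, 2], n = [2, 0, 1], N = 3, p = [2/3, 0, 1/3]
        ps = 2 / 3 * 4 + 1 / 3 * 2
        assert f["ngtdm_coarseness"] == pytest.approx(1 / ps)
        # contrast = [p1*p3*(1-3)^2 * 2 / (2*1)] * [(4+2)/3]
        contrast = (2 / 3) * (1 / 3) * 4 * 2 / (2 * 1) * (6 / 3)
        assert f["ngtdm_contrast"] == pytest.approx(contrast)

    def test_constant_voi_ngtdm_coarseness_capped(self):
        q = qvoi_from_grid(np.ones((2, 2, 2), dtype=int), ng=4)
        f = self._features(q)
        assert f["ngtdm_coarseness"] == 1e6
        assert f["ngtdm_contrast"] == 0.0


# --------------------------------------------------------------------------
# direction-of-effect battery (arm means on small cohorts)


@pytest.mark.slow
def test_direction_of_effect_battery():
    fine = PhantomSpec(tumor_equivalent_diameter=7.0, shape_irregularity=0.0,
                       n_uptake_classes=16, zone_size_mean=4.0,
                       zone_size_dispersion=0.05, psf_fwhm=0.0, noise_cv=0.05)
    coarse = PhantomSpec(tumor_equivalent_diameter=7.0, shape_irregularity=1.5,
                         n_uptake_classes=16, zone_size_mean=14.0,
                         zone_size_dispersion=0.6, psf_fwhm=0.0, noise_cv=0.05)
    means = {"glrlm_sre": {}, "glszm_szv_var": {}, "surface_to_volume_ratio": {}}
    cohort = generate_cohort(20, 20, fine, coarse, seed=2024)
    acc = {k: {"treated": [], "control": []} for k in means}
    for ph in cohort:
        voi = voi_from_mask(ph.image, ph.truth_mask)
        fv = extract_all(voi)
        for k in acc:
            acc[k][ph.group].append(fv[k])
    sre_t = np.mean(acc["glrlm_sre"]["treated"])
    sre_c = np.mean(acc["glrlm_sre"]["control"])
    szv_t = np.mean(acc["glszm_szv_var"]["treated"])
    szv_c = np.mean(acc["glszm_szv_var"]["control"])
    s2v_t = np.mean(acc["surface_to_volume_ratio"]["treated"])
    s2v_c = np.mean(acc["surface_to_volume_ratio"]["control"])
    assert sre_t > sre_c          # fine texture -> more short runs
    assert szv_t < szv_c          # uniform small zones -> lower size variance
    assert s2v_t < s2v_c          # compact sphere -> lower surface/volume
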