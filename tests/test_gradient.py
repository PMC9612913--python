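"""Gradient extraction, normalization model, puncta and clone profiles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from morphograd.gradient import (
    IntensityProfile,
    clone_edge_profile,
    detect_puncta,
    extract_profile,
    fit_profile_normalization,
    max_project,
    normalize_to_origin,
    subtract_background,
    ysl_mask,
)
from morphograd.synthetic import make_embryo_scene, make_profiles


@pytest.fixture(scope="module")
def ysl_scene():
    return make_embryo_scene(n_puncta=40, positive_tiers=12, noise_sd=0.02, seed=3)


class TestYslMask:
    def test_bimodal_separation(self):
        img = np.full((50, 60), 10.0)
        img[:, :15] = 200.0
        mask = ysl_mask(img)
        assert np.array_equal(mask, img == 200.0)

    def test_constant_image_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = ysl_mask(np.zeros((20, 20)))
        assert not mask.any()

    def test_synthetic_scene_coverage(self, ysl_scene):
        channels, truth = ysl_scene
        mask = ysl_mask(channels["farred"])
        pix = truth.pixel_size_um
        x_um = (np.arange(channels["farred"].shape[1]) + 0.5) * pix
        true_ysl = np.tile(x_um < truth.ysl_width_um, (channels["farred"].shape[0], 1))
        recall = (mask & true_ysl).sum() / true_ysl.sum()
        false_pos = (mask & ~true_ysl).sum() / (~true_ysl).sum()
        assert recall >= 0.95
        assert false_pos <= 0.01


class TestMaxProject:
    def test_single_slice_identity(self):
        stack = np.random.default_rng(0).random((4, 10, 12))
        assert np.array_equal(max_project(stack, (2, 3)), stack[2])

    def test_dominant_slice(self):
        stack = np.ones((5, 8, 8))
        stack[3] = 7.0
        assert np.array_equal(max_project(stack), stack[3])

    def test_matches_elementwise_oracle(self):
        stack = np.random.default_rng(1).random((6, 20, 30))
        proj = max_project(stack, (1, 5))
        oracle = np.maximum.reduce([stack[z] for z in range(1, 5)])
        assert np.array_equal(proj, oracle)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((3, 4, 4)), (2, 2))


class TestExtractProfile:
    def test_uniform_image_flat_profile(self):
        prof = extract_profile(np.full((20, 30), 7.0), pixel_size_um=1.0)
        assert np.allclose(prof.intensity, 7.0)

    def test_exponential_columns_recovered(self):
        pix = 2.0
        x_um = (np.arange(200) + 0.5) * pix
        img = np.tile(np.exp(-x_um / 100.0), (50, 1))
        prof = extract_profile(img, pix, bin_um=4.0)
        expected = np.exp(-prof.distance_um / 100.0)
        good = expected > 1e-3
        assert np.max(np.abs(prof.intensity[good] - expected[good]) / expected[good]) < 0.01

    def test_masking_is_local_and_missing_marked(self):
        img = np.full((10, 20), 3.0)
        img[:, 7] = 100.0  # bright artifact column
        mask = np.zeros_like(img, dtype=bool)
        mask[:, 7] = True
        unmasked = extract_profile(img, 1.0)
        masked = extract_profile(img, 1.0, mask=mask)
        assert unmasked.intensity[7] > masked.intensity[7] or np.isnan(masked.intensity[7])
        assert np.isnan(masked.intensity[7])  # whole bin excluded -> missing
        assert masked.n_pixels[7] == 0
        # all other bins unchanged
        others = np.arange(20) != 7
        assert np.allclose(masked.intensity[others], unmasked.intensity[others])


class TestSubtractBackground:
    def test_constant_background(self):
        grid = np.arange(0.5, 50, 1.0)
        prof = IntensityProfile(grid, np.full(len(grid), 12.0))
        ctrl = [IntensityProfile(grid, np.full(len(grid), 5.0))] * 3
        out = subtract_background([prof], ctrl)[0]
        assert np.allclose(out.intensity, 7.0)

    def test_profile_equal_to_control_gives_zero(self):
        grid = np.arange(0.5, 50, 1.0)
        vals = np.exp(-grid / 30) * 40
        prof = IntensityProfile(grid, vals)
        out = subtract_background([prof], [IntensityProfile(grid, vals)])[0]
        assert np.allclose(out.intensity, 0.0)

    def test_matches_median_oracle(self):
        rng = np.random.default_rng(2)
        grid = np.arange(0.5, 30, 1.0)
        ctrl = [IntensityProfile(grid, 5 + rng.random(len(grid))) for _ in range(7)]
        prof = IntensityProfile(grid, np.full(len(grid), 10.0))
        out = subtract_background([prof], ctrl)[0]
        oracle = np.median(np.vstack([c.intensity for c in ctrl]), axis=0)
        assert np.allclose(out.intensity, 10.0 - oracle)


class TestNormalizationModel:
    def test_matches_closed_form_ols(self):
        """(A_n, b_n) equal the closed-form per-embryo least-squares solution."""
        profiles, _ = make_profiles(n_embryos=6, noise_sd=0.05, seed=9)
        res = fit_profile_normalization(profiles)
        cbar = res.mean_profile
        for i, p in enumerate(profiles):
            y = p.intensity
            # two-parameter OLS closed form against regressor cbar
            A = np.cov(cbar, y, bias=True)[0, 1] / np.var(cbar)
            b = y.mean() - A * cbar.mean()
            assert res.A[i] == pytest.approx(A, rel=1e-8)
            assert res.b[i] == pytest.approx(b, rel=1e-8)
            ss = np.sum((y - A * cbar - b) ** 2)
            assert res.ss_res[i] == pytest.approx(ss, rel=1e-6)

    def test_gauge_identifiability_noiseless(self):
        # noiseless I_n = a_n g + c_n: the fit is exact up to the affine gauge
        # of cbar = (mean a) g + (mean c), so A_n/a_n = 1/(mean a) for all n
        # and b_n = c_n - A_n (mean c)
        profiles, truth = make_profiles(n_embryos=5, noise_sd=0.0, seed=4)
        res = fit_profile_normalization(profiles)
        a, c = np.array(truth.A), np.array(truth.b)
        assert np.allclose(res.A, a / a.mean(), rtol=1e-8)
        assert np.allclose(res.b, c - res.A * c.mean(), atol=1e-8)

    def test_identical_profiles(self):
        grid = np.arange(0.5, 100, 2.0)
        vals = 50 * np.exp(-grid / 40) + 3
        profiles = [IntensityProfile(grid, vals.copy()) for _ in range(2)]
        res = fit_profile_normalization(profiles)
        assert np.allclose(res.A, 1.0)
        assert np.allclose(res.b, 0.0, atol=1e-10)

    def test_permutation_invariance(self):
        profiles, _ = make_profiles(n_embryos=5, noise_sd=0.05, seed=10)
        res1 = fit_profile_normalization(profiles)
        res2 = fit_profile_normalization(profiles[::-1])
        assert np.allclose(res1.A, res2.A[::-1])
        assert np.allclose(res1.b, res2.b[::-1])

    def test_constant_mean_profile_unidentifiable(self):
        grid = np.arange(0.5, 20, 1.0)
        profiles = [
            IntensityProfile(grid, np.full(len(grid), float(v))) for v in (3, 5)
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_profile_normalization(profiles)


class TestNormalizeToOrigin:
    def test_divides_by_origin(self):
        prof = IntensityProfile(np.array([0.5, 50.0, 100.0]), np.array([4.0, 2.0, 1.0]))
        out = normalize_to_origin(prof)
        assert np.allclose(out.intensity, [1.0, 0.5, 0.25])

    def test_idempotent_on_normalized(self):
        prof = IntensityProfile(np.array([0.5, 50.0]), np.array([1.0, 0.3]))
        out = normalize_to_origin(prof)
        assert np.allclose(out.intensity, prof.intensity)

    def test_zero_origin_rejected(self):
        prof = IntensityProfile(np.array([0.5, 50.0]), np.array([0.0, 0.3]))
        with pytest.raises(ValueError):
            normalize_to_origin(prof)


class TestDetectPuncta:
    def test_flat_image_no_puncta(self):
        assert len(detect_puncta(np.ones((50, 50)), 1.0, 5.0, 5.0)) == 0

    def test_single_punctum_localized(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        img += 50 * np.exp(-((yy - 17) ** 2 + (xx - 23) ** 2) / (2 * 1.5**2))
        xy = detect_puncta(img, pixel_size_um=1.0, min_prominence=10.0, min_separation_um=3.0)
        assert len(xy) == 1
        assert abs(xy[0, 0] - 23) <= 1.0 and abs(xy[0, 1] - 17) <= 1.0

    def test_scene_precision_recall(self, ysl_scene):
        """>= 0.95 precision and recall against generator truth at SNR ~5."""
        channels, truth = ysl_scene
        proj = max_project(channels["ligand"])
        xy = detect_puncta(
            proj, truth.pixel_size_um, min_prominence=20.0, min_separation_um=6.0
        )
        truth_xy = np.array(truth.puncta_xy_um)
        tree = cKDTree(truth_xy)
        dist, idx = tree.query(xy)
        matched = dist <= 3.0
        precision = matched.mean()
        recall = len(set(idx[matched])) / len(truth_xy)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_distance_distribution_consistency(self, ysl_scene):
        channels, truth = ysl_scene
        proj = max_project(channels["ligand"])
        xy = detect_puncta(proj, truth.pixel_size_um, 20.0, 6.0)
        counts, _ = np.histogram(xy[:, 0], bins=10)
        assert counts.sum() == len(xy)
        assert np.issubdtype(counts.dtype, np.integer)


@pytest.fixture(scope="module")
def clone_scene():
    return make_embryo_scene(layout="clone", positive_tiers=0, noise_sd=0.02, seed=4)


class TestCloneEdgeProfile:

    def test_radial_length_scale_recovery(self, clone_scene):
        channels, truth = clone_scene
        prof = clone_edge_profile(
            max_project(channels["ligand"]),
            channels["farred"],
            truth.pixel_size_um,
            control_median=truth.background * 0.95,
            bin_um=4.0,
            max_distance_um=150.0,
        )
        good = ~np.isnan(prof.intensity) & (prof.intensity > 0.03)
        slope = np.polyfit(prof.distance_um[good], np.log(prof.intensity[good]), 1)[0]
        lam = -1.0 / slope
        assert abs(lam - truth.lambda_um) / truth.lambda_um < 0.05

    def test_roi_width_insensitive_on_symmetric_field(self, clone_scene):
        channels, truth = clone_scene
        args = (max_project(channels["ligand"]), channels["farred"], truth.pixel_size_um)
        kw = dict(control_median=truth.background * 0.95, bin_um=4.0, max_distance_um=150.0)
        p1 = clone_edge_profile(*args, roi_width_um=70.0, **kw)
        p2 = clone_edge_profile(*args, roi_width_um=140.0, **kw)
        good = ~np.isnan(p1.intensity) & (np.abs(p1.intensity) > 0.05)
        rel = np.abs(p2.intensity[good] - p1.intensity[good]) / np.abs(p1.intensity[good])
        assert np.nanmax(rel) < 0.01

    def test_background_field_zero_profile(self):
        farred = np.full((60, 60), 10.0)
        farred[25:35, 25:35] = 1000.0
        ligand = np.full((60, 60), 42.0)
        prof = clone_edge_profile(
            ligand, farred, pixel_size_um=2.0, control_median=42.0, normalize=False
        )
        assert np.allclose(prof.intensity[~np.isnan(prof.intensity)], 0.0)

    def test_no_clone_detected(self):
        with pytest.raises(ValueError, match="no clone"):
            clone_edge_profile(np.ones((20, 20)), np.ones((20, 20)), 1.0)


def test_end_to_end_length_scale_recovery():
    """Full chain (mask, project, extract, subtract, normalize) recovers lambda
    within 10% (median over 10 seeded embryos at <= 5% channel noise)."""
    lams = []
    for seed in range(10):
        channels, truth = make_embryo_scene(
            n_puncta=0, positive_tiers=0, noise_sd=0.05, seed=100 + seed
        )
        mask = ysl_mask(channels["farred"])
        proj = max_project(channels["ligand"])
        prof = extract_profile(proj, truth.pixel_size_um, mask=mask, bin_um=4.0)
        grid = prof.distance_um
        ctrl = IntensityProfile(grid, np.full(len(grid), truth.background))
        prof = subtract_background([prof], [ctrl])[0]
        good = (
            ~np.isnan(prof.intensity)
            & (grid > truth.ysl_width_um + 4)
            & (prof.intensity > 0.02 * np.nanmax(prof.intensity))
        )
        slope = np.polyfit(grid[good], np.log(prof.intensity[good]), 1)[0]
        lams.append(-1.0 / slope)
    med = np.median(lams)
    assert abs(med - 100.0) / 100.0 < 0.10
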