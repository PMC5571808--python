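"""Healing branches: fills, component separation, provenance, invariants."""

import numpy as np
import pytest

from scatterheal import (
    CIRCAVG_FILLED,
    MEASURED,
    SYMMETRY_FILLED,
    Background,
    DetectorImage,
    HoldoutRect,
    MaskSpec,
    PeakSet,
    RunConfig,
    SceneSpec,
    archetype_suite,
    circular_average,
    fill_isotropic,
    heal,
    holdout_peak_rects,
    iterative_local_mean_fill,
    lowrank_background,
    make_peak_mask,
    point_symmetry_fill,
    render_mask,
    render_scene,
    variation_map,
)
from scatterheal.geometry import PolarImage, remesh_to_polar


def polar(values, coverage=None, counts=None):
    values = np.asarray(values, dtype=float)
    n_q, n_chi = values.shape
    cov = np.isfinite(values) if coverage is None else np.asarray(coverage, bool)
    vals = np.where(cov, values, np.nan)
    return PolarImage(
        vals, cov, np.linspace(0, n_q, n_q + 1), np.linspace(0, 360, n_chi + 1), counts
    )


class TestCircularAverage:
    def test_constant_polar(self):
        assert np.allclose(circular_average(polar(np.full((4, 12), 3.0))), 3.0)

    def test_mean_excludes_masked_cells(self):
        row = np.array([[1.0, 2.0, 3.0, 4.0] * 3])
        cov = np.ones((1, 12), bool)
        cov[0, [1, 2]] = False  # drop one 2 and one 3
        prof = circular_average(polar(row, cov))
        assert prof[0] == pytest.approx(row[0][cov[0]].mean())

    def test_empty_row_flagged_nan(self):
        cov = np.ones((3, 12), bool)
        cov[1] = False
        prof = circular_average(polar(np.ones((3, 12)), cov))
        assert np.isnan(prof[1]) and prof[0] == 1.0

    def test_profile_robust_to_random_masking(self, ring_image):
        rng = np.random.default_rng(8)
        mask = rng.uniform(size=ring_image.shape) > 0.3
        masked = DetectorImage(ring_image.intensity, mask, ring_image.center)
        p_masked = circular_average(remesh_to_polar(masked))
        p_full = circular_average(remesh_to_polar(ring_image))
        ok = np.isfinite(p_masked) & np.isfinite(p_full) & (p_full > 0)
        rel = np.abs(p_masked[ok] - p_full[ok]) / p_full[ok]
        assert np.quantile(rel, 0.99) < 0.02


class TestFillIsotropic:
    def test_fully_covered_unchanged(self):
        pol = polar(np.arange(48, dtype=float).reshape(4, 12) + 1)
        filled, prov = fill_isotropic(pol)
        assert np.array_equal(filled.values, pol.values)
        assert (prov == MEASURED).all()

    def test_gap_gets_row_circular_average(self):
        vals = np.tile(np.array([[2.0, 4.0, 6.0, 8.0] * 3]), (3, 1))
        cov = np.ones((3, 12), bool)
        cov[1, 3:6] = False
        pol = polar(vals, cov)
        filled, prov = fill_isotropic(pol)
        expected = vals[1][cov[1]].mean()
        assert np.allclose(filled.values[1, 3:6], expected)
        assert (prov[1, 3:6] == CIRCAVG_FILLED).all()
        assert filled.coverage.all()

    def test_empty_row_interpolated_across_q(self):
        vals = np.ones((3, 12))
        vals[0] *= 2.0
        vals[2] *= 6.0
        cov = np.ones((3, 12), bool)
        cov[1] = False
        filled, _ = fill_isotropic(polar(vals, cov))
        assert np.allclose(filled.values[1], 4.0)


class TestPointSymmetryFill:
    def test_gap_takes_opposite_value(self):
        vals = np.full((8, 360), np.nan)
        cov = np.zeros((8, 360), bool)
        vals[5, 220] = 7.3
        cov[5, 220] = True
        vals[5, 10] = 1.0
        cov[5, 10] = True
        filled, prov = point_symmetry_fill(polar(vals, cov))
        assert filled.values[5, 40] == 7.3  # (5, 40deg) <- (5, 220deg)
        assert prov[5, 40] == SYMMETRY_FILLED

    def test_both_masked_stays_uncovered(self):
        vals = np.full((2, 8), np.nan)
        cov = np.zeros((2, 8), bool)
        vals[0, 0] = 1.0
        cov[0, 0] = True
        filled, _ = point_symmetry_fill(polar(vals, cov))
        assert not filled.coverage[1, 1]

    def test_both_covered_untouched(self):
        vals = np.zeros((1, 8))
        vals[0, 0], vals[0, 4] = 2.0, 9.0  # mates with different values
        filled, _ = point_symmetry_fill(polar(vals))
        assert filled.values[0, 0] == 2.0 and filled.values[0, 4] == 9.0


class TestIterativeLocalMeanFill:
    def test_single_hole_filled_with_neighborhood_constant(self):
        vals = np.full((5, 8), 4.0)
        d = np.ones((5, 8), bool)
        d[2, 3] = False
        out, done, gap = iterative_local_mean_fill(vals, d)
        assert done.all()
        assert out[2, 3] == pytest.approx(4.0)
        assert gap[2, 3] and gap.sum() == 1

    def test_ramp_gap_filled_monotone_between_anchors(self):
        vals = np.array([[3.0, 4.0, 5.0, np.nan, np.nan, np.nan, 9.0, 10.0, 11.0]])
        d = np.isfinite(vals)
        out, done, _ = iterative_local_mean_fill(vals, d, wrap_chi=False)
        assert done.all()
        filled = out[0, 3:6]
        assert np.all(np.diff(out[0]) > 0)  # monotone after smoothing
        assert np.all(filled > 5.0) and np.all(filled < 9.0)

    def test_fully_defined_gets_one_smoothing_pass(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (4, 12))
        out, _, gap = iterative_local_mean_fill(vals, np.ones((4, 12), bool))
        assert not gap.any()
        # one 3x3 box-mean pass (chi wrapped, q edges truncated)
        vp = np.pad(np.pad(vals, ((1, 1), (0, 0))), ((0, 0), (1, 1)), mode="wrap")
        dp = np.pad(np.pad(np.ones((4, 12)), ((1, 1), (0, 0))), ((0, 0), (1, 1)), mode="wrap")
        num = sum(
            vp[i : i + 4, j : j + 12] for i in range(3) for j in range(3)
        )
        den = sum(dp[i : i + 4, j : j + 12] for i in range(3) for j in range(3))
        assert np.allclose(out, num / den)

    def test_no_defined_cells_raises(self):
        with pytest.raises(ValueError):
            iterative_local_mean_fill(np.zeros((3, 3)), np.zeros((3, 3), bool))


class TestLowRankBackground:
    def test_rank_one_matrix_reconstructed_exactly(self):
        u = np.linspace(1, 2, 30)[:, None]
        v = np.linspace(0.5, 1.5, 40)[None, :]
        m = u * v
        assert np.allclose(lowrank_background(m, rank=1), m, atol=1e-12)

    def test_eckart_young_error_equals_discarded_singular_value(self):
        rng = np.random.default_rng(0)
        qm, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        qn, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        m = (qm * np.array([10.0, 5.0, 1.0])) @ qn.T
        err = np.linalg.norm(m - lowrank_background(m, rank=2))
        assert err == pytest.approx(1.0, abs=1e-10)

    def test_rank_nesting(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(1, 2, (20, 25))
        e1 = np.linalg.norm(m - lowrank_background(m, rank=1))
        e2 = np.linalg.norm(m - lowrank_background(m, rank=2))
        assert e2 <= e1

    def test_rank_too_large_raises(self):
        with pytest.raises(ValueError):
            lowrank_background(np.ones((3, 5)), rank=4)

    def test_incomplete_matrix_rejected(self):
        m = np.ones((4, 4))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            lowrank_background(m)


class TestVariationMap:
    def test_identity_when_background_matches(self):
        pol = polar(np.full((5, 12), 2.0))
        vmap = variation_map(pol, np.full((5, 12), 2.0))
        assert np.allclose(vmap, 1.0)

    def test_peak_ratio(self):
        vals = np.full((1, 12), 2.0)
        vals[0, 4] = 10.0  # peak 5x above background 2
        vmap = variation_map(polar(vals), np.full((1, 12), 2.0))
        assert vmap[0, 4] == pytest.approx(5.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(1, 5, (6, 24))
        pol1 = polar(vals)
        bg1 = lowrank_background(vals)
        pol2 = polar(vals * 1e4)
        bg2 = lowrank_background(vals * 1e4)
        assert np.allclose(variation_map(pol1, bg1), variation_map(pol2, bg2), rtol=1e-9)

    def test_uncovered_cells_nan(self):
        cov = np.ones((2, 12), bool)
        cov[0, 3] = False
        vmap = variation_map(polar(np.ones((2, 12)), cov), np.ones((2, 12)))
        assert np.isnan(vmap[0, 3])


class TestPeakMask:
    def test_constant_map_gives_empty_mask(self):
        assert not make_peak_mask(np.ones((6, 30))).any()

    def test_spike_flagged_with_dilation(self):
        vmap = np.ones((5, 60))
        vmap[2, 20:23] = 8.0
        mask = make_peak_mask(vmap, k_mad=3, dilate=1)
        assert mask[2, 20:23].all()
        assert mask[2, 19] and mask[2, 23]  # dilated along chi
        assert mask[1, 21] and mask[3, 21]  # and along q
        assert not mask[0].any() and not mask[4].any()

    def test_dilation_wraps_chi(self):
        vmap = np.ones((1, 36))
        vmap[0, 0] = 9.0
        mask = make_peak_mask(vmap, dilate=1)
        assert mask[0, 35] and mask[0, 1]

    def test_generated_complex_peaks_covered(self):
        from scipy.ndimage import median_filter

        case = {c.name: c for c in archetype_suite(seed=2)}["complex_0"]
        img = case.detector_image()
        pol = remesh_to_polar(img)
        prefilled, _ = fill_isotropic(pol)
        smoothed = median_filter(prefilled.values, size=(1, 61), mode="wrap")
        bg = lowrank_background(smoothed)
        vmap = variation_map(pol, bg)
        pmask = make_peak_mask(vmap)
        # where the generator placed sharp peaks well above local background,
        # the peak mask must fire
        peaks = sum(
            v for k, v in render_scene(case.scene).components.items() if "peakset" in k
        )
        bg_truth = case.truth - peaks
        strong = peaks > 3.0 * bg_truth
        strong_pol = remesh_to_polar(
            DetectorImage(strong.astype(float), case.mask, case.scene.center)
        )
        target = (np.nan_to_num(strong_pol.values) > 0.5) & pol.coverage
        assert pmask[target].mean() > 0.95


@pytest.fixture(scope="module")
def battery1():
    return archetype_suite(seed=1)


class TestHealInvariants:
    @pytest.mark.parametrize("idx", [0, 7, 13, 17])  # one per category
    def test_measured_preserved_complete_nonnegative(self, battery1, idx):
        case = battery1[idx]
        img = case.detector_image()
        res = heal(img)
        assert np.array_equal(res.healed[img.mask], img.intensity[img.mask])
        assert np.isfinite(res.healed).all()
        assert (res.healed >= 0).all()
        assert np.array_equal(res.provenance == MEASURED, img.mask)
        assert res.category.value == case.expected_category

    def test_fully_covered_image_unchanged(self, ring_image):
        res = heal(ring_image)
        assert np.array_equal(res.healed, ring_image.intensity)

    def test_determinism(self, battery1):
        img = battery1[6].detector_image()
        r1, r2 = heal(img), heal(img)
        assert np.array_equal(r1.healed, r2.healed)
        assert np.array_equal(r1.provenance, r2.provenance)
        assert r1.signature.to_json() == r2.signature.to_json()

    def test_mode_override_forces_isotropic_fill(self, battery1):
        case = battery1[7]  # a peaks image
        img = case.detector_image()
        res = heal(img, RunConfig(mode="isotropic"))
        prof = circular_average(res.polar)
        gaps = ~res.polar.coverage
        expected = np.broadcast_to(prof[:, None], res.polar.values.shape)
        ok = np.isfinite(expected) & gaps
        assert np.allclose(res.polar_healed.values[ok], expected[ok])


class TestBranchEquivalenceOnIsotropic:
    @pytest.mark.parametrize("mode", ["isotropic", "ordered", "diffuse", "complex"])
    def test_gap_fill_matches_circular_average(self, masked_iso_scene, mode):
        img, _ = masked_iso_scene
        pol = remesh_to_polar(img)
        iso_fill, _ = fill_isotropic(pol)
        res = heal(img, RunConfig(mode=mode))
        gaps = ~res.polar.coverage
        ref = iso_fill.values[gaps]
        got = res.polar_healed.values[gaps]
        rel = np.abs(got - ref) / np.maximum(ref, 1e-9)
        assert rel.max() < 0.03


class TestHoldoutReconstruction:
    @staticmethod
    def run_holdout(name, noise, seed=1):
        case = {c.name: c for c in archetype_suite(seed=seed, noise=noise)}[name]
        rects = holdout_peak_rects(case.scene)
        mask = render_mask(
            MaskSpec(
                elements=list(case.mask_spec.elements) + rects,
                seed=case.mask_spec.seed,
                center=case.scene.center,
            ),
            case.image.shape,
        )
        held = case.mask & ~mask
        res = heal(DetectorImage(case.image, mask, case.scene.center))
        h, t = res.healed[held], case.truth[held]
        r = np.corrcoef(h, t)[0, 1]
        med_rel = np.median(np.abs(h - t) / np.maximum(t, 1e-9))
        return r, med_rel

    @pytest.mark.parametrize("name", ["iso_peaks_6", "complex_0"])
    def test_noise_free(self, name):
        r, med_rel = self.run_holdout(name, noise=None)
        assert r > 0.95
        assert med_rel < 0.10

    @pytest.mark.parametrize("name", ["iso_peaks_6", "complex_0"])
    def test_poisson_snr10(self, name):
        r, med_rel = self.run_holdout(name, noise="poisson")
        assert r > 0.95
        assert med_rel < 0.20

    def test_whole_peak_behind_mask_reconstructed(self):
        # an entire peak is masked; its symmetry mates recover its position
        scene = SceneSpec(
            shape=(512, 512),
            center=(250.3, 261.7),
            features=[
                PeakSet(q0=120, width_r=6, width_chi=8, fold=4, amplitude=200, phase=45.0)
            ],
            background=Background(constant=40.0),
            noise=None,
            seed=0,
        )
        rend = render_scene(scene)
        rects = holdout_peak_rects(scene, pad_chi=3.0)
        mask = render_mask(MaskSpec(elements=rects, center=scene.center), scene.shape)
        res = heal(DetectorImage(rend.image, mask, scene.center))
        row = res.polar_healed.values[int(120 / res.polar_healed.delta_q)]
        centers = res.polar_healed.chi_centers
        window = (centers > 30) & (centers < 60)
        found = centers[window][np.argmax(row[window])]
        assert abs(found - 45.0) <= 1.0 + res.polar_healed.delta_chi / 2


class TestComplexSeparation:
    def test_component_split_recovers_generator_components(self):
        case = {c.name: c for c in archetype_suite(seed=2, noise=None)}["complex_0"]
        from scipy.ndimage import median_filter

        img = case.detector_image()
        pol = remesh_to_polar(img)
        prefilled, _ = fill_isotropic(pol)
        smoothed = median_filter(prefilled.values, size=(1, 61), mode="wrap")
        bg_lr = lowrank_background(smoothed)
        vmap = variation_map(pol, bg_lr)
        pmask = make_peak_mask(vmap)

        comps = render_scene(case.scene).components
        peaks_truth = sum(v for k, v in comps.items() if "peakset" in k)
        bg_truth = case.truth - peaks_truth

        from scatterheal.healing import heal_diffuse
        from scatterheal.metrics import azimuthal_stats, flag_anisotropic_ranges

        cov_bg = pol.coverage & ~pmask
        bg_pol = PolarImage(
            np.where(cov_bg, pol.values, np.nan), cov_bg, pol.q_edges, pol.chi_edges
        )
        stats = azimuthal_stats(bg_pol)
        ranges = flag_anisotropic_ranges(stats)
        bg_healed, _, _ = heal_diffuse(bg_pol, ranges)

        bg_truth_pol = remesh_to_polar(
            DetectorImage(bg_truth, np.ones_like(case.mask), case.scene.center)
        )
        cov = pol.coverage & np.isfinite(bg_truth_pol.values)
        r = np.corrcoef(bg_healed.values[cov], bg_truth_pol.values[cov])[0, 1]
        assert r > 0.9

    def test_no_peaks_routed_to_complex_behaves_like_diffuse(self):
        case = {c.name: c for c in archetype_suite(seed=1, noise=None)}["diffuse_0"]
        img = case.detector_image()
        res_c = heal(img, RunConfig(mode="complex"))
        res_d = heal(img, RunConfig(mode="diffuse"))
        gaps = ~res_c.polar.coverage
        scale = np.nanmean(res_d.polar_healed.values)
        diff = np.abs(res_c.polar_healed.values[gaps] - res_d.polar_healed.values[gaps])
        assert np.median(diff) / scale < 0.05
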