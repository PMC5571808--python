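"""Anisotropy statistics, histogram signatures and image classification."""

import numpy as np
import pytest
from scipy.special import gammaln

from scatterheal import (
    ClassifierThresholds,
    ImageCategory,
    archetype_suite,
    classify_image,
    fit_poisson_histogram,
    flag_anisotropic_ranges,
)
from scatterheal.geometry import PolarImage, remesh_to_polar
from scatterheal.metrics import AzimuthalStats, analyze, azimuthal_stats


def polar_from_rows(rows, coverage=None):
    rows = np.asarray(rows, dtype=float)
    n_q, n_chi = rows.shape
    cov = np.ones_like(rows, dtype=bool) if coverage is None else np.asarray(coverage, bool)
    vals = np.where(cov, rows, np.nan)
    return PolarImage(
        vals,
        cov,
        q_edges=np.linspace(0, n_q, n_q + 1),
        chi_edges=np.linspace(0, 360, n_chi + 1),
    )


def brute_force_ratio(row, window_deg=7.5, n_chi=360):
    """Independent oracle: explicit per-window loop with bias correction."""
    chi_centers = (np.arange(n_chi) + 0.5) * 360.0 / n_chi

    def corr(n):
        return np.sqrt(2.0 / n) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2))

    sg = row.std() / corr(len(row))
    locals_ = []
    n_w = int(np.ceil(360 / window_deg))
    for w in range(n_w):
        sel = (chi_centers >= w * window_deg) & (chi_centers < (w + 1) * window_deg)
        if sel.sum() >= 3:
            locals_.append(row[sel].std() / corr(sel.sum()))
    return np.mean(locals_) / sg


class TestAzimuthalStats:
    def test_constant_row_ratio_is_one(self):
        pol = polar_from_rows(np.full((12, 360), 5.0))
        stats = azimuthal_stats(pol)
        assert all(s.ratio == 1.0 and s.sigma_global == 0.0 for s in stats)

    def test_block_row_matches_brute_force(self):
        row = np.ones(360)
        row[40:50] = 11.0  # contiguous 10-deg block
        pol = polar_from_rows(np.tile(row, (10, 1)))
        stats = azimuthal_stats(pol)
        expected = brute_force_ratio(row)
        assert stats[0].ratio == pytest.approx(expected, rel=1e-10)
        assert stats[0].ratio < 0.8

    def test_iid_row_ratio_near_one(self):
        rng = np.random.default_rng(42)
        pol = polar_from_rows(rng.uniform(0, 1, (10, 360)))
        stats = azimuthal_stats(pol)
        for s in stats:
            assert 0.9 < s.ratio < 1.1

    def test_sparse_rows_skipped(self):
        cov = np.zeros((3, 360), bool)
        cov[0, :] = True
        cov[1, :7] = True  # fewer than 8 covered bins -> unanalyzable
        cov[2, :50] = True
        pol = polar_from_rows(np.ones((3, 360)), cov)
        stats = azimuthal_stats(pol)
        assert [s.q_index for s in stats] == [0, 2]

    def test_ratio_bounded_above_for_well_covered_rows(self):
        rng = np.random.default_rng(0)
        pol = polar_from_rows(rng.exponential(2.0, (40, 360)))
        for s in azimuthal_stats(pol):
            assert s.n_covered >= 90
            assert s.ratio < 1.15

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        rows = rng.uniform(1, 3, (12, 360))
        r1 = [s.ratio for s in azimuthal_stats(polar_from_rows(rows))]
        r2 = [s.ratio for s in azimuthal_stats(polar_from_rows(rows * 137.0))]
        assert np.allclose(r1, r2)

    def test_sharp_peak_strictly_decreases_ratio(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(10, 0.1, (5, 360))
        base = [s.ratio for s in azimuthal_stats(polar_from_rows(rows))]
        rows_peak = rows.copy()
        chi = np.arange(360)
        rows_peak[2] += 5.0 * np.exp(-((chi - 90.0) ** 2) / (2 * 4.0**2))
        with_peak = [s.ratio for s in azimuthal_stats(polar_from_rows(rows_peak))]
        assert with_peak[2] < base[2]
        assert with_peak[0] == pytest.approx(base[0])


class TestFlagRanges:
    @staticmethod
    def stats_from_ratios(ratios):
        return [AzimuthalStats(i, 1.0, r, r, 360) for i, r in enumerate(ratios)]

    def test_all_isotropic_gives_empty(self):
        assert flag_anisotropic_ranges(self.stats_from_ratios([1.0] * 7)) == []

    def test_contiguous_run(self):
        ranges = flag_anisotropic_ranges(self.stats_from_ratios([1, 1, 0.5, 0.5, 0.5, 1, 1]))
        assert ranges == [(2, 4)]

    def test_short_run_discarded(self):
        assert flag_anisotropic_ranges(self.stats_from_ratios([1, 0.5, 1])) == []

    def test_run_at_end_kept(self):
        assert flag_anisotropic_ranges(self.stats_from_ratios([1, 1, 0.3, 0.3])) == [(2, 3)]

    def test_gap_in_q_indices_breaks_run(self):
        stats = [AzimuthalStats(i, 1.0, 0.5, 0.5, 360) for i in (0, 1, 5, 6)]
        assert flag_anisotropic_ranges(stats) == [(0, 1), (5, 6)]

    def test_empty_stats_raises(self):
        with pytest.raises(ValueError):
            flag_anisotropic_ranges([])


class TestPoissonHistogram:
    def test_identical_values_degenerate(self):
        sig = fit_poisson_histogram([2.5] * 20)
        assert sig.lambda_fit == 0.0
        assert sig.lambda_value == pytest.approx(2.5)
        assert sig.rel_center == pytest.approx(0.5)

    def test_recovers_lambda_four_from_exact_pmf(self):
        # sample values whose 30-bin histogram reproduces a Poisson(4) pmf
        k = np.arange(30)
        pmf = np.exp(k * np.log(4.0) - 4.0 - gammaln(k + 1.0))
        counts = np.round(pmf * 10000).astype(int)
        values = np.repeat(k + 0.5, counts) / 30.0  # bin centers in [0, 1]
        values[0], values[-1] = 0.0, 1.0  # pin the span
        sig = fit_poisson_histogram(values)
        assert sig.lambda_fit == pytest.approx(4.0, rel=0.05)

    def test_skewed_sample_center_below_mean(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(1.0, 0.1, 500), rng.normal(6.0, 0.5, 40)])
        sig = fit_poisson_histogram(vals)
        assert sig.lambda_value < vals.mean()

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_poisson_histogram([1.0] * 9)

    def test_frequencies_sum_to_row_count(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, 143)
        sig = fit_poisson_histogram(vals)
        assert sig.frequencies.sum() == 143


@pytest.fixture(scope="module")
def battery():
    return archetype_suite(seed=1)


class TestClassification:
    def classify(self, case):
        pol = remesh_to_polar(case.detector_image())
        return analyze(pol)

    @pytest.mark.parametrize(
        "name",
        ["isotropic_0", "iso_peaks_6", "diffuse_0", "complex_0"],
    )
    def test_archetypes_classified_correctly(self, battery, name):
        case = {c.name: c for c in battery}[name]
        sig = self.classify(case)
        assert sig.category.value == case.expected_category

    def test_classify_is_pure(self, battery):
        case = battery[0]
        s1 = self.classify(case)
        s2 = self.classify(case)
        assert s1.category == s2.category
        assert classify_image(s1.sig_ratio, s1.sig_sigma) == classify_image(
            s2.sig_ratio, s2.sig_sigma
        )

    def test_category_scale_invariant(self, battery):
        case = {c.name: c for c in battery}["complex_0"]
        img = case.detector_image()
        sig1 = analyze(remesh_to_polar(img))
        scaled = type(img)(img.intensity * 41.0, img.mask, img.center)
        sig2 = analyze(remesh_to_polar(scaled))
        assert sig1.category == sig2.category
        r1 = [s.ratio for s in sig1.stats]
        r2 = [s.ratio for s in sig2.stats]
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_decision_tree_branches(self):
        # exercise the pure decision function on synthetic signatures
        def sig(lambda_value=1.0, rel_center=0.5):
            s = fit_poisson_histogram(list(np.linspace(0, 1, 30)))
            s.lambda_value = lambda_value
            s.rel_center = rel_center
            return s

        th = ClassifierThresholds(t_iso=0.8, t_peak=0.08, t_diffuse=0.7)
        assert classify_image(sig(0.95, 0.5), sig(0.95, 0.5), th) == ImageCategory.ISOTROPIC
        assert classify_image(sig(0.95), sig(rel_center=0.02), th) == ImageCategory.ISO_BG_PLUS_PEAKS
        assert classify_image(sig(0.3), sig(rel_center=0.95), th) == ImageCategory.DIFFUSE_ANISO
        assert classify_image(sig(0.3), sig(rel_center=0.4), th) == ImageCategory.COMPLEX

    def test_signature_serializes_to_json(self, battery):
        sig = self.classify(battery[0])
        import json

        d = json.loads(sig.to_json())
        assert d["category"] == "isotropic"
        assert len(d["histogram_ratio"]["frequencies"]) >= 1
        assert "per_q" in d
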