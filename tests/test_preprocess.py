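"""Preprocessing chain: each of the five steps against independent
oracles, plus end-to-end invariances."""

import numpy as np
import pytest

from skinraman.preprocess import (
    CANONICAL_RANGES,
    PreprocessConfig,
    Segment,
    SpectralRange,
    average_replicates,
    baseline_correct,
    extract_extended_range,
    feature_length,
    preprocess_spectrum,
    savgol_smooth,
    snv_normalize,
    subtract_dark,
    trim_margins,
)
from skinraman.spectra import RamanSpectrum
from skinraman.synth import BandSpec, default_grid


def _spec(grid, y, **kw):
    return RamanSpectrum(grid, y, **kw)


class TestReplicatesAndDark:
    def test_mean_of_identical_is_identity(self, grid):
        s = _spec(grid, np.sin(grid / 100), spectrum_id="s")
        m = average_replicates([s, s, s])
        assert np.allclose(m.intensities, s.intensities, rtol=1e-15, atol=1e-300)
        assert m.replicate_index == "mean"

    def test_channelwise_mean(self):
        grid = np.arange(3.0)
        reps = [_spec(grid, [0, 0, 0]), _spec(grid, [3, 3, 3]), _spec(grid, [6, 6, 6])]
        assert np.array_equal(average_replicates(reps).intensities, [3, 3, 3])

    def test_replicate_mean_variance_scales_as_sigma2_over_k(self):
        """Monte Carlo: variance of the k=3 replicate mean is sigma^2/3."""
        rng = np.random.default_rng(11)
        grid = np.arange(2.0)
        sigma = 1.0
        means = [
            average_replicates(
                [_spec(grid, rng.normal(0, sigma, 2)) for _ in range(3)]
            ).intensities[0]
            for _ in range(2000)
        ]
        assert np.var(means) == pytest.approx(sigma**2 / 3, rel=0.15)

    def test_grid_mismatch_rejected(self):
        a = _spec(np.arange(3.0), np.zeros(3))
        b = _spec(np.arange(1.0, 4.0), np.zeros(3))
        with pytest.raises(ValueError, match="grid mismatch"):
            average_replicates([a, b])
        with pytest.raises(ValueError, match="grid mismatch"):
            subtract_dark(a, b)

    def test_dark_subtraction_identities(self, grid):
        s = _spec(grid, np.cos(grid / 50))
        zeros = _spec(grid, np.zeros_like(grid))
        assert np.array_equal(subtract_dark(s, zeros).intensities, s.intensities)
        assert np.allclose(subtract_dark(s, s).intensities, 0.0)


class TestRangeExtraction:
    def test_extended_segment_channel_count(self, grid):
        """Range (800, 1350) with 50 cm^-1 margins on a 1 cm^-1 grid:
        closed interval 750..1400 -> 651 channels."""
        s = _spec(grid, np.zeros_like(grid))
        seg = extract_extended_range(s, CANONICAL_RANGES[0])
        assert len(seg) == 651
        assert seg.wavenumbers[0] == 750.0 and seg.wavenumbers[-1] == 1400.0

    def test_zero_margin_is_nominal_range(self, grid):
        s = _spec(grid, np.zeros_like(grid))
        seg = extract_extended_range(s, SpectralRange(800, 1350, 5, margin=0.0))
        assert len(seg) == 551

    def test_insufficient_coverage_is_error(self):
        grid = default_grid(780, 1500)
        s = _spec(grid, np.zeros_like(grid))
        with pytest.raises(ValueError, match="does not cover"):
            extract_extended_range(s, CANONICAL_RANGES[0])

    def test_trim_margins_counts_and_idempotence(self, grid):
        s = _spec(grid, np.zeros_like(grid))
        rng0 = CANONICAL_RANGES[0]
        seg = extract_extended_range(s, rng0)
        trimmed = trim_margins(seg, rng0)
        assert len(trimmed) == 551
        again = trim_margins(trimmed, rng0)
        assert np.array_equal(again.wavenumbers, trimmed.wavenumbers)


class TestBaselineCorrection:
    def test_polynomial_annihilation(self):
        """An order-<=5 polynomial input is removed to <1e-6 relative."""
        x = np.linspace(800, 1400, 601)
        y = 5 + 0.01 * (x - 1000) + 1e-5 * (x - 1000) ** 3
        out = baseline_correct(Segment(x, y), order=5)
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.max(np.abs(y))

    def test_ramp_plus_peak_preserves_peak_area(self):
        """Linear ramp + isolated Gaussian, order-1 fit: corrected peak
        area within 5% of the planted area."""
        x = np.linspace(0, 600, 601)
        band = BandSpec(300.0, 20.0, 1.0)
        y = 0.5 + 0.002 * x + band.profile(x)
        out = baseline_correct(Segment(x, y), order=1)
        area = np.trapezoid(out.intensities, x)
        assert area == pytest.approx(band.area, rel=0.05)

    def test_pure_peak_on_zero_baseline(self):
        """Order-1 fit hugs the flanks; the peak maximum survives within 10%."""
        x = np.linspace(0, 600, 601)
        band = BandSpec(300.0, 20.0, 1.0)
        out = baseline_correct(Segment(x, band.profile(x)), order=1)
        assert out.intensities.max() == pytest.approx(1.0, rel=0.10)
        flanks = np.abs(x - 300) > 100
        assert np.max(np.abs(out.intensities[flanks])) < 0.02


class TestSNV:
    def test_hand_computed_example(self):
        out = snv_normalize(Segment(np.arange(3.0), np.array([1.0, 2.0, 3.0])))
        assert np.allclose(out.intensities, [-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=100)
        a = snv_normalize(Segment(np.arange(100.0), y))
        b = snv_normalize(Segment(np.arange(100.0), 3.7 * y + 12.0))
        assert np.allclose(a.intensities, b.intensities, atol=1e-12)

    def test_constant_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            snv_normalize(Segment(np.arange(5.0), np.full(5, 2.0)))

    def test_population_sd_option(self):
        y = np.array([1.0, 2.0, 3.0])
        out = snv_normalize(Segment(np.arange(3.0), y), ddof=0)
        assert np.std(out.intensities, ddof=0) == pytest.approx(1.0)


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        i = np.arange(50.0)
        seg = savgol_smooth(Segment(i, i**2), order=2, window=13)
        assert np.allclose(seg.intensities[6:-6], (i**2)[6:-6], atol=1e-8)

    def test_impulse_center_weight_matches_lsq_oracle(self):
        """The center output of a unit impulse equals the central weight of
        the 13-point order-2 least-squares fit, derived here directly from
        the normal equations."""
        m = 13
        t = np.arange(m) - m // 2
        vand = np.vander(t, 3, increasing=True)  # [1, t, t^2]
        # weight of observation j on the fitted value at t=0:
        weights = vand @ np.linalg.solve(vand.T @ vand, vand.T)
        center_weight = weights[m // 2, m // 2]
        y = np.zeros(51)
        y[25] = 1.0
        seg = savgol_smooth(Segment(np.arange(51.0), y), order=2, window=13)
        assert seg.intensities[25] == pytest.approx(center_weight, abs=1e-12)

    def test_constant_unchanged(self):
        seg = savgol_smooth(Segment(np.arange(20.0), np.full(20, 4.2)))
        assert np.allclose(seg.intensities, 4.2)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            savgol_smooth(Segment(np.arange(5.0), np.zeros(5)))


class TestFullChain:
    def test_canonical_feature_length_and_channel_map(self, grid):
        rng = np.random.default_rng(0)
        y = 1.0 + 0.1 * np.sin(grid / 30) + rng.normal(0, 0.01, grid.size)
        p = preprocess_spectrum(_spec(grid, y, spectrum_id="s1"))
        assert p.features.size == 551 + 401 + 201 == 1153
        cm = p.channel_map
        assert cm["wavenumber"].iloc[0] == 800.0
        assert cm["wavenumber"].iloc[550] == 1350.0
        assert cm["wavenumber"].iloc[551] == 1350.0
        assert cm["wavenumber"].iloc[-1] == 3000.0
        assert list(cm["range_index"].unique()) == [0, 1, 2]

    def test_feature_length_pure_function_of_grid(self, grid):
        assert feature_length(grid) == 1153
        assert feature_length(default_grid(0, 3050, 2.0)) == 276 + 201 + 101

    def test_affine_invariance_end_to_end(self, grid):
        """Global positive gain + offset is cancelled by the chain."""
        rng = np.random.default_rng(2)
        y = 1.0 + 0.2 * np.cos(grid / 70) + rng.normal(0, 0.01, grid.size)
        a = preprocess_spectrum(_spec(grid, y, spectrum_id="a"))
        b = preprocess_spectrum(_spec(grid, 2.5 * y + 7.0, spectrum_id="b"))
        assert np.allclose(a.features, b.features, atol=1e-6)

    def test_per_range_mean_near_zero(self, grid):
        """SNV zeroes each range's mean; Savitzky-Golay edge handling
        perturbs it only at the 1e-4 level."""
        rng = np.random.default_rng(3)
        y = 1.0 + 0.3 * np.sin(grid / 45) + rng.normal(0, 0.02, grid.size)
        p = preprocess_spectrum(_spec(grid, y, spectrum_id="s"))
        for i in range(3):
            mean = p.features[p.channel_map["range_index"] == i].mean()
            assert abs(mean) < 1e-3

    def test_snv_before_smoothing_order_matters(self, grid):
        """The chain applies SNV then smoothing; swapping the two steps
        changes the output, so the order is observable and fixed."""
        rng = np.random.default_rng(4)
        y = 1.0 + rng.normal(0, 0.1, grid.size)
        s = _spec(grid, y, spectrum_id="s")
        p = preprocess_spectrum(s)
        rng0 = CANONICAL_RANGES[0]
        seg = trim_margins(
            baseline_correct(extract_extended_range(s, rng0), rng0.baseline_order),
            rng0,
        )
        swapped = snv_normalize(savgol_smooth(seg))
        stated = savgol_smooth(snv_normalize(seg))
        chain_range0 = p.features[p.channel_map["range_index"] == 0]
        assert np.allclose(chain_range0, stated.intensities, atol=1e-10)
        assert not np.allclose(stated.intensities, swapped.intensities, atol=1e-6)

    def test_stage_errors_carry_range_identity(self):
        grid = default_grid(700, 2000)
        s = _spec(grid, np.ones_like(grid), spectrum_id="s")
        with pytest.raises(ValueError, match="range 2"):
            preprocess_spectrum(s)
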