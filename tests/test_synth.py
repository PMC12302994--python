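"""Generator contracts: line shapes, cohort structure, determinism."""

import numpy as np
import pytest

import skinraman as sr
from skinraman.synth import (
    CAF2_CENTER,
    BandSpec,
    CohortConfig,
    TissueClassProfile,
    default_grid,
    generate_cohort,
    generate_dark_background,
    generate_spectrum,
)

SEED = 11


def _flat_profile(label="EPI-H", bands=(), noise_sd=0.0):
    return TissueClassProfile(
        label=label, bands=list(bands), baseline_coeffs=np.zeros(1), noise_sd=noise_sd
    )


class TestGenerateSpectrum:
    def test_degenerate_profile_is_caf2_only(self, grid):
        """No bands, zero baseline, zero noise -> only the CaF2 window line."""
        rng = np.random.default_rng(0)
        caf2 = BandSpec(CAF2_CENTER, 12.0, 0.4)
        s = generate_spectrum(_flat_profile(), 0.0, grid, rng, caf2=caf2)
        assert np.allclose(s.intensities, caf2.profile(grid))
        far = np.abs(grid - CAF2_CENTER) > 200
        assert np.allclose(s.intensities[far], 0.0, atol=1e-12)

    def test_gaussian_band_area_matches_closed_form(self, grid):
        """Integrated area of a planted Gaussian equals the analytic
        amplitude * (FWHM/2.3548) * sqrt(2*pi) within 1%."""
        band = BandSpec(1089.0, 20.0, 1.0)
        rng = np.random.default_rng(0)
        s = generate_spectrum(_flat_profile(bands=[band]), 0.0, grid, rng)
        numeric = np.trapezoid(s.intensities, grid)
        analytic = 1.0 * (20.0 / 2.3548200450309493) * np.sqrt(2 * np.pi)
        assert numeric == pytest.approx(analytic, rel=0.01)

    def test_same_seed_bit_identical(self, grid):
        prof = _flat_profile(bands=[BandSpec(1000.0, 15.0, 1.0)], noise_sd=0.05)
        a = generate_spectrum(prof, 0.0, grid, np.random.default_rng(42))
        b = generate_spectrum(prof, 0.0, grid, np.random.default_rng(42))
        assert np.array_equal(a.intensities, b.intensities)

    def test_band_outside_grid_rejected(self):
        grid = default_grid(500, 1500)
        prof = _flat_profile(bands=[BandSpec(2000.0, 15.0, 1.0)])
        with pytest.raises(ValueError, match="outside grid span"):
            generate_spectrum(prof, 0.0, grid, np.random.default_rng(0))

    def test_lorentzian_shape_available(self, grid):
        band = BandSpec(1000.0, 20.0, 1.0, shape="lorentzian")
        rng = np.random.default_rng(0)
        s = generate_spectrum(_flat_profile(bands=[band]), 0.0, grid, rng)
        # half maximum at center +/- FWHM/2
        i_c = np.argmin(np.abs(grid - 1000.0))
        i_h = np.argmin(np.abs(grid - 1010.0))
        assert s.intensities[i_h] == pytest.approx(s.intensities[i_c] / 2, rel=1e-6)


class TestDarkBackground:
    def test_deterministic_and_smooth(self, grid):
        a = generate_dark_background(grid, np.random.default_rng(5))
        b = generate_dark_background(grid, np.random.default_rng(5))
        assert np.array_equal(a.intensities, b.intensities)
        # smooth: second differences tiny relative to amplitude
        assert np.max(np.abs(np.diff(a.intensities, 2))) < 1e-4

    def test_different_seeds_differ(self, grid):
        a = generate_dark_background(grid, np.random.default_rng(1))
        b = generate_dark_background(grid, np.random.default_rng(2))
        assert not np.array_equal(a.intensities, b.intensities)

    def test_construct_then_subtract_identity(self, grid):
        """Adding the dark at generation and subtracting it afterwards
        restores the band-only signal exactly at zero noise."""
        from skinraman.preprocess import subtract_dark

        rng = np.random.default_rng(3)
        dark = generate_dark_background(grid, rng)
        prof = _flat_profile(bands=[BandSpec(1450.0, 18.0, 0.8)])
        with_dark = generate_spectrum(prof, 0.0, grid, rng, dark=dark)
        clean = generate_spectrum(prof, 0.0, grid, rng)
        restored = subtract_dark(with_dark, dark)
        assert np.allclose(restored.intensities, clean.intensities, atol=1e-12)


class TestGenerateCohort:
    def test_clinical_cohort_shape(self):
        """Default config reproduces the clinical cohort: 1382 spectra,
        332 patients, per-target counts 253/364/236/216/219/94."""
        ds = generate_cohort(CohortConfig(seed=SEED), sr.default_profiles())
        assert len(ds) == 1382
        assert len(ds.patients) == 332
        counts = ds.target_counts()
        assert counts[("BCC", "EPI-T")] == 253
        assert counts[("BCC", "LOB-T")] == 364
        assert counts[("BCC", "EPI-H")] == 236
        assert counts[("BCC", "DER-H")] == 216
        assert counts[("SCC", "TUM-T")] == 219
        assert counts[("SCC", "EPI-H")] == 94

    def test_two_patient_cohort(self):
        cfg = CohortConfig(
            n_patients_per_lesion={"BCC": 2},
            spectra_per_target={("BCC", "EPI-H"): 2},
            seed=0,
        )
        ds = generate_cohort(cfg, sr.default_profiles())
        assert len(ds) == 2
        assert len(set(s.patient_id for s in ds)) == 2

    def test_determinism_byte_level(self, tmp_path):
        from skinraman.io import write_spectra

        cfg = CohortConfig(
            n_patients_per_lesion={"BCC": 3},
            spectra_per_target={("BCC", "EPI-H"): 3, ("BCC", "LOB-T"): 3},
            seed=7,
        )
        a = generate_cohort(cfg, sr.default_profiles())
        b = generate_cohort(cfg, sr.default_profiles())
        write_spectra(a, tmp_path / "a")
        write_spectra(b, tmp_path / "b")
        assert (tmp_path / "a/spectra.csv").read_bytes() == (
            tmp_path / "b/spectra.csv"
        ).read_bytes()

    def test_invalid_lesion_target_rejected(self):
        cfg = CohortConfig(
            n_patients_per_lesion={"SCC": 2},
            spectra_per_target={("SCC", "LOB-T"): 2},
            seed=0,
        )
        with pytest.raises(ValueError, match="invalid for lesion"):
            generate_cohort(cfg, sr.default_profiles())

    def test_patients_never_span_lesions(self):
        ds = generate_cohort(CohortConfig.small(5, seed=1), sr.default_profiles())
        ds.validate()  # raises on any patient under two lesion types

    def test_planted_band_ratio_recovered(self):
        """A 1.7x amplitude on an isolated 1089 band gives a 1.7x mean
        integrated band area over the cohort (Monte Carlo, 100+ spectra)."""
        from skinraman.biochem import integrate_band

        band = BandSpec(1089.0, 18.0, 0.30)
        hi = BandSpec(1089.0, 18.0, 0.30 * 1.7)
        profiles = {
            "EPI-H": _flat_profile("EPI-H", [band], noise_sd=0.005),
            "LOB-T": _flat_profile("LOB-T", [hi], noise_sd=0.005),
        }
        cfg = CohortConfig(
            n_patients_per_lesion={"BCC": 20},
            spectra_per_target={("BCC", "EPI-H"): 100, ("BCC", "LOB-T"): 100},
            seed=SEED,
            include_dark=False,
            caf2_amplitude=0.0,
        )
        ds = generate_cohort(cfg, profiles)
        areas = {"EPI-H": [], "LOB-T": []}
        for s in ds:
            areas[s.target].append(
                integrate_band(
                    s.intensities, 1025, 1165, wavenumbers=s.wavenumbers
                ).value
            )
        ratio = np.mean(areas["LOB-T"]) / np.mean(areas["EPI-H"])
        assert ratio == pytest.approx(1.7, rel=0.02)


class TestProfiles:
    def test_null_profiles_share_bands(self):
        profiles = sr.default_profiles(effects=False)
        ref = [(b.center, b.amplitude) for b in profiles["EPI-H"].bands]
        for p in profiles.values():
            assert [(b.center, b.amplitude) for b in p.bands] == ref

    def test_planted_effect_sizes(self):
        """The profile library encodes the reported excesses exactly:
        LOB-T 1089 band 1.7x EPI-H; TUM-T 2930 band 1.44x EPI-H."""
        profiles = sr.default_profiles()

        def amp(label, center):
            return next(b for b in profiles[label].bands if b.center == center).amplitude

        assert amp("LOB-T", 1089.0) / amp("EPI-H", 1089.0) == pytest.approx(1.7)
        assert amp("TUM-T", 2930.0) / amp("EPI-H", 2930.0) == pytest.approx(1.44)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            BandSpec(1000.0, -5.0, 1.0)
        with pytest.raises(ValueError):
            BandSpec(3500.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            BandSpec(1000.0, 10.0, -1.0)
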