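"""Synthetic Raman cohort generator.

Emulates the statistical structure of ex-vivo confocal Raman acquisitions
of nonmelanoma skin cancer specimens so every downstream stage (the
preprocessing chain, the classifiers, occlusion attention, band
deconvolution) is testable without clinical data:

* a 0-3000 cm^-1 Raman-shift axis (default 1 cm^-1 channel spacing; band
  widths are kept >= 11 cm^-1, the optical resolution of the spectrometer);
* class-specific biochemical bands (Gaussian or Lorentzian line shapes)
  on a smooth polynomial fluorescence baseline;
* the single CaF2 sample-window line at 321 cm^-1, identical across
  classes (a nuisance feature);
* a smooth dark-background offset (detector signal with the laser off);
* per-patient random effects: a multiplicative intensity gain plus an
  additive offset, drawn once per patient (SNV normalization should cancel
  both within a spectral range — this makes the preprocessing testable);
* additive homoscedastic Gaussian noise per replicate, with triplicate
  acquisitions averaged as in the acquisition protocol.

The default tissue profiles plant the reported biochemical effects: the
DNA O-P-O backbone band at 1089 cm^-1 with a 1.7x amplitude in BCC tumor
lobules relative to healthy epidermis (a +70% band area), the keratin CH3
band at 2930 cm^-1 with a 1.44x amplitude in SCC tumor epidermis (+44%),
collagen-dominated dermis, and lipid bands (2855/2880 cm^-1) stronger in
epidermal classes than in tumor lobules and dermis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    ALL_TARGETS,
    LESION_TARGETS,
    RamanSpectrum,
    SpectralDataset,
)

__all__ = [
    "BandSpec",
    "TissueClassProfile",
    "CohortConfig",
    "PatientEffect",
    "generate_spectrum",
    "generate_dark_background",
    "generate_cohort",
    "default_profiles",
    "two_class_single_band_profiles",
    "default_grid",
    "CAF2_CENTER",
]

#: Raman shift of the single CaF2 sample-window line (cm^-1)
CAF2_CENTER = 321.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM/2.3548


def default_grid(start: float = 0.0, stop: float = 3050.0, step: float = 1.0) -> np.ndarray:
    """Wavenumber axis covering [start, stop] inclusive at ``step`` spacing."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: a symmetric peak on the Raman-shift axis.

    ``width`` is the full width at half maximum (FWHM, cm^-1).
    ``assignment`` is a free-text biochemical attribution carried as
    metadata only (e.g. "nu_s(O-P-O) DNA backbone").
    """

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if not 0.0 <= self.center <= 3000.0:
            raise ValueError("band center must lie in [0, 3000] cm^-1")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        if self.shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * ((grid - self.center) / sigma) ** 2)
        hwhm = self.width / 2.0
        return self.amplitude * hwhm**2 / ((grid - self.center) ** 2 + hwhm**2)

    @property
    def area(self) -> float:
        """Integrated band area (closed form)."""
        if self.shape == "gaussian":
            return self.amplitude * self.width * _FWHM_TO_SIGMA * math.sqrt(2.0 * math.pi)
        return self.amplitude * (self.width / 2.0) * math.pi


@dataclass
class TissueClassProfile:
    """Generative description of one tissue structure's Raman signature."""

    label: str
    bands: list[BandSpec]
    baseline_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(1))
    noise_sd: float = 0.0
    patient_effect_sd: float = 0.0
    patient_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        self.baseline_coeffs = np.asarray(self.baseline_coeffs, dtype=float)
        if self.noise_sd < 0 or self.patient_effect_sd < 0 or self.patient_shift_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def baseline(self, grid: np.ndarray) -> np.ndarray:
        """Smooth fluorescence background: polynomial in x = w/3000."""
        x = grid / 3000.0
        return np.polynomial.polynomial.polyval(x, self.baseline_coeffs)


@dataclass(frozen=True)
class PatientEffect:
    """Per-patient random effect: intensity gain and additive offset."""

    gain: float = 1.0
    shift: float = 0.0


@dataclass
class CohortConfig:
    """Shape and acquisition conventions of a synthetic cohort.

    Defaults reproduce the clinical cohort shape: 247 BCC and 85 SCC
    lesions; 253 EPI-T, 364 LOB-T, 236 EPI-H and 216 DER-H spectra on BCC,
    219 TUM-T and 94 EPI-H spectra on SCC (1382 spectra, 332 patients);
    each spectrum the mean of three replicate acquisitions.
    """

    n_patients_per_lesion: dict[str, int] = field(
        default_factory=lambda: {"BCC": 247, "SCC": 85}
    )
    spectra_per_target: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("BCC", "EPI-T"): 253,
            ("BCC", "LOB-T"): 364,
            ("BCC", "EPI-H"): 236,
            ("BCC", "DER-H"): 216,
            ("SCC", "TUM-T"): 219,
            ("SCC", "EPI-H"): 94,
        }
    )
    # stop at 3050 so the high-wavenumber analysis range (2800-3000) can be
    # margin-extended by 50 cm^-1; the nominal acquisition span [0, 3000]
    # is always covered
    grid_start: float = 0.0
    grid_stop: float = 3050.0
    grid_step: float = 1.0
    replicate_count: int = 3
    seed: int = 0
    keep_replicates: bool = False
    include_dark: bool = True
    caf2_amplitude: float = 0.4
    caf2_width: float = 12.0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if not (self.grid_start <= 0.0 and self.grid_stop >= 3000.0):
            # the analysis ranges only need 750-3050 coverage, but the
            # acquisition convention is the full 0-3000 axis
            pass
        for count in self.spectra_per_target.values():
            if count <= 0:
                raise ValueError("spectra counts must be > 0")
        for count in self.n_patients_per_lesion.values():
            if count <= 0:
                raise ValueError("patient counts must be > 0")

    def grid(self) -> np.ndarray:
        return default_grid(self.grid_start, self.grid_stop, self.grid_step)

    @classmethod
    def small(cls, n_patients_per_lesion: int = 20, seed: int = 0) -> "CohortConfig":
        """Desk-scale cohort: each patient contributes one spectrum per
        target of its lesion type.  Used for fast tests and smoke runs."""
        n = n_patients_per_lesion
        return cls(
            n_patients_per_lesion={"BCC": n, "SCC": n},
            spectra_per_target={
                ("BCC", "EPI-T"): n,
                ("BCC", "LOB-T"): n,
                ("BCC", "EPI-H"): n,
                ("BCC", "DER-H"): n,
                ("SCC", "TUM-T"): n,
                ("SCC", "EPI-H"): n,
            },
            seed=seed,
        )


def _caf2_band(config: CohortConfig) -> BandSpec:
    return BandSpec(
        CAF2_CENTER,
        config.caf2_width,
        config.caf2_amplitude,
        assignment="CaF2 sample window",
    )


def generate_spectrum(
    profile: TissueClassProfile,
    patient_offset: float | PatientEffect,
    grid: np.ndarray,
    rng: np.random.Generator,
    *,
    dark: RamanSpectrum | None = None,
    caf2: BandSpec | None = None,
    **meta,
) -> RamanSpectrum:
    """Simulate one replicate acquisition for a tissue-class profile.

    intensities = gain * (baseline + sum of bands + CaF2 line) + shift
                  + dark background + Normal(0, noise_sd) noise

    ``patient_offset`` may be a plain additive shift or a
    :class:`PatientEffect` (multiplicative gain + shift).  Deterministic
    given the state of ``rng``.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    for band in profile.bands:
        if not (lo <= band.center <= hi):
            raise ValueError(
                f"band center {band.center} cm^-1 outside grid span [{lo}, {hi}]"
            )
    effect = (
        patient_offset
        if isinstance(patient_offset, PatientEffect)
        else PatientEffect(shift=float(patient_offset))
    )
    signal = profile.baseline(grid)
    for band in profile.bands:
        signal = signal + band.profile(grid)
    if caf2 is not None:
        signal = signal + caf2.profile(grid)
    y = effect.gain * signal + effect.shift
    if dark is not None:
        y = y + dark.intensities
    if profile.noise_sd > 0:
        y = y + rng.normal(0.0, profile.noise_sd, size=grid.size)
    return RamanSpectrum(grid, y, target=profile.label if profile.label in ALL_TARGETS else None, **meta)


def generate_dark_background(
    grid: np.ndarray, rng: np.random.Generator, amplitude: float = 0.2
) -> RamanSpectrum:
    """Detector background with the Raman laser off: a smooth low-amplitude
    offset curve with no vibrational bands (order-3 polynomial with
    random coefficients)."""
    grid = np.asarray(grid, dtype=float)
    x = grid / max(grid[-1], 1.0)
    coeffs = amplitude * np.array([1.0, 0.0, 0.0, 0.0]) + amplitude * rng.normal(
        0.0, 0.25, size=4
    )
    y = np.polynomial.polynomial.polyval(x, coeffs)
    return RamanSpectrum(grid, y, spectrum_id="dark", replicate_index=0)


def generate_cohort(
    config: CohortConfig, profiles: dict[str, TissueClassProfile]
) -> SpectralDataset:
    """Generate a full synthetic cohort.

    Each spectrum belongs to exactly one patient; patients never span
    lesion types; the per-patient random effect (gain + shift) is drawn
    once per patient.  Spectra are simulated as ``replicate_count``
    replicates sharing everything but the noise; by default the dataset
    stores the replicate means (``replicate_index="mean"``), matching the
    acquisition convention of averaging three successive acquisitions.
    Deterministic given ``config.seed``.
    """
    for (lesion, target) in config.spectra_per_target:
        if lesion not in LESION_TARGETS:
            raise ValueError(f"unknown lesion {lesion!r}")
        if target not in LESION_TARGETS[lesion]:
            raise ValueError(f"target {target!r} invalid for lesion {lesion!r}")
        if target not in profiles:
            raise ValueError(f"no profile for target {target!r}")

    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    caf2 = _caf2_band(config)
    dark = generate_dark_background(grid, rng) if config.include_dark else None

    # per-patient latent effects, drawn once per patient in a fixed order
    patient_ids: dict[str, list[str]] = {}
    effects: dict[str, tuple[float, float]] = {}
    for lesion in sorted(config.n_patients_per_lesion):
        ids = [
            f"{lesion}-P{i + 1:04d}"
            for i in range(config.n_patients_per_lesion[lesion])
        ]
        patient_ids[lesion] = ids
        for pid in ids:
            effects[pid] = (rng.normal(), rng.normal())  # latent z_gain, z_shift

    spectra = []
    counter = 0
    for (lesion, target) in sorted(config.spectra_per_target):
        n = config.spectra_per_target[(lesion, target)]
        profile = profiles[target]
        pool = patient_ids[lesion]
        # even round-robin assignment over a shuffled patient order
        order = rng.permutation(len(pool))
        for j in range(n):
            pid = pool[order[j % len(pool)]]
            z_gain, z_shift = effects[pid]
            effect = PatientEffect(
                gain=float(np.exp(z_gain * profile.patient_effect_sd)),
                shift=float(z_shift * profile.patient_shift_sd),
            )
            counter += 1
            sid = f"S{counter:05d}"
            reps = [
                generate_spectrum(
                    profile,
                    effect,
                    grid,
                    rng,
                    dark=dark,
                    caf2=caf2,
                    spectrum_id=sid,
                    patient_id=pid,
                    lesion=lesion,
                    replicate_index=r,
                )
                for r in range(config.replicate_count)
            ]
            if config.keep_replicates:
                spectra.extend(reps)
            else:
                mean = np.mean([r.intensities for r in reps], axis=0)
                spectra.append(reps[0].with_intensities(mean, replicate_index="mean"))

    ds = SpectralDataset(
        spectra,
        dark=dark,
        metadata={"seed": config.seed, "generator": "skinraman.synth", "version": 1},
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# default tissue profiles
# ---------------------------------------------------------------------------

#: amplitude ratio of the 1089 cm^-1 DNA band, tumor lobules vs healthy
#: epidermis (a +70% integrated band area in LOB-T)
DNA_EXCESS_LOBT = 1.7
#: amplitude ratio of the 2930 cm^-1 keratin band, SCC tumor epidermis vs
#: healthy epidermis (+44%)
KERATIN_EXCESS_TUMT = 1.44

#: default per-replicate additive noise (intensity a.u.); band amplitudes
#: are O(0.3-2), so single-band SNR is ~10-60 before triplicate averaging
DEFAULT_NOISE_SD = 0.03
DEFAULT_PATIENT_EFFECT_SD = 0.15  # log-scale sd of the multiplicative gain
DEFAULT_PATIENT_SHIFT_SD = 0.05  # sd of the additive per-patient offset

#: smooth fluorescence hump shared by all classes (polynomial in w/3000)
DEFAULT_BASELINE = (0.8, 1.6, -1.2)


def _bands(rows: list[tuple[float, float, float, str]]) -> list[BandSpec]:
    return [BandSpec(c, w, a, assignment=t) for (c, w, a, t) in rows]


def default_profiles(
    effects: bool = True,
    noise_sd: float = DEFAULT_NOISE_SD,
    patient_effect_sd: float = DEFAULT_PATIENT_EFFECT_SD,
    patient_shift_sd: float = DEFAULT_PATIENT_SHIFT_SD,
) -> dict[str, TissueClassProfile]:
    """Profile library for the five tissue structures.

    With ``effects=True`` the class-specific biochemical differences are
    planted (DNA excess in LOB-T, keratin excess in TUM-T, collagen-rich
    dermis, epidermal lipids).  With ``effects=False`` every class uses the
    healthy-epidermis band set, making the classes statistically
    indistinguishable — the null cohort for permutation-style checks.
    """
    # (center, FWHM, amplitude, assignment); FWHM >= 11 cm^-1 throughout
    epi_h_rows = [
        (821.0, 14.0, 0.30, "nu(C-C) proline/hydroxyproline (collagen)"),
        (855.0, 14.0, 0.35, "proline ring / polysaccharides"),
        (938.0, 14.0, 0.30, "nu(C-C) protein backbone (collagen)"),
        (1002.0, 12.0, 0.50, "nu_s(C-C) ring breathing, phenylalanine"),
        (1065.0, 16.0, 0.30, "nu(C-C) skeletal, lipids"),
        (1089.0, 18.0, 0.30, "nu_s(O-P-O) DNA backbone"),
        (1126.0, 16.0, 0.25, "nu(C-N), nu(C-C)"),
        (1245.0, 22.0, 0.45, "amide III"),
        (1302.0, 18.0, 0.50, "CH2 twist, lipids"),
        (1450.0, 18.0, 0.80, "delta(CH) scissoring, proteins/lipids"),
        (1573.0, 16.0, 0.20, "delta(N-H), nu(C-N) nucleic acids"),
        (1655.0, 24.0, 0.90, "amide I"),
        (2855.0, 30.0, 1.20, "nu_s(CH2) lipids"),
        (2880.0, 20.0, 0.90, "nu_as(CH2) lipids"),
        (2930.0, 20.0, 1.50, "nu_s(CH3) mostly keratin"),
        (2955.0, 20.0, 0.80, "nu_as(CH3)"),
    ]

    def mk(label: str, rows) -> TissueClassProfile:
        return TissueClassProfile(
            label=label,
            bands=_bands(rows),
            baseline_coeffs=np.array(DEFAULT_BASELINE),
            noise_sd=noise_sd,
            patient_effect_sd=patient_effect_sd,
            patient_shift_sd=patient_shift_sd,
        )

    if not effects:
        return {label: mk(label, epi_h_rows) for label in ALL_TARGETS}

    def amended(overrides: dict[float, float]) -> list[tuple[float, float, float, str]]:
        return [
            (c, w, overrides.get(c, a), t) for (c, w, a, t) in epi_h_rows
        ]

    profiles = {
        "EPI-H": mk("EPI-H", epi_h_rows),
        # epidermis above tumor lobules: close to healthy epidermis with a
        # mild DNA/protein shift (the hardest pair in the clinical study)
        "EPI-T": mk(
            "EPI-T",
            amended({1089.0: 0.36, 1573.0: 0.24, 1450.0: 0.86, 2855.0: 1.10}),
        ),
        # dermis: collagen-dominated, lipid-poor
        "DER-H": mk(
            "DER-H",
            amended(
                {
                    855.0: 0.55,
                    938.0: 0.48,
                    1089.0: 0.28,
                    1245.0: 0.58,
                    1302.0: 0.32,
                    1655.0: 1.15,
                    2855.0: 0.60,
                    2880.0: 0.45,
                    2930.0: 1.00,
                    2955.0: 0.70,
                }
            ),
        ),
        # BCC tumor lobule: dense nuclei -> 1.7x DNA band; lipid-poor
        "LOB-T": mk(
            "LOB-T",
            amended(
                {
                    1089.0: 0.30 * DNA_EXCESS_LOBT,
                    1573.0: 0.30,
                    1302.0: 0.38,
                    2855.0: 0.50,
                    2880.0: 0.40,
                    2930.0: 1.00,
                    2955.0: 0.70,
                }
            ),
        ),
        # SCC tumor epidermis: protein/keratin overexpression -> 1.44x 2930
        "TUM-T": mk(
            "TUM-T",
            amended(
                {
                    821.0: 0.42,
                    1002.0: 0.68,
                    1245.0: 0.55,
                    1450.0: 1.00,
                    1573.0: 0.30,
                    2930.0: 1.50 * KERATIN_EXCESS_TUMT,
                }
            ),
        ),
    }
    return profiles


def two_class_single_band_profiles(
    band_center: float = 1089.0,
    amplitude_ratio: float = 2.0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> dict[str, TissueClassProfile]:
    """Two profiles identical except for the amplitude of one band.

    Used to test attribution: any model separating the two classes can only
    be using the single discriminative band, so occlusion attention must
    localize there.  Labels the pair as BCC structures EPI-H / LOB-T so the
    cohort machinery applies unchanged.
    """
    base = default_profiles(effects=False, noise_sd=noise_sd)
    a = base["EPI-H"]
    bands_hi = [
        replace(b, amplitude=b.amplitude * amplitude_ratio)
        if b.center == band_center
        else b
        for b in a.bands
    ]
    if all(b.center != band_center for b in a.bands):
        raise ValueError(f"no band at {band_center} cm^-1 in the base profile")
    b = replace(a, label="LOB-T", bands=bands_hi)
    return {"EPI-H": a, "LOB-T": b}
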