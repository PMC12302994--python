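"""Raman spectrum preprocessing chain.

Spectra are split into three spectral ranges — 800-1350, 1350-1750 and
2800-3000 cm^-1 — and each range goes through five steps:

1. extension of the range by 50 cm^-1 at both ends (avoids edge effects);
2. baseline correction by polynomial fitting (order 5 for the two
   fingerprint ranges, order 1 for the high-wavenumber range) under an
   asymmetric truncated-quadratic cost with tolerance 0.01, so points
   above the baseline (Raman peaks) are excluded from the fit;
3. removal of the extended margins;
4. standard normal variate (SNV) normalization;
5. Savitzky-Golay smoothing (order 2, window 13).

The three processed ranges are concatenated into the model input vector.
On a 1 cm^-1 grid with closed [lo, hi] intervals the canonical ranges give
551 + 401 + 201 = 1153 channels.

Replicate averaging and dark-background subtraction (acquisition-level
corrections) also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import RamanSpectrum, SpectralDataset

__all__ = [
    "SpectralRange",
    "PreprocessConfig",
    "Segment",
    "ProcessedSpectrum",
    "ProcessedDataset",
    "CANONICAL_RANGES",
    "average_replicates",
    "subtract_dark",
    "extract_extended_range",
    "baseline_correct",
    "trim_margins",
    "snv_normalize",
    "savgol_smooth",
    "preprocess_spectrum",
    "preprocess_dataset",
    "prepare_dataset",
    "feature_length",
]

_EPS = 1e-9  # float tolerance for closed-interval membership on the grid


@dataclass(frozen=True)
class SpectralRange:
    """One analysis range with its baseline polynomial order and margin."""

    lo: float
    hi: float
    baseline_order: int
    margin: float = 50.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("range lo must be < hi")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.baseline_order < 0:
            raise ValueError("baseline order must be >= 0")


#: the three canonical ranges: two fingerprint ranges (order-5 baseline)
#: and the high-wavenumber CH-stretch range (order-1 baseline)
CANONICAL_RANGES: tuple[SpectralRange, ...] = (
    SpectralRange(800.0, 1350.0, 5),
    SpectralRange(1350.0, 1750.0, 5),
    SpectralRange(2800.0, 3000.0, 1),
)


@dataclass
class PreprocessConfig:
    ranges: tuple[SpectralRange, ...] = CANONICAL_RANGES
    asym_tolerance: float = 0.01
    sg_order: int = 2
    sg_window: int = 13
    snv_ddof: int = 1  # sample sd; set 0 for population sd
    baseline_max_iter: int = 100
    baseline_converge_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.snv_ddof not in (0, 1):
            raise ValueError("snv_ddof must be 0 or 1")


@dataclass
class Segment:
    """A contiguous sub-spectrum of one range (possibly margin-extended)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("segment axis/intensity length mismatch")

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class ProcessedSpectrum:
    """Concatenated per-range feature vector for one spectrum.

    ``channel_map`` maps every feature channel back to its
    (range index, wavenumber) origin.
    """

    features: np.ndarray
    channel_map: pd.DataFrame  # columns: range_index, wavenumber
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.channel_map) != self.features.size:
            raise ValueError("channel_map length must equal feature length")


@dataclass
class ProcessedDataset:
    """Feature matrix (rows = spectra) plus manifest and channel map."""

    features: np.ndarray  # (n_spectra, n_channels)
    channel_map: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.manifest):
            raise ValueError("feature rows must match manifest rows")
        if self.features.shape[1] != len(self.channel_map):
            raise ValueError("feature columns must match channel map")

    def __len__(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# acquisition-level corrections
# ---------------------------------------------------------------------------


def average_replicates(replicates: list[RamanSpectrum]) -> RamanSpectrum:
    """Channelwise mean of replicate acquisitions (same grid and metadata)."""
    if not replicates:
        raise ValueError("no replicates to average")
    first = replicates[0]
    for r in replicates[1:]:
        if not np.array_equal(r.wavenumbers, first.wavenumbers):
            raise ValueError("replicate grid mismatch")
        if (r.spectrum_id, r.patient_id, r.lesion, r.target) != (
            first.spectrum_id,
            first.patient_id,
            first.lesion,
            first.target,
        ):
            raise ValueError("replicate metadata mismatch")
    mean = np.mean([r.intensities for r in replicates], axis=0)
    return first.with_intensities(mean, replicate_index="mean")


def subtract_dark(spectrum: RamanSpectrum, dark: RamanSpectrum) -> RamanSpectrum:
    """Subtract a laser-off background acquisition (same grid)."""
    if not np.array_equal(spectrum.wavenumbers, dark.wavenumbers):
        raise ValueError("dark background grid mismatch")
    return spectrum.with_intensities(spectrum.intensities - dark.intensities)


# ---------------------------------------------------------------------------
# per-range steps
# ---------------------------------------------------------------------------


def extract_extended_range(spectrum: RamanSpectrum, rng: SpectralRange) -> Segment:
    """Step 1: cut the margin-extended closed interval [lo-margin, hi+margin]."""
    w = spectrum.wavenumbers
    lo, hi = rng.lo - rng.margin, rng.hi + rng.margin
    if w[0] > lo + _EPS or w[-1] < hi - _EPS:
        raise ValueError(
            f"grid [{w[0]}, {w[-1]}] does not cover the extended range "
            f"[{lo}, {hi}] cm^-1 for range ({rng.lo}, {rng.hi})"
        )
    mask = (w >= lo - _EPS) & (w <= hi + _EPS)
    return Segment(w[mask], spectrum.intensities[mask])


def baseline_correct(
    segment: Segment,
    order: int,
    tolerance: float = 0.01,
    max_iter: int = 100,
    converge_tol: float = 1e-6,
) -> Segment:
    """Step 2: subtract a polynomial baseline fitted under an asymmetric
    truncated-quadratic cost.

    Iteratively reweighted least squares: points whose residual above the
    current baseline exceeds ``tolerance`` (relative to the segment's
    intensity span) are peaks and get zero weight; points on or below the
    baseline keep the ordinary quadratic cost (weight 1).  Iteration stops
    when the weights are stable or the baseline changes by less than
    ``converge_tol`` (relative); non-convergence is reported as a warning
    with the residual norm, returning the best fit so far.
    """
    y = segment.intensities
    x = segment.wavenumbers
    if len(segment) <= order + 1:
        raise ValueError("segment too short for the requested baseline order")
    scale = float(np.ptp(y))
    if scale == 0.0:
        scale = 1.0
    w = np.ones_like(y)
    baseline = np.zeros_like(y)
    converged = False
    for _ in range(max_iter):
        fit = np.polynomial.Polynomial.fit(x, y, order, w=np.sqrt(w))
        new_baseline = fit(x)
        r = (y - new_baseline) / scale
        new_w = np.where(r > tolerance, 0.0, 1.0)
        if new_w.sum() < order + 2:  # keep the fit overdetermined
            new_w = w
        delta = np.max(np.abs(new_baseline - baseline)) / scale
        stable = np.array_equal(new_w, w)
        baseline = new_baseline
        w = new_w
        if stable or delta < converge_tol:
            converged = True
            break
        # refit once more with the updated weights before declaring done
    if not converged:
        resid = float(np.linalg.norm((y - baseline)[w > 0]))
        warnings.warn(
            f"baseline fit did not converge in {max_iter} iterations "
            f"(weighted residual norm {resid:.3g})",
            RuntimeWarning,
        )
    return Segment(x, y - baseline)


def trim_margins(segment: Segment, rng: SpectralRange) -> Segment:
    """Step 3: restrict to the nominal closed interval [lo, hi]."""
    mask = (segment.wavenumbers >= rng.lo - _EPS) & (
        segment.wavenumbers <= rng.hi + _EPS
    )
    return Segment(segment.wavenumbers[mask], segment.intensities[mask])


def snv_normalize(segment: Segment, ddof: int = 1) -> Segment:
    """Step 4: standard normal variate — center and scale to unit variance."""
    y = segment.intensities
    sd = float(np.std(y, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("SNV undefined for a zero-variance segment")
    return Segment(segment.wavenumbers, (y - np.mean(y)) / sd)


def savgol_smooth(segment: Segment, order: int = 2, window: int = 13) -> Segment:
    """Step 5: Savitzky-Golay smoothing.

    Interior points use the classical least-squares convolution weights;
    the first/last (window-1)/2 points are smoothed by evaluating the
    terminal window's polynomial fit (scipy ``mode="interp"``).
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    if len(segment) < window:
        raise ValueError("segment shorter than the smoothing window")
    return Segment(
        segment.wavenumbers,
        savgol_filter(segment.intensities, window, order, mode="interp"),
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def _range_channels(grid: np.ndarray, rng: SpectralRange) -> np.ndarray:
    mask = (grid >= rng.lo - _EPS) & (grid <= rng.hi + _EPS)
    return grid[mask]


def feature_length(grid: np.ndarray, ranges=CANONICAL_RANGES) -> int:
    """Number of concatenated feature channels — a pure function of the
    grid and the ranges, never of spectrum content."""
    return sum(_range_channels(np.asarray(grid, float), r).size for r in ranges)


def preprocess_spectrum(
    spectrum: RamanSpectrum, config: PreprocessConfig | None = None
) -> ProcessedSpectrum:
    """Run the five-step chain on each range and concatenate in range order."""
    config = config or PreprocessConfig()
    feats, rows = [], []
    for i, rng in enumerate(config.ranges):
        try:
            seg = extract_extended_range(spectrum, rng)
            seg = baseline_correct(
                seg,
                rng.baseline_order,
                config.asym_tolerance,
                config.baseline_max_iter,
                config.baseline_converge_tol,
            )
            seg = trim_margins(seg, rng)
            seg = snv_normalize(seg, ddof=config.snv_ddof)
            seg = savgol_smooth(seg, config.sg_order, config.sg_window)
        except ValueError as err:
            raise ValueError(
                f"range {i} ({rng.lo}-{rng.hi} cm^-1): {err}"
            ) from err
        feats.append(seg.intensities)
        rows.append(
            pd.DataFrame({"range_index": i, "wavenumber": seg.wavenumbers})
        )
    return ProcessedSpectrum(
        features=np.concatenate(feats),
        channel_map=pd.concat(rows, ignore_index=True),
        source_id=spectrum.spectrum_id,
    )


def prepare_dataset(dataset: SpectralDataset) -> SpectralDataset:
    """Acquisition-level corrections: subtract the dark background (if
    recorded) and average replicate acquisitions grouped by spectrum id."""
    spectra = list(dataset)
    if dataset.dark is not None:
        spectra = [subtract_dark(s, dataset.dark) for s in spectra]
    groups: dict[str, list[RamanSpectrum]] = {}
    order: list[str] = []
    for s in spectra:
        if s.spectrum_id not in groups:
            order.append(s.spectrum_id)
        groups.setdefault(s.spectrum_id, []).append(s)
    merged = []
    for sid in order:
        reps = groups[sid]
        merged.append(reps[0] if len(reps) == 1 and reps[0].replicate_index == "mean"
                      else average_replicates(reps))
    return SpectralDataset(merged, dark=None, metadata=dataset.metadata)


def preprocess_dataset(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> ProcessedDataset:
    """Prepare (dark subtraction + replicate averaging) and preprocess every
    spectrum, returning the stacked feature matrix."""
    config = config or PreprocessConfig()
    prepared = prepare_dataset(dataset)
    processed = [preprocess_spectrum(s, config) for s in prepared]
    if not processed:
        raise ValueError("empty dataset")
    features = np.stack([p.features for p in processed])
    return ProcessedDataset(
        features=features,
        channel_map=processed[0].channel_map,
        manifest=prepared.manifest,
    )
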