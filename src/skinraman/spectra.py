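"""Core containers for confocal Raman acquisitions of skin tissue.

A Raman spectrum is a vibrational fingerprint: intensity of inelastically
scattered light as a function of Raman shift (wavenumber, cm^-1).  Spectra
here carry acquisition metadata — the patient the surgical specimen came
from, the lesion type (basal or squamous cell carcinoma) and the targeted
tissue structure:

=======  =====================================================
label    structure
=======  =====================================================
EPI-H    healthy epidermis (surgical margin)
EPI-T    epidermis above BCC tumor lobules
DER-H    healthy dermis (surgical margin)
LOB-T    BCC tumor lobule in the dermis
TUM-T    SCC tumor (cancerous keratinocytes in the epidermis)
=======  =====================================================

BCC specimens contribute EPI-T, LOB-T, EPI-H and DER-H spectra; SCC
specimens contribute TUM-T and EPI-H spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectralDataset",
    "BCC_TARGETS",
    "SCC_TARGETS",
    "ALL_TARGETS",
    "LESION_TARGETS",
    "CLASS_ORDER_4",
    "CLASS_ORDER_5",
]

BCC_TARGETS: tuple[str, ...] = ("EPI-T", "LOB-T", "EPI-H", "DER-H")
SCC_TARGETS: tuple[str, ...] = ("TUM-T", "EPI-H")
ALL_TARGETS: tuple[str, ...] = ("EPI-H", "EPI-T", "DER-H", "LOB-T", "TUM-T")
LESION_TARGETS: dict[str, frozenset[str]] = {
    "BCC": frozenset(BCC_TARGETS),
    "SCC": frozenset(SCC_TARGETS),
}

#: canonical class orders for the two multiclass setups (4-class: BCC
#: structures only; 5-class: BCC + SCC with EPI-H merged across lesions)
CLASS_ORDER_4: tuple[str, ...] = ("EPI-H", "EPI-T", "DER-H", "LOB-T")
CLASS_ORDER_5: tuple[str, ...] = ("EPI-H", "EPI-T", "DER-H", "LOB-T", "TUM-T")


@dataclass
class RamanSpectrum:
    """One Raman acquisition: wavenumber axis, intensities and metadata.

    Parameters
    ----------
    wavenumbers
        Strictly increasing Raman-shift axis in cm^-1.
    intensities
        Same-length intensity vector, arbitrary units.
    spectrum_id
        Identifier of the acquisition (shared by replicates).
    patient_id
        Identifier of the surgical specimen / patient.
    lesion
        ``"BCC"`` or ``"SCC"`` (``None`` for auxiliary spectra such as a
        dark background).
    target
        Tissue-structure label; must be valid for the lesion type.
    replicate_index
        0-based replicate number, or ``"mean"`` for a triplicate average.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    patient_id: str = ""
    lesion: str | None = None
    target: str | None = None
    replicate_index: int | str = "mean"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.lesion is not None:
            if self.lesion not in LESION_TARGETS:
                raise ValueError(f"unknown lesion type {self.lesion!r}")
            if self.target is not None and self.target not in LESION_TARGETS[self.lesion]:
                raise ValueError(
                    f"target {self.target!r} is not acquired on {self.lesion} lesions "
                    f"(valid: {sorted(LESION_TARGETS[self.lesion])})"
                )

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray, **meta) -> "RamanSpectrum":
        """Copy of this spectrum with new intensities (and metadata overrides)."""
        return replace(self, intensities=np.asarray(intensities, dtype=float), **meta)


class SpectralDataset:
    """A collection of Raman spectra plus its cohort manifest.

    The dataset is the unit of patient-grouped cross-validation splitting.
    It may carry a shared dark-background acquisition (``dark``) recorded
    with the Raman laser off, used for background subtraction.
    """

    def __init__(
        self,
        spectra: Sequence[RamanSpectrum],
        dark: RamanSpectrum | None = None,
        metadata: dict | None = None,
    ) -> None:
        self.spectra = list(spectra)
        self.dark = dark
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]

    @property
    def manifest(self) -> pd.DataFrame:
        """Per-spectrum metadata table (one row per spectrum)."""
        return pd.DataFrame(
            {
                "spectrum_id": [s.spectrum_id for s in self.spectra],
                "patient_id": [s.patient_id for s in self.spectra],
                "lesion": [s.lesion for s in self.spectra],
                "target": [s.target for s in self.spectra],
                "replicate_index": [s.replicate_index for s in self.spectra],
            }
        )

    @property
    def patients(self) -> list[str]:
        """Distinct patient identifiers, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.patient_id)
        return list(seen)

    def target_counts(self) -> pd.Series:
        return self.manifest.groupby(["lesion", "target"]).size()

    def filter(
        self,
        lesion: str | None = None,
        targets: Sequence[str] | None = None,
    ) -> "SpectralDataset":
        """Subset by lesion type and/or target labels (metadata preserved)."""
        keep = [
            s
            for s in self.spectra
            if (lesion is None or s.lesion == lesion)
            and (targets is None or s.target in set(targets))
        ]
        return SpectralDataset(keep, dark=self.dark, metadata=self.metadata)

    def validate(self) -> None:
        """Check manifest invariants: unique ids per replicate, consistent
        grids, and that no patient spans two lesion types."""
        seen: set[tuple[str, int | str]] = set()
        patient_lesion: dict[str, str | None] = {}
        for s in self.spectra:
            key = (s.spectrum_id, s.replicate_index)
            if key in seen:
                raise ValueError(f"duplicate spectrum/replicate {key}")
            seen.add(key)
            prev = patient_lesion.setdefault(s.patient_id, s.lesion)
            if prev != s.lesion:
                raise ValueError(
                    f"patient {s.patient_id} appears under two lesion types"
                )
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if not np.array_equal(s.wavenumbers, grid):
                    raise ValueError("spectra are not on a common wavenumber grid")
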