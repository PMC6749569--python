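"""Spectrum container and long-format CSV I/O.

A :class:`Spectrum` is a single fluorescence emission trace: a strictly
increasing wavelength grid (nm), one intensity per grid point (arbitrary
units / detector counts), and the metadata the downstream statistics key on
(excitation wavelength, dietary group, subject and spectrum identifiers).
Every processing step appends its name to ``processing_log`` so the applied
pipeline order can be audited on any output spectrum.

Collections of spectra are exchanged on disk as long-format CSV with columns
``spectrum_id, subject_id, group, excitation_nm, wavelength_nm, intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectrumCollection"]

LONG_COLUMNS = ["spectrum_id", "subject_id", "group", "excitation_nm", "wavelength_nm", "intensity"]


@dataclass
class Spectrum:
    """One emission spectrum plus acquisition metadata."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float
    group: str | None = None
    subject_id: str | None = None
    spectrum_id: str | None = None
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths.shape}) and intensities "
                f"({self.intensities.shape}) must have identical shape"
            )
        if self.wavelengths.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray, step: str) -> "Spectrum":
        """Copy with new intensities and ``step`` appended to the log."""
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            processing_log=[*self.processing_log, step],
        )

    def with_grid(self, wavelengths: np.ndarray, intensities: np.ndarray, step: str) -> "Spectrum":
        return replace(
            self,
            wavelengths=np.asarray(wavelengths, dtype=float),
            intensities=np.asarray(intensities, dtype=float),
            processing_log=[*self.processing_log, step],
        )


class SpectrumCollection:
    """Ordered bag of :class:`Spectrum` with long-CSV round-tripping."""

    def __init__(self, spectra: list[Spectrum] | None = None):
        self.spectra: list[Spectrum] = list(spectra) if spectra else []

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def append(self, s: Spectrum) -> None:
        self.spectra.append(s)

    def subset(self, *, excitation_nm: float | None = None, group: str | None = None) -> "SpectrumCollection":
        out = [
            s
            for s in self.spectra
            if (excitation_nm is None or s.excitation_nm == excitation_nm)
            and (group is None or s.group == group)
        ]
        return SpectrumCollection(out)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            if s.group is not None:
                seen.setdefault(s.group)
        return list(seen)

    @property
    def excitations(self) -> list[float]:
        seen: dict[float, None] = {}
        for s in self.spectra:
            seen.setdefault(s.excitation_nm)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (one row per wavelength point)."""
        parts = []
        for s in self.spectra:
            parts.append(
                pd.DataFrame(
                    {
                        "spectrum_id": s.spectrum_id,
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "excitation_nm": s.excitation_nm,
                        "wavelength_nm": s.wavelengths,
                        "intensity": s.intensities,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=LONG_COLUMNS)
        return pd.concat(parts, ignore_index=True)[LONG_COLUMNS]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectrumCollection":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long spectra table is missing columns: {missing}")
        spectra = []
        for sid, sub in df.groupby("spectrum_id", sort=False):
            sub = sub.sort_values("wavelength_nm")
            first = sub.iloc[0]
            spectra.append(
                Spectrum(
                    wavelengths=sub["wavelength_nm"].to_numpy(),
                    intensities=sub["intensity"].to_numpy(),
                    excitation_nm=float(first["excitation_nm"]),
                    group=None if pd.isna(first["group"]) else str(first["group"]),
                    subject_id=None if pd.isna(first["subject_id"]) else str(first["subject_id"]),
                    spectrum_id=str(sid),
                )
            )
        return cls(spectra)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "SpectrumCollection":
        return cls.from_frame(pd.read_csv(path))
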