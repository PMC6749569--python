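"""Instrument model: dark spectrum, relative spectral response, calibration lamp.

The spectrometer adds a dark (thermal/readout) offset to every acquisition and
weights the true emission by a wavelength-dependent relative sensitivity.  The
sensitivity is estimated from a calibration lamp of known spectral shape:
``response = measured_lamp / reference_lamp`` (after dark subtraction), and is
divided out of every tissue spectrum.

Instrument curves are persisted as two-column CSV (``wavelength_nm,value``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InstrumentModel", "default_instrument"]


@dataclass
class InstrumentModel:
    """Dark spectrum, relative spectral response and lamp reference on one grid."""

    wavelengths: np.ndarray
    dark_spectrum: np.ndarray
    response: np.ndarray
    lamp_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.dark_spectrum = np.asarray(self.dark_spectrum, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.lamp_reference is not None:
            self.lamp_reference = np.asarray(self.lamp_reference, dtype=float)
        n = self.wavelengths.size
        for name in ("dark_spectrum", "response"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must match the wavelength grid length")
        if np.any(self.response <= 0):
            raise ValueError("relative spectral response must be strictly positive")
        if np.any(self.dark_spectrum < 0):
            raise ValueError("dark counts must be non-negative")

    def response_on(self, wavelengths: np.ndarray) -> np.ndarray:
        """Response interpolated onto an arbitrary grid inside the model's span."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.min() < self.wavelengths.min() - 1e-9 or wavelengths.max() > self.wavelengths.max() + 1e-9:
            raise ValueError("requested grid extends beyond the instrument calibration range")
        return np.interp(wavelengths, self.wavelengths, self.response)

    def dark_on(self, wavelengths: np.ndarray) -> np.ndarray:
        wavelengths = np.asarray(wavelengths, dtype=float)
        return np.interp(wavelengths, self.wavelengths, self.dark_spectrum)

    def to_csv(self, dark_path, response_path, lamp_path=None) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths, "value": self.dark_spectrum}).to_csv(
            dark_path, index=False
        )
        pd.DataFrame({"wavelength_nm": self.wavelengths, "value": self.response}).to_csv(
            response_path, index=False
        )
        if lamp_path is not None and self.lamp_reference is not None:
            pd.DataFrame({"wavelength_nm": self.wavelengths, "value": self.lamp_reference}).to_csv(
                lamp_path, index=False
            )

    @classmethod
    def from_csv(cls, dark_path, response_path, lamp_path=None) -> "InstrumentModel":
        dark = pd.read_csv(dark_path)
        resp = pd.read_csv(response_path)
        if not np.allclose(dark["wavelength_nm"], resp["wavelength_nm"]):
            raise ValueError("dark and response files must share one wavelength grid")
        lamp = None
        if lamp_path is not None:
            lamp = pd.read_csv(lamp_path)["value"].to_numpy()
        return cls(
            wavelengths=dark["wavelength_nm"].to_numpy(),
            dark_spectrum=dark["value"].to_numpy(),
            response=resp["value"].to_numpy(),
            lamp_reference=lamp,
        )


def _planck_shape(wavelengths_nm: np.ndarray, temperature_k: float = 3100.0) -> np.ndarray:
    # Tungsten calibration lamps are well approximated by a ~3100 K grey body.
    lam = wavelengths_nm * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    radiance = 1.0 / (lam**5 * np.expm1(h * c / (lam * kb * temperature_k)))
    return radiance / radiance.max()


def default_instrument(
    wavelengths: np.ndarray | None = None,
    *,
    dark_level: float = 120.0,
    temperature_k: float = 3100.0,
) -> InstrumentModel:
    """Deterministic instrument with a bell-shaped CCD response and flat-ish dark.

    The response peaks near 550 nm and falls toward the UV and NIR edges, the
    typical shape of a grating + silicon-CCD spectrometer; the dark spectrum is
    a constant offset with a shallow wavelength ripple emulating pixel-to-pixel
    structure.
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 900.0 + 1e-9, 0.77)
    wavelengths = np.asarray(wavelengths, dtype=float)
    response = 0.35 + 0.65 * np.exp(-0.5 * ((wavelengths - 550.0) / 180.0) ** 2)
    dark = dark_level * (1.0 + 0.02 * np.sin(wavelengths / 17.0))
    lamp = _planck_shape(wavelengths, temperature_k)
    return InstrumentModel(
        wavelengths=wavelengths, dark_spectrum=dark, response=response, lamp_reference=lamp
    )
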