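"""Raw-counts to analysis-ready spectra.

The canonical order is dark subtraction -> spectral-sensitivity correction ->
boxcar smoothing -> excitation-dependent range restriction -> normalization
(intensity 1 at a reference wavelength, 600 nm by default).  Each operation
appends its name to the spectrum's ``processing_log``.
"""

from __future__ import annotations

import numpy as np

from .instrument import InstrumentModel
from .spectra import Spectrum, SpectrumCollection

__all__ = [
    "DEFAULT_RANGES",
    "subtract_dark",
    "boxcar_smooth",
    "correct_sensitivity",
    "normalize_at",
    "restrict_range",
    "preprocess_spectrum",
    "preprocess_collection",
]

# Excitation wavelength (nm) -> retained emission interval (nm), closed.
DEFAULT_RANGES: dict[float, tuple[float, float]] = {
    330.0: (435.5, 721.2),
    365.0: (435.5, 722.0),
    385.0: (440.9, 741.6),
    405.0: (490.9, 795.8),
    415.0: (500.2, 750.7),
}


def subtract_dark(raw: Spectrum, dark: Spectrum | np.ndarray) -> Spectrum:
    """Subtract the dark spectrum pointwise; negative results are clipped to 0.

    Counts are physical, so a measured value below the dark level is treated
    as zero signal rather than propagated as a negative intensity.
    """
    if isinstance(dark, Spectrum):
        if dark.wavelengths.shape != raw.wavelengths.shape or not np.allclose(
            dark.wavelengths, raw.wavelengths
        ):
            raise ValueError("raw and dark spectra must share an identical wavelength grid")
        dark_values = dark.intensities
    else:
        dark_values = np.asarray(dark, dtype=float)
        if dark_values.shape != raw.intensities.shape:
            raise ValueError("dark array length must match the spectrum grid")
    out = np.clip(raw.intensities - dark_values, 0.0, None)
    return raw.with_intensities(out, "subtract_dark")


def boxcar_smooth(s: Spectrum, width: int = 5) -> Spectrum:
    """Centered moving average of odd ``width``; windows truncate at the edges."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"boxcar width must be a positive odd integer, got {width}")
    n = len(s)
    if width > n:
        raise ValueError(f"boxcar width {width} exceeds spectrum length {n}")
    if width == 1:
        return s.with_intensities(s.intensities.copy(), "boxcar_smooth(width=1)")
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(s.intensities)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return s.with_intensities(out, f"boxcar_smooth(width={width})")


def correct_sensitivity(s: Spectrum, instrument: InstrumentModel) -> Spectrum:
    """Divide by the instrument's relative spectral response on the spectrum grid."""
    response = instrument.response_on(s.wavelengths)
    if np.any(response <= 0):
        raise ValueError("instrument response must be strictly positive on the spectrum grid")
    return s.with_intensities(s.intensities / response, "correct_sensitivity")


def normalize_at(s: Spectrum, ref_nm: float = 600.0) -> Spectrum:
    """Scale so the intensity at the grid point nearest ``ref_nm`` equals 1.

    Idempotent: normalizing an already-normalized spectrum changes nothing.
    """
    if ref_nm < s.wavelengths[0] or ref_nm > s.wavelengths[-1]:
        raise ValueError(f"reference wavelength {ref_nm} nm lies outside the spectrum grid")
    i = int(np.argmin(np.abs(s.wavelengths - ref_nm)))
    ref = s.intensities[i]
    if ref <= 0:
        raise ValueError(
            f"intensity at the reference wavelength ({s.wavelengths[i]:.2f} nm) must be positive"
        )
    return s.with_intensities(s.intensities / ref, f"normalize_at({ref_nm:g})")


def restrict_range(s: Spectrum, ranges: dict[float, tuple[float, float]] | None = None) -> Spectrum:
    """Keep grid points inside the closed excitation-dependent interval."""
    ranges = DEFAULT_RANGES if ranges is None else ranges
    exc = float(s.excitation_nm)
    if exc not in ranges:
        raise KeyError(f"no retained range defined for excitation {exc} nm")
    lo, hi = ranges[exc]
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no grid points fall inside [{lo}, {hi}] nm")
    return s.with_grid(
        s.wavelengths[mask], s.intensities[mask], f"restrict_range({lo:g},{hi:g})"
    )


def preprocess_spectrum(
    raw: Spectrum,
    instrument: InstrumentModel,
    *,
    boxcar_width: int = 5,
    ranges: dict[float, tuple[float, float]] | None = None,
    normalize_nm: float | None = 600.0,
) -> Spectrum:
    """Full chain: dark -> sensitivity -> boxcar -> restrict (-> normalize).

    ``normalize_nm=None`` stops after range restriction, which is the form the
    spectral-area statistic consumes; the classifier consumes the normalized
    form.
    """
    s = subtract_dark(raw, instrument.dark_on(raw.wavelengths))
    s = correct_sensitivity(s, instrument)
    s = boxcar_smooth(s, boxcar_width)
    s = restrict_range(s, ranges)
    if normalize_nm is not None:
        s = normalize_at(s, normalize_nm)
    return s


def preprocess_collection(
    raw: SpectrumCollection,
    instrument: InstrumentModel,
    **kwargs,
) -> SpectrumCollection:
    return SpectrumCollection([preprocess_spectrum(s, instrument, **kwargs) for s in raw])
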