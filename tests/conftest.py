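import warnings

import numpy as np
import pytest

import steatofluor as sf
from steatofluor import preprocess as pp
from steatofluor.spectra import Spectrum, SpectrumCollection


@pytest.fixture(scope="session")
def instrument():
    return sf.default_instrument()


@pytest.fixture(scope="session")
def full_study():
    """Default-design synthetic study (1870 spectra), simulated once per session."""
    return sf.simulate_study(seed=1)


@pytest.fixture(scope="session")
def corrected_study(full_study, instrument):
    """Dark/sensitivity/boxcar/range-corrected spectra of the default study."""
    spectra, lipid = full_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = pp.preprocess_collection(spectra, instrument, normalize_nm=None)
    return corrected, lipid


@pytest.fixture(scope="session")
def normalized_study(corrected_study):
    corrected, lipid = corrected_study
    normalized = SpectrumCollection([pp.normalize_at(s, 600.0) for s in corrected])
    return normalized, lipid


@pytest.fixture
def toy_spectrum():
    """Simple spectrum on a coarse grid for unit tests."""
    wl = np.linspace(400.0, 800.0, 81)
    return Spectrum(
        wavelengths=wl,
        intensities=100.0 + 50.0 * np.exp(-0.5 * ((wl - 600.0) / 60.0) ** 2),
        excitation_nm=405.0,
        group="MCC",
        subject_id="MCC-01",
        spectrum_id="toy-1",
    )


def small_design(n_per_group: int = 12, excitations=(330.0, 365.0, 385.0, 405.0, 415.0)):
    """Reduced study design for fast pipeline tests."""
    return sf.StudyDesign(
        subjects={"MCC": 3, "MCD2w": 3, "MCD8w": 3},
        spectra_counts={g: {float(e): n_per_group for e in excitations} for g in ("MCC", "MCD2w", "MCD8w")},
        excitations=tuple(float(e) for e in excitations),
    )
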