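"""Synthetic liver autofluorescence study generator.

Generates raw spectrometer counts with the statistical structure of an
ex-vivo murine steatosis study: three dietary groups (MCC control, MCD2w and
MCD8w, i.e. methionine–choline-deficient diet for two or eight weeks), five
excitation wavelengths (330/365/385/405/415 nm), several spectra per liver,
and a per-subject Oil-Red-O lipid content (% area) coupled to the fluorescence
through a latent severity factor.

The generative model for one spectrum is

    clean(lambda) = sum_f  A_f(group) * m_f(subject) * e_f(lambda_exc) * b_f(lambda)
    raw(lambda)   = clean(lambda) * response(lambda) + dark(lambda) + noise

where ``A_f`` is the stage-profile mean amplitude of fluorophore ``f``,
``m_f`` a per-subject lognormal multiplier, ``e_f`` the excitation efficiency
at the source wavelength and ``b_f`` a Gaussian band shape (optionally with a
secondary lobe, as for porphyrins).  Noise is zero-mean Gaussian with a
standard deviation proportional to the local signal plus an instrument floor,
so the spread of the spectra grows with disease stage as it does in real
acquisitions.

Lipid content per subject is drawn from a zero-truncated normal whose
Gaussian score is correlated (Gaussian copula) with the severity factor that
scales the lipid-associated fluorophores, so a positive rank correlation
between spectral area and lipid content exists by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import InstrumentModel, default_instrument
from .spectra import Spectrum, SpectrumCollection

__all__ = [
    "FluorophoreBand",
    "FluorophorePanel",
    "StageProfile",
    "StudyDesign",
    "default_panel",
    "default_profiles",
    "default_design",
    "simulate_study",
    "GROUPS",
    "EXCITATIONS",
]

GROUPS = ("MCC", "MCD2w", "MCD8w")
EXCITATIONS = (330.0, 365.0, 385.0, 405.0, 415.0)


@dataclass
class FluorophoreBand:
    """A single endogenous fluorophore emission band.

    ``excitation_efficiency`` maps source wavelength (nm) to a unitless
    efficiency >= 0; fluorophores not excited at a wavelength simply carry 0.
    ``secondary_*`` describe an optional second emission lobe (porphyrins emit
    at 620 nm with a secondary peak at 680 nm); ``secondary_fraction`` is the
    weight of that lobe in the mixture.
    """

    name: str
    emission_center: float
    emission_sigma: float
    excitation_efficiency: dict[float, float]
    secondary_center: float | None = None
    secondary_sigma: float | None = None
    secondary_fraction: float = 0.0
    lipid_associated: bool = False

    def __post_init__(self) -> None:
        if self.emission_sigma <= 0:
            raise ValueError(f"{self.name}: emission_sigma must be positive")
        if any(v < 0 for v in self.excitation_efficiency.values()):
            raise ValueError(f"{self.name}: excitation efficiencies must be >= 0")
        if not 0.0 <= self.secondary_fraction <= 1.0:
            raise ValueError(f"{self.name}: secondary_fraction must lie in [0, 1]")
        if self.secondary_fraction > 0 and (
            self.secondary_center is None or self.secondary_sigma is None or self.secondary_sigma <= 0
        ):
            raise ValueError(f"{self.name}: secondary lobe requires center and positive sigma")

    def shape(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-peak band shape (mixture of one or two Gaussian lobes)."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        main = np.exp(-0.5 * ((wavelengths - self.emission_center) / self.emission_sigma) ** 2)
        if self.secondary_fraction == 0.0:
            return main
        second = np.exp(-0.5 * ((wavelengths - self.secondary_center) / self.secondary_sigma) ** 2)
        return (1.0 - self.secondary_fraction) * main + self.secondary_fraction * second

    def efficiency(self, excitation_nm: float) -> float:
        return float(self.excitation_efficiency.get(float(excitation_nm), 0.0))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "emission_center": self.emission_center,
            "emission_sigma": self.emission_sigma,
            "excitation_efficiency": {float(k): float(v) for k, v in self.excitation_efficiency.items()},
            "secondary_center": self.secondary_center,
            "secondary_sigma": self.secondary_sigma,
            "secondary_fraction": self.secondary_fraction,
            "lipid_associated": self.lipid_associated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FluorophoreBand":
        d = dict(d)
        d["excitation_efficiency"] = {float(k): float(v) for k, v in d["excitation_efficiency"].items()}
        return cls(**d)


class FluorophorePanel:
    """Named collection of :class:`FluorophoreBand`, dict-like by name."""

    def __init__(self, bands: list[FluorophoreBand]):
        self._bands: dict[str, FluorophoreBand] = {}
        for b in bands:
            if b.name in self._bands:
                raise ValueError(f"duplicate fluorophore name {b.name!r}")
            self._bands[b.name] = b

    def __getitem__(self, name: str) -> FluorophoreBand:
        return self._bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __iter__(self):
        return iter(self._bands.values())

    @property
    def names(self) -> list[str]:
        return list(self._bands)

    def to_dict(self) -> dict:
        return {"bands": [b.to_dict() for b in self]}

    @classmethod
    def from_dict(cls, d: dict) -> "FluorophorePanel":
        return cls([FluorophoreBand.from_dict(b) for b in d["bands"]])


@dataclass
class StageProfile:
    """Mean fluorophore amplitudes and variability for one dietary group.

    ``amplitude`` maps fluorophore name to mean amplitude (arbitrary intensity
    units); ``subject_cv`` is the coefficient of variation of the lognormal
    per-subject multiplier; ``noise_sd`` is the relative scale of the
    signal-proportional Gaussian measurement noise; ``lipid_mean``/``lipid_sd``
    parameterize the zero-truncated-normal lipid content (% area).
    """

    group: str
    amplitude: dict[str, float]
    subject_cv: float
    noise_sd: float
    lipid_mean: float
    lipid_sd: float

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError(f"{self.group}: amplitudes must be >= 0")
        if self.subject_cv < 0:
            raise ValueError(f"{self.group}: subject_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError(f"{self.group}: noise_sd must be >= 0")
        if self.lipid_sd <= 0:
            raise ValueError(f"{self.group}: lipid_sd must be positive")

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "amplitude": dict(self.amplitude),
            "subject_cv": self.subject_cv,
            "noise_sd": self.noise_sd,
            "lipid_mean": self.lipid_mean,
            "lipid_sd": self.lipid_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageProfile":
        return cls(**d)


@dataclass
class StudyDesign:
    """Group sizes, spectra counts and wavelength grids of the study."""

    subjects: dict[str, int]
    spectra_counts: dict[str, dict[float, int]]  # group -> excitation -> n spectra
    subject_overrides: dict[str, dict[float, int]] = field(default_factory=dict)
    grid: tuple[float, float, float] = (420.0, 810.0, 0.77)  # start, stop, step (nm)
    excitations: tuple[float, ...] = EXCITATIONS
    noise_floor: float = 100.0  # signal-equivalent counts; noise sd = noise_sd * (floor + signal)

    def __post_init__(self) -> None:
        for g, per_exc in self.spectra_counts.items():
            for exc, n in per_exc.items():
                if n < 1:
                    raise ValueError(f"spectra count for ({g}, {exc}) must be >= 1")
        for g, n in self.subjects.items():
            if n < 1:
                raise ValueError(f"subject count for {g} must be >= 1")

    def n_subjects(self, group: str, excitation_nm: float) -> int:
        return self.subject_overrides.get(group, {}).get(float(excitation_nm), self.subjects[group])

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + 1e-9, step)

    @property
    def total_spectra(self) -> int:
        return sum(n for per_exc in self.spectra_counts.values() for n in per_exc.values())

    def to_dict(self) -> dict:
        return {
            "subjects": dict(self.subjects),
            "spectra_counts": {g: {float(e): int(n) for e, n in d.items()} for g, d in self.spectra_counts.items()},
            "subject_overrides": {g: {float(e): int(n) for e, n in d.items()} for g, d in self.subject_overrides.items()},
            "grid": list(self.grid),
            "excitations": list(self.excitations),
            "noise_floor": self.noise_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["spectra_counts"] = {g: {float(e): int(n) for e, n in v.items()} for g, v in d["spectra_counts"].items()}
        d["subject_overrides"] = {
            g: {float(e): int(n) for e, n in v.items()} for g, v in d.get("subject_overrides", {}).items()
        }
        d["grid"] = tuple(d["grid"])
        d["excitations"] = tuple(float(e) for e in d["excitations"])
        return cls(**d)


def default_panel() -> FluorophorePanel:
    """Built-in six-fluorophore liver panel.

    Band centers follow the emission maxima reported for hepatic tissue:
    NAD(P)H around 465 nm, vitamin A near 490 nm, flavins (FAD) at 520 nm,
    lipopigments at 540 nm, lipofuscin and porphyrins at 620 nm with the
    porphyrin secondary emission at 680 nm.  Excitation efficiencies encode
    the qualitative excitation pattern: NAD(P)H and vitamin A are not excited
    at 405/415 nm, flavins peak near 365 nm, and porphyrin excitation grows
    monotonically toward the violet.
    """
    return FluorophorePanel(
        [
            FluorophoreBand(
                "NAD(P)H", 465.0, 40.0,
                {330.0: 1.0, 365.0: 0.55, 385.0: 0.10, 405.0: 0.0, 415.0: 0.0},
            ),
            FluorophoreBand(
                "vitamin A", 490.0, 55.0,
                {330.0: 0.80, 365.0: 0.25, 385.0: 0.05, 405.0: 0.0, 415.0: 0.0},
            ),
            FluorophoreBand(
                "flavins", 520.0, 33.0,
                {330.0: 0.35, 365.0: 1.0, 385.0: 0.85, 405.0: 0.60, 415.0: 0.45},
            ),
            FluorophoreBand(
                "lipopigments", 540.0, 48.0,
                {330.0: 0.30, 365.0: 0.55, 385.0: 0.80, 405.0: 0.85, 415.0: 0.85},
                lipid_associated=True,
            ),
            FluorophoreBand(
                "lipofuscin", 620.0, 50.0,
                {330.0: 0.20, 365.0: 0.30, 385.0: 0.55, 405.0: 0.75, 415.0: 0.85},
                lipid_associated=True,
            ),
            FluorophoreBand(
                "porphyrins", 620.0, 22.0,
                {330.0: 0.08, 365.0: 0.15, 385.0: 0.45, 405.0: 0.85, 415.0: 1.0},
                secondary_center=680.0, secondary_sigma=20.0, secondary_fraction=0.30,
                lipid_associated=True,
            ),
        ]
    )


# Mean amplitudes per stage (arbitrary units).  NAD(P)H / vitamin A are held
# flat; the lipid-associated bands and flavins grow strictly with diet time so
# the >550 nm intensity rise, the band redshift and the growing spread all
# emerge from the mixture.  Lipid moments are the study's morphometric values.
_DEFAULT_STAGE_PARAMS = {
    "MCC": dict(
        amplitude={"NAD(P)H": 100.0, "vitamin A": 40.0, "flavins": 30.0,
                   "lipopigments": 18.0, "lipofuscin": 14.0, "porphyrins": 10.0},
        subject_cv=0.15, noise_sd=0.020, lipid_mean=0.16, lipid_sd=0.35,
    ),
    "MCD2w": dict(
        amplitude={"NAD(P)H": 100.0, "vitamin A": 40.0, "flavins": 48.0,
                   "lipopigments": 45.0, "lipofuscin": 45.0, "porphyrins": 32.0},
        subject_cv=0.25, noise_sd=0.025, lipid_mean=6.73, lipid_sd=5.78,
    ),
    "MCD8w": dict(
        amplitude={"NAD(P)H": 100.0, "vitamin A": 40.0, "flavins": 65.0,
                   "lipopigments": 85.0, "lipofuscin": 110.0, "porphyrins": 75.0},
        subject_cv=0.35, noise_sd=0.030, lipid_mean=10.99, lipid_sd=6.83,
    ),
}


def default_profiles() -> dict[str, StageProfile]:
    return {g: StageProfile(group=g, **_DEFAULT_STAGE_PARAMS[g]) for g in GROUPS}


# Spectra per group and excitation wavelength in the emulated study design.
_DEFAULT_COUNTS = {
    "MCC": {330.0: 132, 365.0: 133, 385.0: 136, 405.0: 145, 415.0: 137},
    "MCD2w": {330.0: 130, 365.0: 125, 385.0: 129, 405.0: 131, 415.0: 68},
    "MCD8w": {330.0: 111, 365.0: 116, 385.0: 128, 405.0: 125, 415.0: 124},
}


def default_design() -> StudyDesign:
    """Study design: 9/6/7 subjects, 1870 spectra, MCD2w reduced to 3 mice at 415 nm."""
    return StudyDesign(
        subjects={"MCC": 9, "MCD2w": 6, "MCD8w": 7},
        spectra_counts={g: dict(d) for g, d in _DEFAULT_COUNTS.items()},
        subject_overrides={"MCD2w": {415.0: 3}},
    )


def _lognormal_params(cv: float) -> tuple[float, float]:
    """(mu, sigma) of a unit-mean lognormal with the given coefficient of variation."""
    if cv == 0.0:
        return 0.0, 0.0
    sigma2 = math.log1p(cv * cv)
    return -0.5 * sigma2, math.sqrt(sigma2)


def _truncnorm_from_gaussian(score: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal scores to a normal(mean, sd) truncated at zero."""
    a = (0.0 - mean) / sd
    u = stats.norm.cdf(score)
    # clip away exact 0/1 so ppf stays finite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def simulate_study(
    design: StudyDesign | None = None,
    panel: FluorophorePanel | None = None,
    profiles: dict[str, StageProfile] | None = None,
    instrument: InstrumentModel | None = None,
    seed: int = 0,
    lipid_coupling: float = 0.8,
) -> tuple[SpectrumCollection, pd.DataFrame]:
    """Simulate a full multi-excitation study.

    Parameters
    ----------
    design, panel, profiles, instrument
        Study layout, fluorophore panel, per-group generative parameters and
        instrument model; defaults reproduce the emulated study conditions.
    seed
        Seed for all randomness; identical seed and configuration give
        identical output.
    lipid_coupling
        Copula correlation in [0, 1] between the per-subject severity factor
        (which scales the lipid-associated fluorophores) and the Gaussian
        score of the lipid draw.  0 decouples them, for null testing.

    Returns
    -------
    (SpectrumCollection, DataFrame)
        Raw spectra (counts, instrument effects included) with metadata, and
        a lipid table with columns ``subject_id, group, lipid_pct``.
    """
    design = design or default_design()
    panel = panel or default_panel()
    profiles = profiles or default_profiles()
    instrument = instrument or default_instrument()
    if not -1.0 <= lipid_coupling <= 1.0:
        raise ValueError("lipid_coupling must lie in [-1, 1]")
    for g, prof in profiles.items():
        unknown = [f for f in prof.amplitude if f not in panel]
        if unknown:
            raise ValueError(f"profile {g!r} references unknown fluorophores: {unknown}")

    rng = np.random.default_rng(seed)
    grid = design.wavelength_grid()
    response = instrument.response_on(grid)
    dark = instrument.dark_on(grid)

    # Per-band unit-peak shapes on the grid, computed once.
    shapes = {b.name: b.shape(grid) for b in panel}

    lipid_rows = []
    spectra = SpectrumCollection()
    groups = [g for g in design.subjects if g in profiles]

    # Draw per-subject latent factors in a fixed order (group, subject index).
    subject_latents: dict[tuple[str, int], tuple[float, float]] = {}
    for g in groups:
        prof = profiles[g]
        for i in range(design.subjects[g]):
            severity = rng.standard_normal()  # scales lipid-associated bands
            baseline = rng.standard_normal()  # scales the remaining bands
            subject_latents[(g, i)] = (severity, baseline)
            lipid_score = lipid_coupling * severity + math.sqrt(
                1.0 - lipid_coupling**2
            ) * rng.standard_normal()
            lipid = float(_truncnorm_from_gaussian(np.asarray(lipid_score), prof.lipid_mean, prof.lipid_sd))
            lipid_rows.append({"subject_id": f"{g}-{i + 1:02d}", "group": g, "lipid_pct": lipid})

    for g in groups:
        prof = profiles[g]
        mu_ln, sigma_ln = _lognormal_params(prof.subject_cv)
        for exc in design.excitations:
            n_spec = design.spectra_counts[g][float(exc)]
            n_subj = design.n_subjects(g, exc)
            for j in range(n_spec):
                subj = j % n_subj
                severity, baseline = subject_latents[(g, subj)]
                clean = np.zeros_like(grid)
                for band in panel:
                    amp = prof.amplitude.get(band.name, 0.0)
                    eff = band.efficiency(exc)
                    if amp == 0.0 or eff == 0.0:
                        continue
                    latent = severity if band.lipid_associated else baseline
                    mult = math.exp(mu_ln + sigma_ln * latent)
                    clean += amp * mult * eff * shapes[band.name]
                signal = clean * response
                sd = prof.noise_sd * (design.noise_floor + signal)
                raw = signal + dark + rng.standard_normal(grid.size) * sd
                spectra.append(
                    Spectrum(
                        wavelengths=grid,
                        intensities=raw,
                        excitation_nm=float(exc),
                        group=g,
                        subject_id=f"{g}-{subj + 1:02d}",
                        spectrum_id=f"{g}-exc{int(exc)}-{j + 1:03d}",
                        processing_log=["simulated_raw"],
                    )
                )

    lipid_table = pd.DataFrame(lipid_rows, columns=["subject_id", "group", "lipid_pct"])
    return spectra, lipid_table
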