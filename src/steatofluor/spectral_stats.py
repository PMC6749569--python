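"""Spectral area statistic and univariate group comparisons.

The area under the curve (AUC) of a fluorescence spectrum over a fixed,
excitation-dependent interval is the univariate summary used to compare
dietary groups (one-way ANOVA with Tukey HSD post-hoc) and to correlate the
optical signal with morphometric lipid content (Spearman rank correlation on
per-subject mean AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import Spectrum, SpectrumCollection

__all__ = [
    "DEFAULT_INTEGRATION_LIMITS",
    "AUCResult",
    "GroupComparison",
    "SpearmanResult",
    "spectral_auc",
    "auc_table",
    "anova_tukey",
    "spearman_vs_lipid",
    "per_subject_mean_auc",
]

# Excitation wavelength (nm) -> spectral integration interval (nm).  The lower
# limit rises with the excitation wavelength to stay clear of the excitation
# band.  The limits intentionally exceed the measured ranges; the integral is
# taken over the intersection with the actual grid, which leaves within-
# excitation comparisons unaffected.
DEFAULT_INTEGRATION_LIMITS: dict[float, tuple[float, float]] = {
    330.0: (425.0, 800.0),
    365.0: (425.0, 800.0),
    385.0: (440.0, 800.0),
    405.0: (490.0, 800.0),
    415.0: (500.0, 800.0),
}


@dataclass
class AUCResult:
    spectrum_id: str | None
    excitation_nm: float
    auc: float
    group: str | None = None
    subject_id: str | None = None


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    alpha: float
    pairs: list[dict] = field(default_factory=list)  # group_a, group_b, difference, p_adj, reject

    @property
    def rejected_pairs(self) -> list[tuple[str, str]]:
        return [(p["group_a"], p["group_b"]) for p in self.pairs if p["reject"]]

    def all_pairs_separated(self) -> bool:
        return all(p["reject"] for p in self.pairs)


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def spectral_auc(
    s: Spectrum, limits: dict[float, tuple[float, float]] | None = None
) -> AUCResult:
    """Trapezoidal integral of intensity over the excitation's interval.

    Integration runs over the grid points inside ``[a, b]`` intersected with
    the spectrum's own span; a warning is emitted when the stated interval
    extends beyond the measured grid.
    """
    limits = DEFAULT_INTEGRATION_LIMITS if limits is None else limits
    exc = float(s.excitation_nm)
    if exc not in limits:
        raise KeyError(f"no integration limits defined for excitation {exc} nm")
    a, b = limits[exc]
    if a >= b:
        raise ValueError(f"integration limits must satisfy a < b, got ({a}, {b})")
    mask = (s.wavelengths >= a) & (s.wavelengths <= b)
    if not mask.any():
        raise ValueError(f"no grid points inside the integration interval [{a}, {b}] nm")
    if a < s.wavelengths[0] or b > s.wavelengths[-1]:
        warnings.warn(
            f"integration interval [{a}, {b}] nm exceeds the measured span "
            f"[{s.wavelengths[0]:.1f}, {s.wavelengths[-1]:.1f}] nm; integrating the intersection",
            stacklevel=2,
        )
    value = float(np.trapezoid(s.intensities[mask], s.wavelengths[mask]))
    return AUCResult(
        spectrum_id=s.spectrum_id,
        excitation_nm=exc,
        auc=value,
        group=s.group,
        subject_id=s.subject_id,
    )


def auc_table(
    spectra: SpectrumCollection, limits: dict[float, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Per-spectrum AUC as a tidy frame (spectrum_id, subject_id, group, excitation_nm, auc)."""
    rows = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for s in spectra:
            r = spectral_auc(s, limits)
            rows.append(
                {
                    "spectrum_id": r.spectrum_id,
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "excitation_nm": r.excitation_nm,
                    "auc": r.auc,
                }
            )
    for message in dict.fromkeys(str(w.message) for w in caught):
        warnings.warn(message, UserWarning, stacklevel=2)
    return pd.DataFrame(rows, columns=["spectrum_id", "subject_id", "group", "excitation_nm", "auc"])


def anova_tukey(auc_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by Tukey HSD on all group pairs.

    Unequal group sizes use the Tukey–Kramer form.  With exactly two groups
    the Tukey adjusted p equals the pooled-variance two-sample t-test p.
    """
    groups = list(auc_by_group)
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    samples = [np.asarray(auc_by_group[g], dtype=float) for g in groups]
    for g, x in zip(groups, samples):
        if x.size < 2:
            raise ValueError(f"group {g!r} needs at least two observations")

    if all(np.ptp(x) == 0 for x in samples) and len({float(x[0]) for x in samples}) > 1:
        # zero within-group variance with unequal means: separation is certain
        f_stat, p_val = np.inf, 0.0
    else:
        f_stat, p_val = stats.f_oneway(*samples)

    tukey = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(tukey.pvalue[i, j])
            pairs.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "difference": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": p_adj,
                    "reject": bool(p_adj < alpha),
                }
            )
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p_val), alpha=alpha, pairs=pairs)


def per_subject_mean_auc(auc: pd.DataFrame, excitation_nm: float) -> pd.DataFrame:
    """Mean AUC per subject at one excitation (columns subject_id, group, mean_auc)."""
    sub = auc[auc["excitation_nm"] == float(excitation_nm)]
    out = (
        sub.groupby(["subject_id", "group"], sort=True)["auc"].mean().reset_index()
    )
    return out.rename(columns={"auc": "mean_auc"})


def spearman_vs_lipid(per_subject_auc, lipid_pct) -> SpearmanResult:
    """Spearman rank correlation between per-subject mean AUC and lipid content.

    Ties receive average ranks; the p-value uses the t approximation on
    n - 2 degrees of freedom.
    """
    x = np.asarray(per_subject_auc, dtype=float)
    y = np.asarray(lipid_pct, dtype=float)
    if x.size != y.size:
        raise ValueError("per-subject AUC and lipid content must be paired")
    if x.size < 4:
        raise ValueError("at least 4 paired subjects are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=int(x.size))
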