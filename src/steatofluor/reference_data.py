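"""Published summary tables from the ex-vivo mouse steatosis study.

The raw spectra of the original study are not publicly deposited, but its
report tables are: the distribution of spectra over groups and excitation
wavelengths, the paired classification / cross-validation confusion matrices
of the QDA model, and the one-vs-rest ROC summaries.  They are embedded here
as plain numbers so that the package's report arithmetic (success and error
rates, table averages) can be validated against the printed values and so the
synthetic study design can mirror the real one.
"""

from __future__ import annotations

import numpy as np

from .discriminant import ConfusionMatrix

__all__ = [
    "GROUPS",
    "EXCITATIONS_NM",
    "SPECTRA_COUNTS",
    "LIPID_CONTENT_PCT",
    "reference_confusion",
    "REFERENCE_ROC",
    "REFERENCE_SPEARMAN",
]

GROUPS = ("MCC", "MCD2w", "MCD8w")
EXCITATIONS_NM = (330, 365, 385, 405, 415)

# group -> excitation -> number of measured spectra (column sums 683/583/604,
# grand total 1870)
SPECTRA_COUNTS = {
    "MCC": {330: 132, 365: 133, 385: 136, 405: 145, 415: 137},
    "MCD2w": {330: 130, 365: 125, 385: 129, 405: 131, 415: 68},
    "MCD8w": {330: 111, 365: 116, 385: 128, 405: 125, 415: 124},
}

# morphometric lipid content, % area (mean, sd) per group
LIPID_CONTENT_PCT = {"MCC": (0.16, 0.35), "MCD2w": (6.73, 5.78), "MCD8w": (10.99, 6.83)}

# excitation -> scheme -> 3x3 counts (rows actual MCC/MCD2w/MCD8w, columns predicted)
_CONFUSION = {
    330: {
        "classification": [[117, 15, 0], [2, 128, 0], [0, 5, 106]],
        "cross-validation": [[115, 16, 1], [4, 126, 0], [1, 5, 105]],
    },
    365: {
        "classification": [[133, 0, 0], [4, 121, 0], [0, 0, 116]],
        "cross-validation": [[133, 0, 0], [6, 118, 1], [0, 1, 114]],
    },
    385: {
        "classification": [[135, 1, 0], [1, 127, 1], [1, 0, 127]],
        "cross-validation": [[135, 1, 0], [4, 124, 1], [1, 0, 126]],
    },
    405: {
        "classification": [[145, 0, 0], [2, 129, 0], [1, 1, 123]],
        "cross-validation": [[145, 0, 0], [3, 128, 0], [1, 1, 123]],
    },
    415: {
        "classification": [[137, 0, 0], [1, 67, 0], [2, 0, 122]],
        "cross-validation": [[136, 0, 1], [1, 67, 0], [2, 0, 123]],
    },
}


def reference_confusion(excitation_nm: int, scheme: str = "classification") -> ConfusionMatrix:
    """Published confusion matrix for one excitation wavelength and scheme."""
    if excitation_nm not in _CONFUSION:
        raise KeyError(f"no reference confusion matrix for excitation {excitation_nm} nm")
    if scheme not in ("classification", "cross-validation"):
        raise ValueError("scheme must be 'classification' or 'cross-validation'")
    return ConfusionMatrix(
        labels=list(GROUPS),
        counts=np.array(_CONFUSION[excitation_nm][scheme], dtype=int),
        scheme=scheme,
    )


# excitation -> class -> (roc auc, optimal sensitivity, 1 - optimal specificity,
# optimal cutoff); classes are one-vs-rest
REFERENCE_ROC = {
    330: {
        "MCC": (0.980, 0.909, 0.041, 0.359),
        "MCD2w": (0.973, 0.985, 0.128, 0.341),
        "MCD8w": (0.995, 0.973, 0.031, 0.287),
    },
    365: {
        "MCC": (0.998, 0.977, 0.008, 0.841),
        "MCD2w": (0.990, 0.960, 0.032, 0.295),
        "MCD8w": (0.998, 1.000, 0.008, 0.116),
    },
    385: {
        "MCC": (0.994, 0.985, 0.016, 0.847),
        "MCD2w": (0.991, 0.977, 0.049, 0.155),
        "MCD8w": (0.992, 0.977, 0.011, 0.434),
    },
    405: {
        "MCC": (0.997, 0.986, 0.004, 0.548),
        "MCD2w": (0.997, 0.992, 0.007, 0.554),
        "MCD8w": (0.993, 0.992, 0.007, 0.222),
    },
    415: {
        "MCC": (0.994, 0.985, 0.031, 0.456),
        "MCD2w": (0.996, 0.985, 0.027, 0.363),
        "MCD8w": (0.997, 0.992, 0.000, 0.003),
    },
}

# excitation -> (Spearman rho of per-subject mean AUC vs lipid content, p-value)
REFERENCE_SPEARMAN = {
    330: (0.57538, 0.00508),
    365: (0.24901, 0.26378),
    385: (0.7572, 4.50604e-5),
    405: (0.75833, 4.32295e-5),
    415: (0.72632, 4.29233e-4),
}
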