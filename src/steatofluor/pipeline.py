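"""End-to-end reproducible runs: simulate -> preprocess -> statistics -> reports.

A :class:`RunConfig` fully specifies a run (seed, design and profile
overrides, preprocessing and analysis options); re-executing a saved config
reproduces the run bit-for-bit.  :func:`run_all` executes every stage for
each excitation wavelength independently and writes a manifest with a SHA-256
checksum per artifact; :func:`render_tables` lays the results out in the
report formats used in the field (paired classification/cross-validation
confusion cells, error rates under both total definitions, per-class ROC
summaries with averages, spectra-count tables).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import spectral_stats as ss
from .discriminant import (
    canonical_plane,
    classify,
    confusion_rates,
    covariance_equality_test,
    loocv,
    pca_fit,
    qda_fit,
    qda_predict,
)
from .instrument import default_instrument
from .roc import roc_report
from .simulate import (
    FluorophorePanel,
    StageProfile,
    StudyDesign,
    default_design,
    default_panel,
    default_profiles,
    simulate_study,
)
from .spectra import SpectrumCollection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "render_tables", "RunArtifacts"]


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    seed: int = 0
    output_dir: str = "steatofluor_run"
    # simulation
    design: dict | None = None  # StudyDesign.to_dict() override
    panel: dict | None = None  # FluorophorePanel.to_dict() override
    profiles: dict | None = None  # group -> StageProfile.to_dict() override
    lipid_coupling: float = 0.8
    # preprocessing
    boxcar_width: int = 5
    normalize_nm: float = 600.0
    ranges: dict | None = None  # excitation -> [lo, hi]
    integration_limits: dict | None = None  # excitation -> [a, b]
    # analysis
    n_components: int = 6
    variance_floor: float = 0.90
    alpha: float = 0.05
    priors: str = "empirical"
    roc_score_source: str = "classification"  # or "loocv"
    grid_resolution: int = 400
    write_spectra: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    # ---- resolved objects -------------------------------------------------

    def resolve_design(self) -> StudyDesign:
        return StudyDesign.from_dict(self.design) if self.design else default_design()

    def resolve_panel(self) -> FluorophorePanel:
        return FluorophorePanel.from_dict(self.panel) if self.panel else default_panel()

    def resolve_profiles(self) -> dict[str, StageProfile]:
        if self.profiles:
            return {g: StageProfile.from_dict(d) for g, d in self.profiles.items()}
        return default_profiles()

    def resolve_ranges(self) -> dict[float, tuple[float, float]]:
        if self.ranges:
            return {float(k): (float(v[0]), float(v[1])) for k, v in self.ranges.items()}
        return dict(pp.DEFAULT_RANGES)

    def resolve_limits(self) -> dict[float, tuple[float, float]]:
        if self.integration_limits:
            return {float(k): (float(v[0]), float(v[1])) for k, v in self.integration_limits.items()}
        return dict(ss.DEFAULT_INTEGRATION_LIMITS)

    def validate(self) -> None:
        design = self.resolve_design()
        ranges = self.resolve_ranges()
        limits = self.resolve_limits()
        for exc in design.excitations:
            if float(exc) not in ranges:
                raise ValueError(f"excitation {exc} nm has no retained-range entry")
            if float(exc) not in limits:
                raise ValueError(f"excitation {exc} nm has no integration-limits entry")
        if self.roc_score_source not in ("classification", "loocv"):
            raise ValueError("roc_score_source must be 'classification' or 'loocv'")
        if self.priors not in ("empirical", "uniform"):
            raise ValueError("priors must be 'empirical' or 'uniform'")
        if self.boxcar_width < 1 or self.boxcar_width % 2 == 0:
            raise ValueError("boxcar_width must be a positive odd integer")


@dataclass
class RunArtifacts:
    """In-memory results of a run plus the list of files written."""

    config: RunConfig
    results: dict  # excitation -> stage results
    lipid_table: pd.DataFrame
    auc_table: pd.DataFrame
    manifest: dict
    output_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def analyze_excitation(
    normalized: SpectrumCollection,
    excitation_nm: float,
    *,
    n_components: int = 6,
    variance_floor: float = 0.90,
    alpha: float = 0.05,
    priors: str = "empirical",
    roc_score_source: str = "classification",
    grid_resolution: int = 400,
) -> dict:
    """PCA -> covariance gate -> QDA -> LOOCV -> ROC -> canonical plane for one excitation."""
    sub = normalized.subset(excitation_nm=excitation_nm)
    groups = sub.groups
    X = np.vstack([s.intensities for s in sub])
    y = np.array([s.group for s in sub])

    pca = pca_fit(X, n_components=n_components, variance_floor=variance_floor)
    scores = pca.transform(X)
    by_group = {g: scores[y == g] for g in groups}

    box = covariance_equality_test(by_group, alpha=alpha)
    model = qda_fit(by_group, priors=priors)
    cm_cls = classify(model, scores, y)
    cm_cv, cv_posteriors = loocv(scores, y, priors=priors, return_posteriors=True)
    if roc_score_source == "classification":
        _, posteriors = qda_predict(model, scores)
    else:
        posteriors = cv_posteriors
    roc = roc_report(posteriors, y, model.labels)
    plane = canonical_plane(scores, y, grid_resolution=grid_resolution, priors=priors)

    return {
        "excitation_nm": excitation_nm,
        "n_observations": int(len(sub)),
        "groups": groups,
        "pca": pca,
        "pca_explained_pct": float(100.0 * pca.explained_variance_fraction.sum()),
        "box_m": box,
        "model": model,
        "confusion": {
            "classification": cm_cls,
            "cross-validation": cm_cv,
        },
        "rates": {
            "classification": confusion_rates(cm_cls),
            "cross-validation": confusion_rates(cm_cv),
        },
        "roc": roc,
        "canonical_plane": plane,
    }


def run_all(config: RunConfig) -> RunArtifacts:
    """Execute every stage for each excitation wavelength and write all artifacts."""
    config.validate()
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    design = config.resolve_design()
    panel = config.resolve_panel()
    profiles = config.resolve_profiles()
    instrument = default_instrument()
    ranges = config.resolve_ranges()
    limits = config.resolve_limits()

    logger.info("simulating study (seed=%d, %d spectra)", config.seed, design.total_spectra)
    raw, lipid = simulate_study(
        design, panel, profiles, instrument, seed=config.seed, lipid_coupling=config.lipid_coupling
    )

    logger.info("preprocessing %d spectra", len(raw))
    corrected = pp.preprocess_collection(
        raw, instrument, boxcar_width=config.boxcar_width, ranges=ranges, normalize_nm=None
    )
    normalized = SpectrumCollection(
        [pp.normalize_at(s, config.normalize_nm) for s in corrected]
    )

    auc = ss.auc_table(corrected, limits)
    results: dict = {}
    for exc in design.excitations:
        t_exc = time.time()
        exc = float(exc)
        sub_auc = auc[auc["excitation_nm"] == exc]
        by_group = {g: sub_auc.loc[sub_auc["group"] == g, "auc"].to_numpy() for g in design.subjects}
        comparison = ss.anova_tukey(by_group, alpha=config.alpha)
        per_subj = ss.per_subject_mean_auc(auc, exc).merge(lipid, on=["subject_id", "group"])
        spearman = ss.spearman_vs_lipid(per_subj["mean_auc"], per_subj["lipid_pct"])
        analysis = analyze_excitation(
            normalized,
            exc,
            n_components=config.n_components,
            variance_floor=config.variance_floor,
            alpha=config.alpha,
            priors=config.priors,
            roc_score_source=config.roc_score_source,
            grid_resolution=config.grid_resolution,
        )
        analysis["auc_group_mean"] = {g: float(v.mean()) for g, v in by_group.items()}
        analysis["auc_group_sd"] = {g: float(v.std(ddof=1)) for g, v in by_group.items()}
        analysis["anova_tukey"] = comparison
        analysis["spearman"] = spearman
        results[exc] = analysis
        logger.info("excitation %.0f nm analyzed in %.1f s", exc, time.time() - t_exc)

    # ---- write artifacts --------------------------------------------------
    if config.write_spectra:
        raw_path = out / "spectra_raw.csv"
        raw.to_csv(raw_path)
        written.append(raw_path)
    lipid_path = out / "lipid_content.csv"
    lipid.to_csv(lipid_path, index=False, float_format="%.6g")
    written.append(lipid_path)
    auc_path = out / "spectral_auc.csv"
    auc.to_csv(auc_path, index=False, float_format="%.10g")
    written.append(auc_path)

    report = {}
    for exc, r in results.items():
        report[f"{exc:g}"] = {
            "n_observations": r["n_observations"],
            "pca_explained_pct": round(r["pca_explained_pct"], 2),
            "box_m": {
                "statistic": r["box_m"].statistic,
                "df": r["box_m"].df,
                "p_value": r["box_m"].p_value,
                "recommendation": r["box_m"].recommendation,
            },
            "auc_group_mean": r["auc_group_mean"],
            "auc_group_sd": r["auc_group_sd"],
            "anova": {
                "F": r["anova_tukey"].f_statistic,
                "p_value": r["anova_tukey"].p_value,
                "pairs": r["anova_tukey"].pairs,
            },
            "spearman": {
                "rho": r["spearman"].rho,
                "p_value": r["spearman"].p_value,
                "n": r["spearman"].n,
            },
            "rates": r["rates"],
            "roc": [
                {k: (None if v is None else round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
                for row in r["roc"].to_rows()
            ],
        }
    report_path = out / "analysis_report.json"
    _write_json(report, report_path)
    written.append(report_path)

    for exc, r in results.items():
        plane = r["canonical_plane"]
        raster = pd.DataFrame(
            plane.raster, index=np.round(plane.grid_y, 6), columns=np.round(plane.grid_x, 6)
        )
        raster_path = out / f"canonical_plane_{exc:g}nm.csv"
        raster.to_csv(raster_path)
        written.append(raster_path)

    tables = render_tables(results)
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)

    config_path = out / "config.yaml"
    config.save(config_path)
    written.append(config_path)

    manifest = {
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": {p.name: _sha256(p) for p in sorted(written)},
    }
    _write_json(manifest, out / "manifest.json")
    logger.info("run complete in %.1f s; %d artifacts", time.time() - t0, len(written))

    auc_named = auc  # tidy per-spectrum AUC
    return RunArtifacts(
        config=config,
        results=results,
        lipid_table=lipid,
        auc_table=auc_named,
        manifest=manifest,
        output_dir=out,
    )


# ---------------------------------------------------------------------------
# Report rendering


def render_tables(results: dict) -> dict[str, pd.DataFrame]:
    """Lay analysis results out in the standard report formats.

    Returns frames keyed ``confusion_pairs`` (paired "classification,
    cross-validation" cells), ``error_rates`` (both total definitions),
    ``roc_summary`` and ``spectra_counts``.  An empty ``results`` yields
    header-only frames.
    """
    confusion_rows, rate_rows, roc_rows, count_rows = [], [], [], []
    for exc in sorted(results):
        r = results[exc]
        groups = r["groups"]
        cls = r["confusion"]["classification"]
        cv = r["confusion"]["cross-validation"]
        rates_cls = r["rates"]["classification"]
        rates_cv = r["rates"]["cross-validation"]
        for i, g in enumerate(groups):
            row = {
                "excitation_nm": f"{exc:g}",
                "actual_group": f"{g} ({int(cls.row_totals()[i])})",
            }
            for j, h in enumerate(groups):
                row[f"predicted_{h}"] = f"{cls.counts[i, j]}, {cv.counts[i, j]}"
            row["percent_success"] = (
                f"{rates_cls['per_group'][g]['success_pct']:.1f}, "
                f"{rates_cv['per_group'][g]['success_pct']:.1f}"
            )
            confusion_rows.append(row)
        rate_row = {"excitation_nm": f"{exc:g}"}
        for g in groups:
            rate_row[f"{g}_error_pct"] = (
                f"{rates_cls['per_group'][g]['error_pct']:.1f}, "
                f"{rates_cv['per_group'][g]['error_pct']:.1f}"
            )
        rate_row["total_error_pct_pooled"] = (
            f"{rates_cls['total_error_pct_pooled']:.1f}, "
            f"{rates_cv['total_error_pct_pooled']:.1f}"
        )
        rate_row["total_error_pct_unweighted"] = (
            f"{rates_cls['total_error_pct_unweighted']:.1f}, "
            f"{rates_cv['total_error_pct_unweighted']:.1f}"
        )
        rate_rows.append(rate_row)
        for row in r["roc"].to_rows():
            roc_rows.append(
                {
                    "excitation_nm": f"{exc:g}",
                    "class": row["class"],
                    "auc": round(row["auc"], 3),
                    "optimal_sensitivity": round(row["optimal_sensitivity"], 3),
                    "one_minus_optimal_specificity": round(row["one_minus_optimal_specificity"], 3),
                    "optimal_cutoff": None
                    if row["optimal_cutoff"] is None
                    else round(row["optimal_cutoff"], 3),
                }
            )
        cm = r["confusion"]["classification"]
        for i, g in enumerate(groups):
            count_rows.append(
                {"group": g, "excitation_nm": f"{exc:g}", "n_spectra": int(cm.row_totals()[i])}
            )

    groups_seen = list(dict.fromkeys(row["group"] for row in count_rows))
    if count_rows:
        counts = pd.DataFrame(count_rows).pivot(index="group", columns="excitation_nm", values="n_spectra")
        counts = counts.reindex(groups_seen)
        counts["Total"] = counts.sum(axis=1)
        counts.loc["Total"] = counts.sum(axis=0)
        counts = counts.reset_index().rename(columns={"index": "group"})
    else:
        counts = pd.DataFrame(columns=["group", "Total"])

    confusion_cols = ["excitation_nm", "actual_group"]
    if confusion_rows:
        confusion_cols = list(confusion_rows[0])
    rate_cols = ["excitation_nm", "total_error_pct_pooled", "total_error_pct_unweighted"]
    if rate_rows:
        rate_cols = list(rate_rows[0])
    roc_cols = [
        "excitation_nm",
        "class",
        "auc",
        "optimal_sensitivity",
        "one_minus_optimal_specificity",
        "optimal_cutoff",
    ]
    return {
        "confusion_pairs": pd.DataFrame(confusion_rows, columns=confusion_cols),
        "error_rates": pd.DataFrame(rate_rows, columns=rate_cols),
        "roc_summary": pd.DataFrame(roc_rows, columns=roc_cols),
        "spectra_counts": counts,
    }
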