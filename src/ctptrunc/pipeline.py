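"""End-to-end orchestration: simulate -> sweep -> label -> features ->
train/evaluate -> report.

Every stage draws its randomness from sub-seeds of the single
configured seed, so re-running a configuration reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as cio
from .classifiers import (ClassifierSpec, bootstrap_importance, error_by_osd_gap,
                          evaluate_baseline_grid, grouped_cross_validate)
from .deconv import DEFAULT_LAMBDA_REL, compute_maps
from .features import AugmentationParams, extract_features_from_series
from .labeling import (ScanAnalysis, analyze_scan, build_dataset, cohort_osd_stats,
                       MIN_HYPO_ML, RELIABLE_ABS_ML, RELIABLE_REL_PCT, STABILITY_TOL_ML)
from .lesion import (RCBF_THRESHOLD, TMAX_THRESHOLD_S, compute_rcbf, segment_lesions)
from .synthetic import CTPSeries, SimConfig, simulate_cohort

log = logging.getLogger("ctptrunc")

__all__ = ["RunConfig", "make_analyzer", "analyze_cohort", "run_pipeline"]

DEFAULT_CLASSIFIERS = ("baseline_duration", "single_feature:aif_coverage",
                       "gradient_boosting")


@dataclass
class RunConfig:
    """Full pipeline configuration (thresholds in ml / s / dimensionless)."""

    sim: SimConfig = field(default_factory=SimConfig)
    lambda_rel: float = DEFAULT_LAMBDA_REL
    tmax_threshold_s: float = TMAX_THRESHOLD_S
    rcbf_threshold: float = RCBF_THRESHOLD
    stability_tol_ml: float = STABILITY_TOL_ML
    reliable_abs_ml: float = RELIABLE_ABS_ML
    reliable_rel_pct: float = RELIABLE_REL_PCT
    min_hypo_ml: float = MIN_HYPO_ML
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    cv_folds: int = 5
    search_budget: int = 16
    n_boot_importance: int = 0  # 0 disables the bootstrap stage
    seed: int = 17
    make_figures: bool = False

    def validate(self) -> None:
        self.sim.validate()
        self.augmentation.validate()
        for name in ("lambda_rel", "tmax_threshold_s", "rcbf_threshold",
                     "stability_tol_ml", "reliable_abs_ml", "reliable_rel_pct",
                     "min_hypo_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "augmentation" in d:
            aug = dict(d["augmentation"])
            for key in ("shift_range", "scale_range"):
                if key in aug:
                    aug[key] = tuple(aug[key])
            d["augmentation"] = AugmentationParams(**aug)
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def parse_spec(text: str, search_budget: int) -> ClassifierSpec:
    """'family' or 'single_feature:<name>' -> ClassifierSpec."""
    if ":" in text:
        family, feature = text.split(":", 1)
        return ClassifierSpec(family=family, feature=feature, search_budget=search_budget)
    return ClassifierSpec(family=text, search_budget=search_budget)


def make_analyzer(config: RunConfig):
    """Per-series volume pipeline: deconvolve at the ground-truth AIF
    site, normalize CBF against control tissue, segment, measure."""

    def analyze(series: CTPSeries):
        aif = series.vascular_curve(series.truth.aif_site, "AIF")
        maps = compute_maps(series, aif, lambda_rel=config.lambda_rel)
        compute_rcbf(maps, tmax_threshold_s=config.tmax_threshold_s)
        return segment_lesions(maps, tmax_threshold_s=config.tmax_threshold_s,
                               rcbf_threshold=config.rcbf_threshold)

    return analyze


def analyze_cohort(series_list: list[CTPSeries], config: RunConfig) -> list[ScanAnalysis]:
    analyzer = make_analyzer(config)
    out = []
    for s in series_list:
        t0 = time.time()
        a = analyze_scan(s, analyzer, feature_extractor=extract_features_from_series,
                         stability_tol_ml=config.stability_tol_ml,
                         abs_ml=config.reliable_abs_ml, rel_pct=config.reliable_rel_pct,
                         min_hypo_ml=config.min_hypo_ml)
        log.info("sweep %s: %d durations, %s, %.1fs", s.scan_id,
                 len(a.sweep.durations),
                 a.labels.exclusion_reason or "retained", time.time() - t0)
        out.append(a)
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the whole study on a synthetic cohort and write the artifacts.

    Writes ``dataset.csv`` (one row per retained truncated version with
    the nine features), ``labels.json``, ``report.json`` and optional
    figures into ``outdir``; returns the report dict.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_digest": config.digest(), "seed": config.seed}

    series_list, manifest = simulate_cohort(config.sim)
    cio.write_manifest(manifest, outdir / "manifest.csv")

    analyses = analyze_cohort(series_list, config)
    records, exclusion_report = build_dataset(analyses)
    dataset = pd.DataFrame(records)
    retained = dataset[dataset["label"].notna()] if len(dataset) else dataset
    dataset.to_csv(outdir / "dataset.csv", index=False)

    labels_obj = {
        a.scan_id: {
            "stability": a.labels.stability,
            "excluded": a.labels.excluded,
            "exclusion_reason": a.labels.exclusion_reason,
            "osd_s": a.labels.osd_s,
            "full_duration_s": a.labels.full_duration_s,
            "labels": {str(d): lab for d, lab in sorted(a.labels.labels.items())},
        }
        for a in analyses
    }
    cio.write_json({"scans": labels_obj, **stamp}, outdir / "labels.json")

    n_scans = len(analyses)
    n_records = len(retained)
    n_unreliable = int((retained["label"] == "unreliable").sum()) if n_records else 0
    report: dict = {**stamp, "n_scans": n_scans,
                    "exclusions": exclusion_report,
                    "retained_pct": 100.0 * exclusion_report["retained"] / n_scans,
                    "n_truncated_records": n_records,
                    "unreliable_pct": 100.0 * n_unreliable / n_records if n_records else 0.0}
    log.info("cohort: %d scans, %d retained, %d records (%.1f%% unreliable)",
             n_scans, exclusion_report["retained"], n_records,
             report["unreliable_pct"])

    aif_peaks = {a.scan_id: a.features[a.sweep.full_duration_s].argmax_aif
                 for a in analyses if a.features}
    if exclusion_report["retained"]:
        report["osd_stats"] = cohort_osd_stats(analyses, aif_peaks)

    if n_records and config.classifiers:
        k = min(config.cv_folds, retained["scan_id"].nunique())
        if k < config.cv_folds:
            log.warning("cv folds clamped from %d to %d", config.cv_folds, k)
        specs = [parse_spec(t, config.search_budget) for t in config.classifiers]
        cv = grouped_cross_validate(retained, specs, k=k,
                                    aug_params=config.augmentation,
                                    seed=config.seed,
                                    search_budget=config.search_budget)
        report["classifiers"] = {}
        for name, res in cv.items():
            entry = {"pooled": res.pooled, "folds": res.fold_metrics}
            entry["osd_gap"] = error_by_osd_gap(res.predictions)
            report["classifiers"][name] = entry
        report["baseline_theta_grid"] = {
            str(th): m for th, m in evaluate_baseline_grid(retained).items()}
        if config.n_boot_importance >= 2:
            imp = bootstrap_importance(retained, n_boot=config.n_boot_importance,
                                       seed=config.seed)
            report["feature_importance"] = {"mean": imp.mean, "sd": imp.sd,
                                            "n_boot": imp.n_boot}
        if config.make_figures:
            _write_figures(report, outdir)

    cio.write_json(report, outdir / "report.json")
    return report


def _write_figures(report: dict, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.get("classifiers", {}))
    if not names:
        return
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3), squeeze=False)
    for ax, name in zip(axes[0], names):
        g = report["classifiers"][name]["osd_gap"]
        edges = np.asarray(g["bin_edges_s"])
        centers = (edges[:-1] + edges[1:]) / 2
        ax.bar(centers, g["correct"], width=0.9, label="correct", alpha=0.6)
        ax.bar(centers, g["incorrect"], width=0.9, label="incorrect", alpha=0.8)
        ax.axvline(-g["window_s"], ls="--", c="k", lw=0.8)
        ax.axvline(g["window_s"], ls="--", c="k", lw=0.8)
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("scan duration - OSD (s)")
    axes[0][0].set_ylabel("samples")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "osd_gap_histograms.png", dpi=120)
    plt.close(fig)
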