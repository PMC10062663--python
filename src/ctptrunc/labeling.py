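"""Truncation sweep and reliability labeling.

Shorter acquisitions are simulated by repeatedly discarding the last
timepoint down to the first 10 seconds.  Each truncated version is
re-analyzed independently (deconvolution, control-tissue normalization
and volumetry are all recomputed), producing per-duration lesion
volumes from which the reliability labels are derived:

* a scan is *stable* when truncating its final 6 frames or less never
  changes either lesion volume by more than 2.5 ml (strict);
  unstable scans are excluded;
* a truncated version is *reliable* when, for both lesion types, the
  volume deviates from the untruncated estimate by < 5 ml or < 10%;
  once a duration is unreliable, all shorter versions are unreliable
  (downward propagation);
* stable scans whose hypoperfused volume is below 5 ml (or zero) are
  excluded;
* the optimal scan duration (OSD) is the shortest reliable duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .lesion import LesionVolumes
from .synthetic import CTPSeries

__all__ = [
    "TruncationSweep",
    "ScanLabelSet",
    "truncate_series",
    "run_sweep",
    "label_stability",
    "label_reliability",
    "build_dataset",
    "cohort_osd_stats",
    "STABILITY_TOL_ML",
    "RELIABLE_ABS_ML",
    "RELIABLE_REL_PCT",
    "MIN_HYPO_ML",
    "MIN_DURATION_FRAMES",
    "STABILITY_FRAMES",
]

STABILITY_TOL_ML = 2.5
RELIABLE_ABS_ML = 5.0
RELIABLE_REL_PCT = 10.0
MIN_HYPO_ML = 5.0
MIN_DURATION_FRAMES = 10
STABILITY_FRAMES = 6


@dataclass
class TruncationSweep:
    """Lesion volumes of one scan across all truncated durations."""

    scan_id: str
    dt: float
    full_duration_s: float
    volumes: dict[float, LesionVolumes]  # duration_s -> volumes
    failed: set[float] = field(default_factory=set)

    @property
    def durations(self) -> list[float]:
        return sorted(self.volumes)


@dataclass
class ScanLabelSet:
    scan_id: str
    stability: str  # "stable" | "unstable"
    labels: dict[float, str]  # duration_s -> "reliable" | "unreliable"
    osd_s: Optional[float]
    full_duration_s: float
    excluded: bool = False
    exclusion_reason: Optional[str] = None  # unstable | small_lesion | no_lesion | sweep_failed


def truncate_series(series: CTPSeries, duration_s: float) -> CTPSeries:
    """First duration_s/dt timepoints of a scan; spatial truth unchanged."""
    dt = series.dt
    n_keep = duration_s / dt
    if abs(n_keep - round(n_keep)) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    n_keep = int(round(n_keep))
    n = series.n_timepoints
    if n_keep < MIN_DURATION_FRAMES or n_keep > n:
        raise ValueError(f"duration {duration_s} outside [{MIN_DURATION_FRAMES * dt}, {n * dt}]")
    if n_keep == n:
        return series
    return CTPSeries(values=series.values[..., :n_keep], dt=dt,
                     voxel_volume_ml=series.voxel_volume_ml,
                     brain_mask=series.brain_mask, truth=series.truth,
                     scan_id=series.scan_id)


def run_sweep(series: CTPSeries,
              analyzer: Callable[[CTPSeries], LesionVolumes]) -> TruncationSweep:
    """Analyze every truncated version of a scan independently.

    ``analyzer`` maps a series to lesion volumes (deconvolution plus
    volumetry with fixed vascular sites and regularization).  Failures
    at individual durations are recorded; a failure within the final
    6 frames makes stability unassessable and is flagged by the caller.
    """
    dt = series.dt
    n = series.n_timepoints
    volumes: dict[float, LesionVolumes] = {}
    failed: set[float] = set()
    for frames in range(MIN_DURATION_FRAMES, n + 1):
        d = frames * dt
        try:
            volumes[d] = analyzer(truncate_series(series, d))
        except Exception:
            failed.add(d)
    return TruncationSweep(scan_id=series.scan_id, dt=dt,
                           full_duration_s=n * dt, volumes=volumes, failed=failed)


def _deviations(sweep: TruncationSweep, d: float) -> tuple[float, float]:
    ref = sweep.volumes[sweep.full_duration_s]
    v = sweep.volumes[d]
    return abs(v.hypo_ml - ref.hypo_ml), abs(v.core_ml - ref.core_ml)


def label_stability(sweep: TruncationSweep, tol_ml: float = STABILITY_TOL_ML,
                    frames: int = STABILITY_FRAMES) -> str:
    """Stable iff dropping each of the last ``frames`` frames moves both
    lesion volumes by at most ``tol_ml`` (a deviation of exactly tol_ml
    is still stable)."""
    T = sweep.full_duration_s
    dt = sweep.dt
    needed = [T - k * dt for k in range(1, frames + 1)]
    if (T / dt) - frames < MIN_DURATION_FRAMES:
        raise ValueError("sweep too short to assess stability")
    for d in needed + [T]:
        if d not in sweep.volumes:
            raise ValueError(f"missing volumes at duration {d}")
    for d in needed:
        dh, dc = _deviations(sweep, d)
        if dh > tol_ml or dc > tol_ml:
            return "unstable"
    return "stable"


def label_reliability(sweep: TruncationSweep, stability: str,
                      abs_ml: float = RELIABLE_ABS_ML,
                      rel_pct: float = RELIABLE_REL_PCT,
                      min_hypo_ml: float = MIN_HYPO_ML) -> ScanLabelSet:
    """Per-duration reliable/unreliable labels with downward propagation."""
    if stability != "stable":
        raise ValueError("reliability labels are only defined for stable scans")
    T = sweep.full_duration_s
    ref = sweep.volumes[T]

    def acceptable(delta: float, ref_ml: float) -> bool:
        if delta < abs_ml:
            return True
        return ref_ml > 0 and 100.0 * delta / ref_ml < rel_pct

    raw: dict[float, bool] = {}
    for d in sweep.durations:
        dh, dc = _deviations(sweep, d)
        raw[d] = acceptable(dh, ref.hypo_ml) and acceptable(dc, ref.core_ml)

    # downward propagation: everything at or below the longest raw-unreliable
    # duration is unreliable
    unrel = [d for d, ok in raw.items() if not ok] + list(sweep.failed)
    cutoff = max(unrel) if unrel else -np.inf
    labels = {d: ("unreliable" if d <= cutoff else "reliable") for d in sweep.durations}
    reliable_ds = [d for d, lab in labels.items() if lab == "reliable"]
    osd = min(reliable_ds) if reliable_ds else None

    excluded, reason = False, None
    if ref.hypo_ml == 0:
        excluded, reason = True, "no_lesion"
    elif ref.hypo_ml < min_hypo_ml:
        excluded, reason = True, "small_lesion"
    return ScanLabelSet(scan_id=sweep.scan_id, stability="stable", labels=labels,
                        osd_s=osd, full_duration_s=T, excluded=excluded,
                        exclusion_reason=reason)


@dataclass
class ScanAnalysis:
    """One scan's sweep, labels and per-duration feature vectors."""

    scan_id: str
    sweep: TruncationSweep
    labels: Optional[ScanLabelSet]
    features: dict[float, "object"] = field(default_factory=dict)  # duration -> FeatureVector


def analyze_scan(series: CTPSeries, analyzer,
                 feature_extractor=None,
                 stability_tol_ml: float = STABILITY_TOL_ML,
                 abs_ml: float = RELIABLE_ABS_ML, rel_pct: float = RELIABLE_REL_PCT,
                 min_hypo_ml: float = MIN_HYPO_ML) -> ScanAnalysis:
    """Sweep + stability + reliability labels for one scan.

    ``feature_extractor(truncated_series) -> FeatureVector`` is invoked
    per retained duration when given.
    """
    sweep = run_sweep(series, analyzer)
    T = sweep.full_duration_s
    critical = [T - k * sweep.dt for k in range(0, STABILITY_FRAMES + 1)]
    if any(d in sweep.failed for d in critical):
        labels = ScanLabelSet(scan_id=series.scan_id, stability="unstable", labels={},
                              osd_s=None, full_duration_s=T, excluded=True,
                              exclusion_reason="sweep_failed")
        return ScanAnalysis(series.scan_id, sweep, labels)
    stability = label_stability(sweep, tol_ml=stability_tol_ml)
    if stability == "unstable":
        labels = ScanLabelSet(scan_id=series.scan_id, stability="unstable", labels={},
                              osd_s=None, full_duration_s=T, excluded=True,
                              exclusion_reason="unstable")
        return ScanAnalysis(series.scan_id, sweep, labels)
    labels = label_reliability(sweep, stability, abs_ml=abs_ml, rel_pct=rel_pct,
                               min_hypo_ml=min_hypo_ml)
    analysis = ScanAnalysis(series.scan_id, sweep, labels)
    if feature_extractor is not None and not labels.excluded:
        for d in sweep.durations:
            analysis.features[d] = feature_extractor(truncate_series(series, d))
    return analysis


def build_dataset(analyses: list[ScanAnalysis]):
    """Assemble the truncation-record table and the exclusion report.

    Returns ``(records, report)`` where ``records`` is a list of dict
    rows (scan_id, duration_s, label, osd_s, nine features) over all
    retained truncated versions, and ``report`` counts scans by
    exclusion reason.
    """
    from .features import FEATURE_NAMES  # local import to avoid a cycle

    records: list[dict] = []
    report = {"retained": 0, "unstable": 0, "small_lesion": 0,
              "no_lesion": 0, "sweep_failed": 0}
    for a in analyses:
        ls = a.labels
        if ls is None or ls.excluded:
            reason = ls.exclusion_reason if ls is not None else "sweep_failed"
            report[reason] = report.get(reason, 0) + 1
            continue
        report["retained"] += 1
        for d in a.sweep.durations:
            row = {"scan_id": a.scan_id, "duration_s": d,
                   "label": ls.labels[d], "osd_s": ls.osd_s}
            fv = a.features.get(d)
            if fv is not None:
                for name in FEATURE_NAMES:
                    row[name] = getattr(fv, name)
            records.append(row)
    return records, report


def cohort_osd_stats(analyses: list[ScanAnalysis],
                     aif_peak_s: dict[str, float]) -> dict[str, dict[str, float]]:
    """Descriptive statistics (mean, std, min, max, P5, P95) in seconds
    for scan duration, OSD and OSD minus the AIF peak time, over the
    retained stable scans."""
    rows = [(a.labels.full_duration_s, a.labels.osd_s,
             a.labels.osd_s - aif_peak_s[a.scan_id])
            for a in analyses
            if a.labels is not None and not a.labels.excluded and a.labels.osd_s is not None]
    if not rows:
        raise ValueError("no retained stable scans")
    arr = np.asarray(rows, dtype=float)
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(("scan_duration", "osd", "osd_minus_aif_peak")):
        col = arr[:, j]
        out[name] = {
            "mean": float(col.mean()),
            "std": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            "min": float(col.min()),
            "max": float(col.max()),
            "p5": float(np.percentile(col, 5)),
            "p95": float(np.percentile(col, 95)),
        }
    return out
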