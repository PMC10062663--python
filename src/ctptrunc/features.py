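"""The nine AIF/VOF features and perfusion-specific augmentation.

For each vascular curve (raw HU, no baseline subtraction) the peak time
and three derived quantities are measured:

* ``argmax`` — time to the curve's peak;
* ``coverage`` — scan duration minus the peak time, i.e. the
  acquisition time available after the peak (0 when the scan ends
  at or before the peak: the severe-truncation signature);
* ``UCI`` / ``DCI`` — upward/downward contrast increase: peak value
  minus the first / last sample.

Time convention: sample ``i`` sits at ``(i + 1) * dt`` so the last
sample of an N-sample 1 Hz scan lies exactly at the scan duration N s.

Augmentation emulates contrast-injection protocol variability: one
uniform time shift applied jointly to scan duration and both peak
times (coverages are unchanged by construction), and one uniform gain
applied to the four UCI/DCI amplitudes.  Neither transform alters
whether the acquisition was truncated, so augmented copies inherit the
source label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import CTPSeries, VascularFunction

__all__ = ["FeatureVector", "AugmentationParams", "FEATURE_NAMES",
           "extract_features", "extract_features_from_series", "augment_features"]

FEATURE_NAMES = (
    "scan_duration",
    "argmax_aif",
    "argmax_vof",
    "aif_coverage",
    "vof_coverage",
    "aif_uci",
    "aif_dci",
    "vof_uci",
    "vof_dci",
)


@dataclass
class FeatureVector:
    scan_duration: float  # s
    argmax_aif: float  # s
    argmax_vof: float  # s
    aif_coverage: float  # s
    vof_coverage: float  # s
    aif_uci: float  # HU
    aif_dci: float  # HU
    vof_uci: float  # HU
    vof_dci: float  # HU

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("non-finite feature")
        for curve in ("aif", "vof"):
            cov = getattr(self, f"{curve}_coverage")
            expect = self.scan_duration - getattr(self, f"argmax_{curve}")
            if abs(cov - expect) > 1e-9:
                raise ValueError(f"{curve} coverage identity violated")


@dataclass
class AugmentationParams:
    """Uniform ranges for the time shift and the amplitude gain."""

    shift_range: tuple[float, float] = (-5.0, 10.0)  # s
    scale_range: tuple[float, float] = (0.7, 1.3)
    n_augment_per_sample: int = 2
    max_retries: int = 100

    def validate(self) -> None:
        if self.scale_range[0] <= 0:
            raise ValueError("scale lower bound must be positive")
        if self.shift_range[1] < self.shift_range[0] or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("range bounds out of order")
        if self.n_augment_per_sample < 0:
            raise ValueError("n_augment_per_sample must be >= 0")


def _curve_features(curve: VascularFunction, duration_s: float):
    s = curve.samples
    peak_idx = int(np.argmax(s))  # first occurrence on ties
    argmax_t = (peak_idx + 1) * curve.dt
    return argmax_t, duration_s - argmax_t, float(s[peak_idx] - s[0]), float(s[peak_idx] - s[-1])


def extract_features(aif: VascularFunction, vof: VascularFunction) -> FeatureVector:
    """Measure the nine features from raw-HU AIF and VOF curves."""
    if len(aif.samples) != len(vof.samples):
        raise ValueError("AIF and VOF must have equal length")
    n = len(aif.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if aif.dt != vof.dt:
        raise ValueError("AIF and VOF must share the sampling interval")
    duration = n * aif.dt
    a_argmax, a_cov, a_uci, a_dci = _curve_features(aif, duration)
    v_argmax, v_cov, v_uci, v_dci = _curve_features(vof, duration)
    fv = FeatureVector(scan_duration=duration, argmax_aif=a_argmax, argmax_vof=v_argmax,
                       aif_coverage=a_cov, vof_coverage=v_cov,
                       aif_uci=a_uci, aif_dci=a_dci, vof_uci=v_uci, vof_dci=v_dci)
    fv.validate()
    return fv


def extract_features_from_series(series: CTPSeries) -> FeatureVector:
    """Features from the ground-truth vascular sites of a simulated scan."""
    if series.truth is None:
        raise ValueError("series carries no vascular ground truth")
    aif = series.vascular_curve(series.truth.aif_site, "AIF")
    vof = series.vascular_curve(series.truth.vof_site, "VOF")
    return extract_features(aif, vof)


def augment_features(fv: FeatureVector, params: AugmentationParams,
                     rng: np.random.Generator,
                     min_duration_s: float = 10.0) -> list[FeatureVector]:
    """Generate augmented feature vectors; copies inherit the source label."""
    params.validate()
    out: list[FeatureVector] = []
    for _ in range(params.n_augment_per_sample):
        for attempt in range(params.max_retries + 1):
            delta = rng.uniform(*params.shift_range)
            scale = rng.uniform(*params.scale_range)
            new_dur = fv.scan_duration + delta
            new_aif = fv.argmax_aif + delta
            new_vof = fv.argmax_vof + delta
            if new_dur >= min_duration_s and new_aif > 0 and new_vof > 0:
                break
        else:
            raise RuntimeError("could not draw a valid augmentation shift")
        aug = FeatureVector(
            scan_duration=new_dur, argmax_aif=new_aif, argmax_vof=new_vof,
            aif_coverage=new_dur - new_aif, vof_coverage=new_dur - new_vof,
            aif_uci=fv.aif_uci * scale, aif_dci=fv.aif_dci * scale,
            vof_uci=fv.vof_uci * scale, vof_dci=fv.vof_dci * scale)
        aug.validate()
        out.append(aug)
    return out
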