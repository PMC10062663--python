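"""Delay-invariant block-circulant truncated-SVD deconvolution.

The tissue curve is modeled as C(t) = dt * (AIF (*) k), with
k(t) = CBF * R(t) the flow-scaled residue function.  Building the AIF
convolution matrix as a zero-padded circulant makes the estimate
insensitive to bolus arrival delay between AIF and tissue: a pure time
shift of the tissue curve shifts argmax(k) without changing max(k).
Regularization is a fixed relative singular-value threshold.

Perfusion maps follow the standard definitions: CBF = max(k),
Tmax = dt * argmax(k), CBV = integral(C_tissue)/integral(C_AIF),
MTT = CBV/CBF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import circulant

from .synthetic import CTPSeries, VascularFunction

__all__ = [
    "ConcentrationCurve",
    "ResidueFunction",
    "PerfusionMaps",
    "to_concentration",
    "build_circulant",
    "svd_deconvolve",
    "Deconvolver",
    "compute_maps",
]

DEFAULT_LAMBDA_REL = 0.15
DEFAULT_PAD_FACTOR = 2


@dataclass
class ConcentrationCurve:
    """Baseline-subtracted contrast concentration curve (HU above baseline)."""

    samples: np.ndarray
    dt: float
    baseline_hu: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class ResidueFunction:
    """Flow-scaled residue estimate k(t) = CBF * R(t), sampled at dt."""

    k: np.ndarray
    dt: float

    @property
    def cbf(self) -> float:
        return float(max(self.k.max(), 0.0))

    @property
    def tmax_s(self) -> float:
        # first index attaining the maximum (tie-break)
        return float(int(np.argmax(self.k)) * self.dt)


@dataclass
class PerfusionMaps:
    """Voxelwise perfusion maps on the scan's spatial grid."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray  # NaN where CBF = 0
    tmax: np.ndarray  # seconds
    brain_mask: np.ndarray
    dt: float
    voxel_volume_ml: float
    rcbf: Optional[np.ndarray] = None


def detect_bolus_arrival(samples: np.ndarray) -> Optional[int]:
    """First index whose value exceeds the expanding pre-window mean + 3 sd.

    Returns None when no arrival is detected (flat curve, or a curve
    already rising at acquisition start — the no-pre-contrast case).
    """
    samples = np.asarray(samples, dtype=float)
    for i in range(3, len(samples)):
        w = samples[:i]
        m = w.mean()
        s = max(w.std(), 1e-9 * max(1.0, abs(m)))
        if samples[i] > m + 3.0 * s:
            return i
    return None


def to_concentration(curve, dt: Optional[float] = None) -> ConcentrationCurve:
    """Convert a raw HU curve to concentration by baseline subtraction.

    Baseline is the mean of samples before the detected bolus arrival;
    when no arrival is detected the first sample is used (covers both a
    constant curve and a scan with no pre-contrast acquisition).  Noise
    may leave slightly negative concentrations; they are not clipped.
    """
    if isinstance(curve, VascularFunction):
        if dt is None:
            dt = curve.dt
        curve = curve.samples
    if dt is None:
        raise ValueError("dt required for bare arrays")
    samples = np.asarray(curve, dtype=float)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    arrival = detect_bolus_arrival(samples)
    baseline = float(samples[:arrival].mean()) if arrival is not None else float(samples[0])
    return ConcentrationCurve(samples=samples - baseline, dt=dt, baseline_hu=baseline)


def build_circulant(aif: ConcentrationCurve, pad_factor: int = DEFAULT_PAD_FACTOR) -> np.ndarray:
    """Zero-padded circulant AIF matrix D[i, j] = dt * aif[(i - j) mod L]."""
    if pad_factor < 2:
        raise ValueError("pad_factor must be >= 2 to avoid wrap-around")
    n = len(aif.samples)
    if n < 3:
        raise ValueError("AIF too short")
    L = pad_factor * n
    padded = np.zeros(L)
    padded[:n] = aif.samples
    return aif.dt * circulant(padded)


class Deconvolver:
    """Precomputed truncated-SVD pseudo-inverse for one AIF.

    Amortizes the SVD so that all voxels of a scan (and all its
    truncated versions' re-analyses) reuse a single factorization.
    """

    def __init__(self, aif: ConcentrationCurve, lambda_rel: float = DEFAULT_LAMBDA_REL,
                 pad_factor: int = DEFAULT_PAD_FACTOR):
        if not (0.0 < lambda_rel < 1.0):
            raise ValueError("lambda_rel must lie in (0, 1)")
        if not np.any(aif.samples):
            raise ValueError("all-zero AIF cannot be deconvolved")
        self.n = len(aif.samples)
        self.dt = aif.dt
        D = build_circulant(aif, pad_factor)
        U, s, Vt = np.linalg.svd(D)
        s_inv = np.where(s >= lambda_rel * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
        # rows beyond n are wrap-around territory; only the first n are reported
        self.pinv = (Vt.T * s_inv) @ U.T

    def apply(self, tissue: np.ndarray) -> np.ndarray:
        """Deconvolve tissue concentration curve(s), shape (n,) or (n, n_voxels)."""
        tissue = np.asarray(tissue, dtype=float)
        L = self.pinv.shape[1]
        if tissue.shape[0] != self.n:
            raise ValueError("tissue length must match the AIF length")
        k = self.pinv[:self.n, :self.n] @ tissue  # padded tail of c is zero
        return k


def svd_deconvolve(tissue: ConcentrationCurve, aif: ConcentrationCurve,
                   lambda_rel: float = DEFAULT_LAMBDA_REL,
                   pad_factor: int = DEFAULT_PAD_FACTOR) -> ResidueFunction:
    """Estimate the flow-scaled residue function of one tissue curve."""
    if len(tissue.samples) != len(aif.samples):
        raise ValueError("tissue and AIF must have equal length")
    dec = Deconvolver(aif, lambda_rel=lambda_rel, pad_factor=pad_factor)
    k = dec.apply(tissue.samples)
    return ResidueFunction(k=k, dt=aif.dt)


def compute_maps(series: CTPSeries, aif: VascularFunction,
                 lambda_rel: float = DEFAULT_LAMBDA_REL,
                 pad_factor: int = DEFAULT_PAD_FACTOR) -> PerfusionMaps:
    """Voxelwise perfusion maps for every brain-mask voxel.

    Tissue baselines are estimated from the pre-arrival window detected
    on the AIF (tissue contrast can only arrive at or after the arterial
    arrival); when the AIF shows no pre-contrast window each voxel falls
    back to its first sample.
    """
    if len(aif.samples) != series.n_timepoints:
        raise ValueError("AIF length must equal the series' timepoint count")
    mask = series.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    aif_conc = to_concentration(aif)
    dec = Deconvolver(aif_conc, lambda_rel=lambda_rel, pad_factor=pad_factor)

    curves = np.asarray(series.values[mask], dtype=float)  # (n_voxels, n_t)
    arrival = detect_bolus_arrival(aif.samples)
    if arrival is not None and arrival >= 1:
        baseline = curves[:, :arrival].mean(axis=1)
    else:
        baseline = curves[:, 0]
    conc = curves - baseline[:, None]
    bad = ~np.all(np.isfinite(conc), axis=1)
    conc[bad] = 0.0

    k = dec.apply(conc.T)  # (n_t, n_voxels)
    cbf_v = np.maximum(k.max(axis=0), 0.0)
    tmax_v = np.argmax(k, axis=0) * series.dt
    denom = np.trapezoid(aif_conc.samples, dx=series.dt)
    cbv_v = np.trapezoid(conc, dx=series.dt, axis=1) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_v = np.where(cbf_v > 0, cbv_v / cbf_v, np.nan)
    cbf_v[bad] = 0.0
    cbv_v[bad] = 0.0
    tmax_v[bad] = 0.0
    mtt_v[bad] = np.nan

    shape = mask.shape

    def _fill(vals: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(shape, fill, dtype=np.float32)
        out[mask] = vals
        return out

    return PerfusionMaps(cbf=_fill(cbf_v), cbv=_fill(cbv_v),
                         mtt=_fill(mtt_v, np.nan), tmax=_fill(tmax_v),
                         brain_mask=mask, dt=series.dt,
                         voxel_volume_ml=series.voxel_volume_ml)
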