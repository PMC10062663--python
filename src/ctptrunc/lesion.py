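"""Lesion segmentation and volumetry from perfusion maps.

Hypoperfusion is Tmax > 6 s (strict); the ischemic core is the subset
with rCBF < 0.38 (strict), where rCBF normalizes CBF by the mean over
control tissue (Tmax < 6 s).  Volumes are voxel counts times the voxel
volume — no morphological cleanup by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .deconv import PerfusionMaps

__all__ = ["LesionVolumes", "ControlTissueError", "compute_rcbf", "segment_lesions"]

TMAX_THRESHOLD_S = 6.0
RCBF_THRESHOLD = 0.38


class ControlTissueError(RuntimeError):
    """No control tissue (Tmax < 6 s) available: globally abnormal perfusion."""


@dataclass
class LesionVolumes:
    hypo_ml: float
    core_ml: float
    hypo_mask: np.ndarray
    core_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.core_ml > self.hypo_ml + 1e-9:
            raise ValueError("core volume cannot exceed hypoperfused volume")


def compute_rcbf(maps: PerfusionMaps, brain_mask: np.ndarray | None = None,
                 tmax_threshold_s: float = TMAX_THRESHOLD_S) -> np.ndarray:
    """Relative CBF: CBF / mean CBF over control tissue (Tmax < threshold).

    Raises :class:`ControlTissueError` when no control voxel exists, in
    which case the scan must be excluded rather than normalized.
    """
    mask = maps.brain_mask if brain_mask is None else brain_mask
    control = mask & (maps.tmax < tmax_threshold_s)
    if not control.any():
        raise ControlTissueError("no control tissue with Tmax below threshold")
    mean_cbf = float(maps.cbf[control].mean())
    if mean_cbf <= 0:
        raise ControlTissueError("control tissue has zero mean CBF")
    rcbf = np.where(mask, maps.cbf / mean_cbf, 0.0).astype(np.float32)
    maps.rcbf = rcbf
    return rcbf


def segment_lesions(maps: PerfusionMaps, brain_mask: np.ndarray | None = None,
                    voxel_volume_ml: float | None = None,
                    tmax_threshold_s: float = TMAX_THRESHOLD_S,
                    rcbf_threshold: float = RCBF_THRESHOLD,
                    min_cluster_voxels: int = 0) -> LesionVolumes:
    """Segment hypoperfused and core lesions and report their volumes."""
    mask = maps.brain_mask if brain_mask is None else brain_mask
    vv = maps.voxel_volume_ml if voxel_volume_ml is None else voxel_volume_ml
    rcbf = maps.rcbf if maps.rcbf is not None else compute_rcbf(maps, mask, tmax_threshold_s)
    hypo = mask & (maps.tmax > tmax_threshold_s)
    if min_cluster_voxels > 0 and hypo.any():
        lab, n = ndimage.label(hypo)
        counts = np.bincount(lab.ravel())
        keep = counts >= min_cluster_voxels
        keep[0] = False
        hypo = keep[lab]
    core = hypo & (rcbf < rcbf_threshold)
    return LesionVolumes(hypo_ml=float(hypo.sum()) * vv,
                         core_ml=float(core.sum()) * vv,
                         hypo_mask=hypo, core_mask=core)
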