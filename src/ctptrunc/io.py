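"""Readers and writers: NIfTI-1 series/masks, CSV tables, YAML configs."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import CTPSeries, SimConfig

log = logging.getLogger("ctptrunc")

__all__ = ["write_ctp_nifti", "read_ctp_nifti", "write_mask_nifti", "read_mask_nifti",
           "write_manifest", "load_config", "save_config", "write_json"]


def write_ctp_nifti(series: CTPSeries, path) -> None:
    """4D NIfTI-1 with time as the 4th dimension; dt stored in pixdim[4]."""
    img = nib.Nifti1Image(np.asarray(series.values, dtype=np.float32), affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = series.dt
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_ctp_nifti(path, mask_path=None, voxel_volume_ml: float = 0.125) -> CTPSeries:
    """Load a 4D CTP series.

    dt comes from pixdim[4]; a missing/zero value falls back to 1 s
    (one volume per second) with a warning.  The brain mask is read from
    ``mask_path`` when given, otherwise estimated by Otsu thresholding
    of the temporal-mean volume.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxel values")
    dt = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if dt <= 0:
        log.warning("%s: missing pixdim[4]; assuming dt = 1 s", path)
        dt = 1.0
    if mask_path is not None:
        mask = read_mask_nifti(mask_path)
    else:
        mask = _otsu_mask(data.mean(axis=3))
    return CTPSeries(values=data, dt=dt, voxel_volume_ml=voxel_volume_ml,
                     brain_mask=mask, scan_id=Path(str(path)).stem.split(".")[0])


def _otsu_mask(mean_vol: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Otsu threshold on the temporal-mean volume (foreground = brain)."""
    hist, edges = np.histogram(mean_vol.ravel(), bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1
    thr = centers[int(np.argmax(sigma_b))]
    return mean_vol > thr


def write_mask_nifti(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)), str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_manifest(manifest: list[dict], path) -> None:
    pd.DataFrame(manifest).to_csv(path, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path):
    """Load a pipeline or simulator config from YAML/JSON (by extension)."""
    from .pipeline import RunConfig

    p = Path(str(path))
    with open(p) as fh:
        raw = json.load(fh) if p.suffix == ".json" else yaml.safe_load(fh)
    if "sim" in raw:
        return RunConfig.from_dict(raw)
    return SimConfig.from_dict(raw)
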