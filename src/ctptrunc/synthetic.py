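"""Synthetic CT-perfusion (CTP) cohort generation.

Builds 4D digital perfusion phantoms with known ground truth: a
gamma-variate arterial bolus, a delayed/dispersed venous outflow, and
tissue time-attenuation curves obtained by causal convolution of the
arterial input with an exponential residue function.  Hypoperfused
lesion voxels receive reduced flow plus an arrival delay, so the
downstream Tmax/rCBF segmentation has a known target.

The forward convolution is truncated at the scan end.  That tail loss
is deliberate: it is the physical mechanism that makes short
acquisitions unreliable, which is the phenomenon the rest of the
package detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CTPSeries",
    "VascularFunction",
    "gamma_variate",
    "simulate_tissue_curve",
    "simulate_ctp_scan",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Configuration of the synthetic CTP cohort.

    Defaults emulate the acquisition characteristics of public
    multi-center stroke CTP data sampled at 1 volume per second:
    scan duration ~ N(46.6, 5.3) s clipped to [31, 64] s, and an
    arterial peak time of roughly 15.6 +/- 4.5 s (minimum 5 s), which
    is obtained here as bolus arrival ~ N(11.1, 4.5) s (minimum 0.5 s)
    plus the gamma-variate rise time alpha*beta = 4.5 s.
    """

    n_scans: int = 30
    dt: float = 1.0  # s per volume
    # (mean, sd, min, max), seconds
    duration_dist: tuple[float, float, float, float] = (46.6, 5.3, 31.0, 64.0)
    # (mean, sd, min), seconds; no upper bound
    bolus_arrival_dist: tuple[float, float, float] = (11.1, 4.5, 0.5)
    # (alpha [-], beta [s], peak amplitude [HU])
    aif_shape: tuple[float, float, float] = (3.0, 1.5, 200.0)
    vof_amplitude: float = 300.0  # venous curves exceed arterial in CTP
    vof_delay: float = 6.0  # s
    vof_dispersion: float = 2.0  # s
    tissue_grid: tuple[int, int, int] = (64, 64, 4)
    voxel_volume_ml: float = 0.125
    healthy_cbf_rel: float = 0.012  # 1/s, relative flow scale
    lesion_cbf_rel: float = 0.004
    healthy_mtt: float = 4.0  # s
    lesion_mtt: float = 10.0  # s
    lesion_delay: float = 8.0  # s, pushes lesion Tmax past the 6 s rule
    lesion_dispersion: float = 3.0  # s
    lesion_fraction: float = 0.05  # fraction of brain voxels
    cbf_jitter: float = 0.15  # per-voxel uniform +/- fraction on flow
    noise_sd: float = 1.0  # HU, effective residual noise after clinical preprocessing
    baseline_hu: float = 40.0
    seed: int = 17

    def validate(self) -> None:
        mean, sd, dmin, dmax = self.duration_dist
        if dmin < 10.0 * self.dt:
            raise ValueError("minimum duration must allow a 10-frame truncation sweep")
        if dmax < dmin:
            raise ValueError("duration max < min")
        if not (self.lesion_cbf_rel < self.healthy_cbf_rel):
            raise ValueError("lesion flow must be below healthy flow")
        for name in ("dt", "healthy_mtt", "lesion_mtt", "vof_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.lesion_fraction < 1.0):
            raise ValueError("lesion_fraction must be in [0, 1)")
        alpha, beta, amp = self.aif_shape
        if min(alpha, beta, amp) <= 0:
            raise ValueError("aif_shape parameters must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("duration_dist", "bolus_arrival_dist", "aif_shape", "tissue_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-scan simulation truth used by tests and by feature extraction."""

    hypo_mask: np.ndarray  # 3D bool, hypoperfused lesion
    core_mask: np.ndarray  # 3D bool, subset of hypo_mask
    aif_site: tuple[int, int, int]
    vof_site: tuple[int, int, int]
    cbf: np.ndarray  # per-voxel relative flow (1/s)
    delay: np.ndarray  # per-voxel arrival delay (s) on top of bolus arrival
    mtt: np.ndarray  # per-voxel mean transit time (s)
    bolus_arrival_s: float = 0.0


@dataclass
class CTPSeries:
    """A 4D CTP acquisition: HU values on (x, y, z, t)."""

    values: np.ndarray
    dt: float
    voxel_volume_ml: float
    brain_mask: np.ndarray
    truth: Optional[GroundTruth] = None
    scan_id: str = "scan"

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def duration_s(self) -> float:
        # N samples at interval dt cover N*dt seconds of acquisition
        return self.n_timepoints * self.dt

    def validate(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be 4D (x, y, z, t)")
        if self.n_timepoints < 10:
            raise ValueError("series must have at least 10 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite voxel values")
        if self.brain_mask.shape != self.values.shape[:3]:
            raise ValueError("brain_mask shape mismatch")

    def vascular_curve(self, site: tuple[int, int, int], role: str) -> "VascularFunction":
        return VascularFunction(samples=np.asarray(self.values[site], dtype=float),
                                dt=self.dt, role=role)


@dataclass
class VascularFunction:
    """1-D vascular time-attenuation curve (raw HU)."""

    samples: np.ndarray
    dt: float
    role: str  # "AIF" or "VOF"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.role not in ("AIF", "VOF"):
            raise ValueError("role must be 'AIF' or 'VOF'")


def gamma_variate(t, t0: float, alpha: float, beta: float, amplitude: float):
    """Peak-normalized gamma-variate bolus curve.

    Zero for ``t <= t0``; for ``t > t0`` equals
    ``amplitude * ((t - t0)/(alpha*beta))**alpha * exp(alpha - (t - t0)/beta)``,
    whose continuous maximum is exactly ``amplitude`` at ``t = t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0 or amplitude <= 0:
        raise ValueError("alpha, beta and amplitude must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    x = (t - t0) / (alpha * beta)
    up = x > 0
    out[up] = amplitude * x[up] ** alpha * np.exp(alpha * (1.0 - x[up]))
    return out if out.ndim else float(out)


def _exp_kernel(tau: float, dt: float, n: int) -> np.ndarray:
    """Discrete normalized exponential dispersion kernel; identity when tau = 0."""
    if tau <= 0:
        k = np.zeros(n)
        k[0] = 1.0
        return k
    t = np.arange(n) * dt
    k = np.exp(-t / tau)
    return k / k.sum()


def _shift_zero_fill(curve: np.ndarray, delay: float, dt: float) -> np.ndarray:
    """Shift right by delay (rounded to whole samples), zero-filling the head."""
    s = int(round(delay / dt))
    if s <= 0:
        return curve.copy()
    out = np.zeros_like(curve)
    out[s:] = curve[: len(curve) - s]
    return out


def disperse_and_delay(curve: np.ndarray, delay: float, dispersion: float,
                       dt: float) -> np.ndarray:
    """Apply arrival delay then exponential transit dispersion to a curve."""
    shifted = _shift_zero_fill(np.asarray(curve, dtype=float), delay, dt)
    kern = _exp_kernel(dispersion, dt, len(shifted))
    return np.convolve(shifted, kern)[: len(shifted)]


def simulate_tissue_curve(aif, cbf_rel: float, mtt: float, delay: float = 0.0,
                          dispersion: float = 0.0, dt: Optional[float] = None) -> np.ndarray:
    """Forward tissue model: C(t) = cbf_rel * dt * (AIF_eff (*) R).

    ``aif`` is a baseline-free arterial concentration curve (array or
    :class:`VascularFunction`); ``R(t) = exp(-t/mtt)`` is the residue
    function.  The convolution tail beyond the scan end is discarded,
    mirroring what a finite acquisition records.
    """
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    if isinstance(aif, VascularFunction):
        if dt is None:
            dt = aif.dt
        aif = aif.samples
    if dt is None:
        raise ValueError("dt required when aif is a bare array")
    aif = np.asarray(aif, dtype=float)
    n = len(aif)
    aif_eff = disperse_and_delay(aif, delay, dispersion, dt)
    residue = np.exp(-np.arange(n) * dt / mtt)
    return cbf_rel * dt * np.convolve(aif_eff, residue)[:n]


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random()
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _ellipse_brain_mask(grid: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid
    x = (np.arange(nx) - (nx - 1) / 2.0) / (0.45 * nx)
    y = (np.arange(ny) - (ny - 1) / 2.0) / (0.45 * ny)
    mask2d = x[:, None] ** 2 + y[None, :] ** 2 <= 1.0
    return np.repeat(mask2d[:, :, None], nz, axis=2)


def _ellipsoid_lesion(rng: np.random.Generator, brain: np.ndarray,
                      target_voxels: int) -> np.ndarray:
    if target_voxels < 1:
        return np.zeros_like(brain)
    nx, ny, nz = brain.shape
    centers = np.argwhere(brain)
    cx, cy, cz = centers[rng.integers(len(centers))]
    # semi-axes (1.2, 1.0, 0.8)*r with 4/3*pi*a*b*c = target volume
    r = (3.0 * target_voxels / (4.0 * np.pi * 1.2 * 0.8)) ** (1.0 / 3.0)
    ax, ay, az = 1.2 * r, r, max(0.8 * r, 0.6)
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ell = (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2) <= 1.0
    return ell & brain


def _vof_from_aif(t_grid: np.ndarray, t0: float, cfg: SimConfig) -> np.ndarray:
    """Venous curve: the arterial bolus delayed, dispersed, rescaled.

    The continuous (untruncated) venous peak is scaled to
    ``cfg.vof_amplitude``; on a short scan the observed VOF peak may
    therefore be cut off, exactly as in severely truncated acquisitions.
    """
    alpha, beta, _ = cfg.aif_shape
    dt = cfg.dt
    # long internal grid so the scaling never depends on scan duration
    n_long = len(t_grid) + int(round((cfg.vof_delay + 10 * max(cfg.vof_dispersion, beta) + 20) / dt))
    t_long = (np.arange(n_long) + 1) * dt
    aif_long = gamma_variate(t_long, t0, alpha, beta, 1.0)
    vof_long = disperse_and_delay(aif_long, cfg.vof_delay, cfg.vof_dispersion, dt)
    peak = vof_long.max()
    if peak <= 0:
        raise RuntimeError("degenerate venous curve")
    return cfg.vof_amplitude / peak * vof_long[: len(t_grid)]


def simulate_ctp_scan(config: SimConfig, rng: np.random.Generator,
                      scan_id: str = "scan") -> CTPSeries:
    """Simulate one 4D CTP scan with ground truth.

    Randomness comes exclusively from ``rng``; passing no generator is
    an error (there is no hidden global stream).
    """
    if rng is None or not isinstance(rng, np.random.Generator):
        raise TypeError("an explicit numpy Generator is required")
    config.validate()
    dt = config.dt
    dmean, dsd, dmin, dmax = config.duration_dist
    duration = _truncnorm_draw(rng, dmean, dsd, dmin, dmax)
    n_t = int(round(duration / dt))
    amean, asd, amin = config.bolus_arrival_dist
    t0 = _truncnorm_draw(rng, amean, asd, amin, np.inf)

    alpha, beta, amp = config.aif_shape
    t_grid = (np.arange(n_t) + 1) * dt  # sample i sits at time (i+1)*dt
    aif_conc = gamma_variate(t_grid, t0, alpha, beta, amp)
    vof_conc = _vof_from_aif(t_grid, t0, config)

    brain = _ellipse_brain_mask(config.tissue_grid)
    n_brain = int(brain.sum())
    lesion = _ellipsoid_lesion(rng, brain, int(round(config.lesion_fraction * n_brain)))

    shape3 = config.tissue_grid
    cbf = np.zeros(shape3)
    delay = np.zeros(shape3)
    mtt = np.zeros(shape3)
    healthy = brain & ~lesion
    jit = config.cbf_jitter
    cbf[healthy] = config.healthy_cbf_rel * rng.uniform(1 - jit, 1 + jit, int(healthy.sum()))
    cbf[lesion] = config.lesion_cbf_rel * rng.uniform(1 - jit, 1 + jit, int(lesion.sum()))
    mtt[healthy] = config.healthy_mtt
    mtt[lesion] = config.lesion_mtt
    # lesion arrival delay jittered on the sample grid so base curves stay shared
    delay[lesion] = config.lesion_delay + dt * rng.integers(-1, 2, int(lesion.sum()))

    values = np.zeros(shape3 + (n_t,), dtype=np.float32)
    noise = rng.normal(0.0, config.noise_sd, values.shape)
    values += noise.astype(np.float32)
    values[brain] += config.baseline_hu

    # shared unit-flow base curves per (delay, mtt, dispersion) class
    classes: dict[tuple[float, float, float], np.ndarray] = {}

    def base_curve(d: float, m: float, disp: float) -> np.ndarray:
        key = (round(d, 6), round(m, 6), round(disp, 6))
        if key not in classes:
            classes[key] = simulate_tissue_curve(aif_conc, 1.0, m, d, disp, dt=dt)
        return classes[key]

    for region, disp in ((healthy, 0.0), (lesion, config.lesion_dispersion)):
        if not region.any():
            continue
        for dval in np.unique(delay[region]):
            sub = region & (delay == dval)
            c = base_curve(float(dval), float(mtt[sub].flat[0]), disp)
            values[sub] += (cbf[sub][:, None] * c[None, :]).astype(np.float32)

    # vascular sites: healthy voxels carrying the pure arterial/venous signal
    healthy_idx = np.argwhere(healthy)
    aif_site = tuple(int(v) for v in healthy_idx[rng.integers(len(healthy_idx))])
    vof_site = tuple(int(v) for v in healthy_idx[rng.integers(len(healthy_idx))])
    while vof_site == aif_site and len(healthy_idx) > 1:
        vof_site = tuple(int(v) for v in healthy_idx[rng.integers(len(healthy_idx))])
    site_noise = rng.normal(0.0, config.noise_sd, (2, n_t))
    values[aif_site] = config.baseline_hu + aif_conc + site_noise[0]
    values[vof_site] = config.baseline_hu + vof_conc + site_noise[1]

    ratio = config.lesion_cbf_rel / config.healthy_cbf_rel
    core = lesion.copy() if ratio < 0.38 else np.zeros_like(lesion)
    truth = GroundTruth(hypo_mask=lesion, core_mask=core, aif_site=aif_site,
                        vof_site=vof_site, cbf=cbf, delay=delay, mtt=mtt,
                        bolus_arrival_s=t0)
    series = CTPSeries(values=values, dt=dt, voxel_volume_ml=config.voxel_volume_ml,
                       brain_mask=brain, truth=truth, scan_id=scan_id)
    series.validate()
    return series


def simulate_cohort(config: SimConfig):
    """Simulate ``config.n_scans`` scans with per-scan sub-seeds.

    Returns ``(series_list, manifest)`` where the manifest is a list of
    per-scan dict rows (id, seed, duration, truth volumes).
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_scans)
    series_list: list[CTPSeries] = []
    manifest: list[dict] = []
    seen: set[str] = set()
    for i, child in enumerate(children):
        scan_id = f"sim{i:03d}"
        if scan_id in seen:
            raise ValueError(f"duplicate scan id {scan_id}")
        seen.add(scan_id)
        rng = np.random.default_rng(child)
        s = simulate_ctp_scan(config, rng, scan_id=scan_id)
        series_list.append(s)
        manifest.append({
            "scan_id": scan_id,
            "seed": int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31)),
            "duration_s": s.duration_s,
            "bolus_arrival_s": s.truth.bolus_arrival_s,
            "truth_hypo_ml": float(s.truth.hypo_mask.sum() * s.voxel_volume_ml),
            "truth_core_ml": float(s.truth.core_mask.sum() * s.voxel_volume_ml),
        })
    return series_list, manifest
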