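"""Synthetic multi-scan datasets with known ground truth.

The generator emulates the qualitative regime the pipeline is built to
handle: intermittent head-motion spikes on top of low-amplitude AR(1)
drift, spike-locked BOLD artifacts whose shared spatial loading decays
with distance from a random focus (inducing distance-dependent spurious
FC), smooth tissue-like nuisance signals, and covariate effects (a
continuous age-like and a binary sex-like effect) planted on disjoint
edge sets of the latent connectivity.

All randomness flows from a single master seed through per-scan,
per-purpose substreams, so every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from . import io as fio
from .metrics import DEFAULT_RADIUS_MM, compute_fd
from .types import (
    FDTrace,
    MotionTrace,
    ROIGeometry,
    ROITimeSeries,
    ScanRecord,
    VolumeSeries,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ScanBundle",
    "SyntheticDataset",
    "simulate_motion",
    "simulate_scan",
    "simulate_dataset",
    "simulate_volumes",
]

# substream tags keep per-purpose RNGs independent
_STREAM_GLOBAL, _STREAM_MOTION, _STREAM_BOLD, _STREAM_VOLUME = 0, 1, 2, 3


def _rng(seed: int, stream: int, scan_index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(scan_index)])


@dataclass
class SimulationConfig:
    n_scans: int = 20
    n_roi: int = 30
    frames: int = 144
    tr_seconds: float = 3.0
    spike_rate: float = 12.0  # expected high-motion events per scan
    spike_amp_mm: float = 3.0  # exponential scale of spike magnitude
    motion_var: float = 0.8  # lognormal sigma of per-scan spike-rate severity
    baseline_ar: float = 0.95  # AR(1) coefficient of low-amplitude motion
    baseline_scale_mm: float = 0.12  # AR(1) innovation SD
    artifact_gain: float = 4.0  # BOLD contamination per mm of FD above the floor
    artifact_floor_mm: float = 0.75  # FD level below which frames stay clean
    artifact_decay_mm: float = 40.0  # length scale of shared-artifact loading
    ga_effect: float = 0.2
    sex_effect: float = 0.12
    n_signal_edges: int | None = None  # affected connections per covariate; None = auto
    tissue_gain: float = 0.4
    noise_sd: float = 0.8
    seed: int = 0
    ga_window: tuple[float, float] = (19.0, 40.0)
    radius_mm: float = DEFAULT_RADIUS_MM
    n_tissue_signals: int = 10
    volume_artifact_gain: float = 0.4  # FD-jump gain for simulated volumes
    volume_grid: tuple[int, int, int] = (16, 16, 8)
    volume_signal_amp: float = 1.0

    def __post_init__(self) -> None:
        n_edges = self.n_roi * (self.n_roi - 1) // 2
        if self.n_signal_edges is None:
            # auto: 40 edges, capped so the two planted sets stay disjoint
            self.n_signal_edges = max(1, min(30, n_edges // 5))
        if min(self.n_scans, self.n_roi, self.frames, self.n_signal_edges) < 1:
            raise ValueError("all counts must be positive")
        if 2 * self.n_signal_edges > n_edges:
            raise ValueError("n_signal_edges too large for n_roi")
        if not (0 <= self.baseline_ar < 1):
            raise ValueError("baseline_ar must lie in [0, 1)")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if not self.artifact_decay_mm > 0:
            raise ValueError("artifact_decay_mm must be positive")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class SyntheticTruth:
    latent_fc: np.ndarray  # (n_roi, n_roi) correlation, symmetric PSD unit diag
    ga_edges: np.ndarray  # (k, 2) planted continuous-covariate edges
    sex_edges: np.ndarray  # (k, 2) planted binary-covariate edges, disjoint
    geometry: ROIGeometry | None = None
    fd_traces: list[FDTrace] = field(default_factory=list)
    ga_weeks: list[float] = field(default_factory=list)
    sex: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = np.asarray(self.latent_fc, dtype=float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("latent_fc must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-8):
            raise ValueError("latent_fc must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("latent_fc must be positive semi-definite")
        a = {tuple(e) for e in np.asarray(self.ga_edges)}
        b = {tuple(e) for e in np.asarray(self.sex_edges)}
        if a & b:
            raise ValueError("ga_edges and sex_edges must be disjoint")


@dataclass
class ScanBundle:
    record: ScanRecord
    motion: MotionTrace
    bold: ROITimeSeries
    tissue_signals: np.ndarray  # (frames, n_tissue_signals)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    scans: list[ScanBundle]
    truth: SyntheticTruth
    geometry: ROIGeometry

    def write(self, out_dir: str | Path) -> None:
        """Write the full bundle as plain-text artifacts."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.scans:
            fio.write_motion_trace(out / f"{s.record.scan_id}_motion.par", s.motion)
            fio.write_roi_timeseries(out / f"{s.record.scan_id}_bold.tsv", s.bold)
            np.savetxt(
                out / f"{s.record.scan_id}_tissue.tsv",
                s.tissue_signals,
                fmt="%.10g",
                delimiter="\t",
            )
        fio.write_scan_records(out / "scans.tsv", [s.record for s in self.scans])
        fio.write_roi_geometry(out / "centroids.tsv", self.geometry)
        fio.write_json(
            out / "truth.json",
            {
                "latent_fc": self.truth.latent_fc,
                "ga_edges": self.truth.ga_edges,
                "sex_edges": self.truth.sex_edges,
                "ga_weeks": self.truth.ga_weeks,
                "sex": self.truth.sex,
                "seed": self.config.seed,
            },
        )


def simulate_motion(config: SimulationConfig, scan_index: int) -> MotionTrace:
    """6-parameter trace: AR(1) baseline plus sparse step-change spikes.

    Spike events are Poisson in number with exponential amplitudes; each
    event steps the head to a new pose, splitting its FD magnitude
    across the six axes with random signs (rotations scaled by the brain
    radius so the FD contribution of an isolated event equals its drawn
    amplitude exactly). Deterministic given ``(config.seed, scan_index)``.
    """
    rng = _rng(config.seed, _STREAM_MOTION, scan_index)
    n, phi = config.frames, config.baseline_ar
    # AR(1) baseline per axis; rotations generated in radians at matched mm scale
    innov = rng.standard_normal((n, 6)) * config.baseline_scale_mm
    innov[:, 3:] /= config.radius_mm
    params = np.zeros((n, 6))
    for t in range(1, n):
        params[t] = phi * params[t - 1] + innov[t]
    # spike events: step changes persisting until the next event; a
    # lognormal severity factor makes scans heterogeneous in spike load
    rate = config.spike_rate
    if config.motion_var > 0:
        rate *= float(rng.lognormal(mean=0.0, sigma=config.motion_var))
    n_events = int(rng.poisson(rate))
    n_events = min(n_events, n - 1)
    if n_events > 0 and config.spike_amp_mm > 0:
        event_frames = rng.choice(np.arange(1, n), size=n_events, replace=False)
        for t in np.sort(event_frames):
            amp = rng.exponential(config.spike_amp_mm)
            weights = rng.dirichlet(np.ones(6))
            signs = rng.choice([-1.0, 1.0], size=6)
            delta = signs * weights * amp
            delta[3:] /= config.radius_mm
            params[t:] += delta
    return MotionTrace(params=params, tr_seconds=config.tr_seconds)


def _nearest_psd_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and renormalize to a correlation matrix."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, floor)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _scan_covariance(
    config: SimulationConfig, truth: SyntheticTruth, record: ScanRecord
) -> np.ndarray:
    """Latent correlation after per-scan covariate modulation."""
    C = truth.latent_fc.copy()
    lo, hi = config.ga_window
    z_ga = (record.ga_weeks - 0.5 * (lo + hi)) / ((hi - lo) / np.sqrt(12.0))
    for i, j in truth.ga_edges:
        v = np.clip(C[i, j] * (1.0 + config.ga_effect * z_ga), -0.9, 0.9)
        C[i, j] = C[j, i] = v
    if record.sex == "M" and config.sex_effect != 0.0:
        for i, j in truth.sex_edges:
            v = np.clip(C[i, j] + config.sex_effect, -0.9, 0.9)
            C[i, j] = C[j, i] = v
    return _nearest_psd_correlation(C)


def simulate_scan(
    config: SimulationConfig,
    truth: SyntheticTruth,
    motion: MotionTrace,
    record: ScanRecord,
    scan_index: int = 0,
) -> tuple[ROITimeSeries, np.ndarray]:
    """ROI BOLD for one scan, plus its raw tissue-signal matrix.

    BOLD = network signal (latent covariance after covariate modulation)
    + FD-locked shared artifact with distance-decaying loadings around
    per-burst random foci + tissue components + white noise.
    """
    if truth.geometry is None:
        raise ValueError("truth must carry ROI geometry")
    n, n_roi = config.frames, config.n_roi
    rng = _rng(config.seed, _STREAM_BOLD, scan_index)
    C = _scan_covariance(config, truth, record)
    try:
        L = np.linalg.cholesky(C + 1e-9 * np.eye(n_roi))
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("latent covariance is not positive definite") from exc
    bold = rng.standard_normal((n, n_roi)) @ L.T

    # spike-locked shared artifact with per-burst random focus; frames
    # below the FD floor stay clean, so censoring can actually remove it
    fd = compute_fd(motion, config.radius_mm).fd
    fd_excess = np.maximum(fd - config.artifact_floor_mm, 0.0)
    if config.artifact_gain != 0.0:
        dmat = truth.geometry.pairwise_distances()
        focus_default = int(rng.integers(n_roi))
        focus = np.full(n, focus_default)
        high = fd_excess > 0
        t = 0
        while t < n:
            if high[t]:
                f = int(rng.integers(n_roi))
                while t < n and high[t]:
                    focus[t] = f
                    t += 1
            else:
                t += 1
        loadings = np.exp(-dmat / config.artifact_decay_mm)  # (n_roi focus, n_roi)
        bold += config.artifact_gain * fd_excess[:, None] * loadings[focus]

    # smooth tissue-like nuisance components with random ROI loadings
    latent_tissue = gaussian_filter1d(rng.standard_normal((n, 2)), sigma=5.0, axis=0)
    latent_tissue /= np.maximum(latent_tissue.std(axis=0, ddof=1), 1e-12)
    if config.tissue_gain != 0.0:
        roi_load = rng.normal(0.0, config.tissue_gain, (2, n_roi))
        bold += latent_tissue @ roi_load
    mixing = rng.normal(0.0, 1.0, (2, config.n_tissue_signals))
    tissue_signals = latent_tissue @ mixing + 0.05 * rng.standard_normal(
        (n, config.n_tissue_signals)
    )

    if config.noise_sd > 0:
        bold += config.noise_sd * rng.standard_normal((n, n_roi))
    ts = ROITimeSeries(
        data=bold,
        roi_ids=[f"roi{i:03d}" for i in range(n_roi)],
        tr_seconds=config.tr_seconds,
    )
    return ts, tissue_signals


def _draw_edge_sets(
    rng: np.random.Generator, n_roi: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    iu = np.column_stack(np.triu_indices(n_roi, k=1))
    if 2 * k > iu.shape[0]:
        raise ValueError("n_signal_edges too large for n_roi")
    chosen = rng.choice(iu.shape[0], size=2 * k, replace=False)
    return iu[chosen[:k]], iu[chosen[k:]]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full multi-scan bundle with ground truth and ROI geometry."""
    rng = _rng(config.seed, _STREAM_GLOBAL)
    centroids = rng.uniform(0.0, 90.0, (config.n_roi, 3))
    geometry = ROIGeometry(centroids=centroids)

    # latent connectivity: distance kernel (PSD) with planted edge values
    D = geometry.pairwise_distances()
    C = 0.3 * np.exp(-D / 40.0)
    np.fill_diagonal(C, 1.0)
    ga_edges, sex_edges = _draw_edge_sets(rng, config.n_roi, config.n_signal_edges)
    for i, j in np.vstack([ga_edges, sex_edges]):
        C[i, j] = C[j, i] = 0.25
    latent = _nearest_psd_correlation(C)
    truth = SyntheticTruth(
        latent_fc=latent, ga_edges=ga_edges, sex_edges=sex_edges, geometry=geometry
    )

    lo, hi = config.ga_window
    ga = rng.uniform(lo, hi, config.n_scans)
    sexes = np.array(["M", "F"])[np.arange(config.n_scans) % 2]
    rng.shuffle(sexes)

    scans: list[ScanBundle] = []
    for i in range(config.n_scans):
        record = ScanRecord(
            scan_id=f"scan{i:03d}",
            ga_weeks=float(ga[i]),
            sex=str(sexes[i]),
            ga_range=(min(18.0, lo), max(42.0, hi)),
        )
        motion = simulate_motion(config, i)
        bold, tissue = simulate_scan(config, truth, motion, record, i)
        scans.append(ScanBundle(record=record, motion=motion, bold=bold, tissue_signals=tissue))
        truth.fd_traces.append(compute_fd(motion, config.radius_mm))
        truth.ga_weeks.append(float(ga[i]))
        truth.sex.append(str(sexes[i]))
    return SyntheticDataset(config=config, scans=scans, truth=truth, geometry=geometry)


def simulate_volumes(
    config: SimulationConfig, motion: MotionTrace, scan_index: int = 0
) -> VolumeSeries:
    """Small 4-D volume with block-structured signal and FD-locked jumps.

    The grid is partitioned into cubic blocks carrying smooth shared
    courses (blocks 0 and 1 share one course — a planted two-block
    network, block 0 doubling as the seed region). Head motion enters as
    a global intensity jump proportional to FD. Gray matter covers the
    signal blocks; brain covers everything but a one-voxel border.
    """
    nx, ny, nz = config.volume_grid
    n = motion.frames
    rng = _rng(config.seed, _STREAM_VOLUME, scan_index)
    fd = compute_fd(motion, config.radius_mm).fd
    fd_excess = np.maximum(fd - config.artifact_floor_mm, 0.0)

    data = np.full((nx, ny, nz, n), 100.0)
    brain = np.zeros((nx, ny, nz), dtype=bool)
    brain[1:-1, 1:-1, :] = True
    gray = np.zeros_like(brain)
    seed_mask = np.zeros_like(brain)

    # cubic blocks inside the brain
    bs = 4
    blocks: list[tuple[slice, slice, slice]] = []
    for x0 in range(1, nx - 1 - bs + 1, bs):
        for y0 in range(1, ny - 1 - bs + 1, bs):
            for z0 in range(0, nz - bs + 1, bs):
                blocks.append((slice(x0, x0 + bs), slice(y0, y0 + bs), slice(z0, z0 + bs)))
    shared = gaussian_filter1d(rng.standard_normal(n), sigma=3.0)
    shared /= max(shared.std(), 1e-12)
    for b, sl in enumerate(blocks):
        if b in (0, 1):
            course = shared
        else:
            course = gaussian_filter1d(rng.standard_normal(n), sigma=3.0)
            course /= max(course.std(), 1e-12)
        data[sl[0], sl[1], sl[2], :] += config.volume_signal_amp * course
        gray[sl[0], sl[1], sl[2]] = True
        if b == 0:
            seed_mask[sl[0], sl[1], sl[2]] = True
    gray &= brain

    # FD-locked intensity jumps with a smooth spatial loading field shared
    # across scans (dataset-level stream) so group contrasts are patchy
    # rather than a single global blob
    rng_field = _rng(config.seed, _STREAM_VOLUME, 999_999)
    field_ = gaussian_filter(rng_field.standard_normal((nx, ny, nz)), sigma=1.5)
    field_ = (field_ - field_.min()) / max(field_.max() - field_.min(), 1e-12)
    field_[seed_mask] = 1.0  # artifact always reaches the seed region
    data[brain] += config.volume_artifact_gain * field_[brain][:, None] * fd_excess[None, :]
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)

    white = brain & ~gray
    csf = np.zeros_like(brain)
    csf[:, :, :1] = True
    csf &= ~gray
    return VolumeSeries(
        data=data,
        masks={"brain": brain, "gray": gray, "white": white, "csf": csf, "seed": seed_mask},
        affine=np.diag([2.5, 2.5, 3.0, 1.0]),
    )
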