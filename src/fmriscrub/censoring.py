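"""Censor masks, nuisance designs, and one-step cleaning.

Censoring, nuisance regression, and bandpass filtering are applied
simultaneously: the design carries sine/cosine regressors for every DFT
frequency outside the passband (built on the *original* frame grid), and
ordinary least squares is solved on retained rows only. No censored
frame can therefore leak into any retained residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import DEFAULT_RADIUS_MM, DVARSTrace
from .types import CensorMask, CensorMetric, FDTrace, MotionTrace, ROITimeSeries

__all__ = [
    "NuisanceDesign",
    "CleanSeries",
    "make_censor_mask",
    "build_motion_regressors",
    "tissue_pcs",
    "spectral_basis",
    "build_design",
    "clean_timeseries",
    "RankDeficientError",
]

VALID_MOTION_SETS = (6, 12, 24, 36)
DEFAULT_BAND_HZ = (0.01, 0.1)


class RankDeficientError(RuntimeError):
    """Too few retained frames for the design rank; scan must be excluded."""


@dataclass
class NuisanceDesign:
    """frames x k design matrix with labeled columns."""

    matrix: np.ndarray
    column_labels: list[str]
    motion_set: int
    n_tissue_pcs: int
    band_hz: tuple[float, float]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("column count does not match labels")

    @property
    def frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CleanSeries:
    """Residual BOLD on retained frames after one-step cleaning."""

    data: np.ndarray  # (n_retained, n_roi)
    retained_index: np.ndarray
    dof: int
    roi_ids: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.retained_index = np.asarray(self.retained_index, dtype=int)
        if self.data.shape[0] != self.retained_index.size:
            raise ValueError("rows must equal number of retained frames")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")

    @property
    def n_retained(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


def make_censor_mask(
    metric_trace: FDTrace | DVARSTrace,
    threshold: float,
    metric: CensorMetric | str = CensorMetric.FD,
    extend_before: bool = False,
    sdvars_trace: DVARSTrace | None = None,
    sdvars_threshold: float | None = None,
) -> CensorMask:
    """Censor frames whose metric strictly exceeds ``threshold``.

    With ``extend_before`` the frame preceding each censored frame is
    removed as well. For the combined metric a frame is removed when
    either trace exceeds its threshold; pass the FD trace as
    ``metric_trace`` and the sDVARS trace via ``sdvars_trace``.
    """
    metric = CensorMetric(metric)
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    primary = metric_trace.fd if isinstance(metric_trace, FDTrace) else metric_trace.sdvars
    bad = primary > threshold
    if metric is CensorMetric.FD_AND_SDVARS:
        if sdvars_trace is None or sdvars_threshold is None:
            raise ValueError("combined metric requires sdvars_trace and sdvars_threshold")
        if sdvars_trace.frames != primary.size:
            raise ValueError("sDVARS trace length differs from FD trace")
        bad = bad | (sdvars_trace.sdvars > sdvars_threshold)
    if extend_before:
        bad = bad.copy()
        bad[:-1] |= bad[1:]
    return CensorMask(keep=~bad, threshold_mm=threshold, metric=metric)


def build_motion_regressors(
    motion: MotionTrace,
    motion_set: int = 12,
    radius_mm: float = DEFAULT_RADIUS_MM,
) -> tuple[np.ndarray, list[str]]:
    """Motion regressor expansion: 6, 12 (+derivatives), 24 or 36 (Volterra).

    6  -> [R]
    12 -> [R, R'] with R' the backward difference (first row 0)
    24 -> [R, R^2, R_{t-1}, R_{t-1}^2]
    36 -> 24 + [R_{t-2}, R_{t-2}^2]

    Rotational columns are converted to mm by arc length at
    ``radius_mm`` before any expansion; lagged columns are zero-padded.
    """
    if motion_set not in VALID_MOTION_SETS:
        raise ValueError(f"motion_set must be one of {VALID_MOTION_SETS}")
    if motion.frames < 3:
        raise ValueError("need >= 3 frames for motion regressors")
    R = motion.params.copy()
    R[:, 3:] *= radius_mm
    names = ["dx", "dy", "dz", "phi", "theta", "psi"]

    def lagged(arr: np.ndarray, lag: int) -> np.ndarray:
        out = np.zeros_like(arr)
        out[lag:] = arr[:-lag]
        return out

    blocks: list[tuple[np.ndarray, str]] = [(R, "R")]
    if motion_set == 12:
        deriv = np.zeros_like(R)
        deriv[1:] = np.diff(R, axis=0)
        blocks.append((deriv, "dR"))
    elif motion_set >= 24:
        blocks.append((R**2, "R^2"))
        blocks.append((lagged(R, 1), "R[t-1]"))
        blocks.append((lagged(R, 1) ** 2, "R[t-1]^2"))
        if motion_set == 36:
            blocks.append((lagged(R, 2), "R[t-2]"))
            blocks.append((lagged(R, 2) ** 2, "R[t-2]^2"))
    matrix = np.hstack([b for b, _ in blocks])
    labels = [f"{tag}:{n}" for _, tag in blocks for n in names]
    assert matrix.shape[1] == motion_set
    return matrix, labels


def tissue_pcs(signals: np.ndarray, n_pcs: int = 3) -> np.ndarray:
    """Top principal-component time courses of tissue signals.

    Columns are centered before the SVD; returned components are scaled
    to unit variance.
    """
    signals = np.asarray(signals, dtype=float)
    frames, m = signals.shape
    if m < n_pcs:
        raise ValueError(f"need >= {n_pcs} tissue signals, got {m}")
    if frames <= n_pcs:
        raise ValueError("need more frames than components")
    centered = signals - signals.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if np.sum(s > s[0] * 1e-10) < n_pcs:
        raise ValueError(f"tissue signals have rank < {n_pcs}")
    pcs = u[:, :n_pcs] * s[:n_pcs]
    return pcs / pcs.std(axis=0, ddof=1)


def spectral_basis(
    frames: int,
    tr_seconds: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> tuple[np.ndarray, list[str]]:
    """Sine/cosine regressors at every DFT frequency outside the passband.

    Built on the original frame grid so that OLS on retained rows
    implements band-pass-with-censoring without leakage. A linear trend
    column is always included; at the Nyquist frequency (even ``frames``)
    only the cosine column exists.
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band {band_hz} must satisfy 0 <= low < high <= Nyquist ({nyquist:g} Hz)"
        )
    t = np.arange(frames)
    cols = [np.linspace(-1.0, 1.0, frames)]
    labels = ["trend"]
    for k in range(1, frames // 2 + 1):
        freq = k / (frames * tr_seconds)
        if low <= freq <= high:
            continue
        arg = 2.0 * np.pi * k * t / frames
        cols.append(np.cos(arg))
        labels.append(f"cos:{freq:.6g}Hz")
        if not (frames % 2 == 0 and k == frames // 2):  # sine at Nyquist is 0
            cols.append(np.sin(arg))
            labels.append(f"sin:{freq:.6g}Hz")
    return np.column_stack(cols), labels


def build_design(
    motion: MotionTrace,
    motion_set: int = 12,
    tissue_signals: np.ndarray | None = None,
    n_tissue_pcs: int = 3,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    radius_mm: float = DEFAULT_RADIUS_MM,
) -> NuisanceDesign:
    """Full nuisance design: intercept + motion set + tissue PCs + spectral basis."""
    frames = motion.frames
    mot, mot_labels = build_motion_regressors(motion, motion_set, radius_mm)
    spec, spec_labels = spectral_basis(frames, motion.tr_seconds, band_hz)
    parts = [np.ones((frames, 1)), mot]
    labels = ["intercept"] + mot_labels
    n_pcs = 0
    if tissue_signals is not None and n_tissue_pcs > 0:
        pcs = tissue_pcs(np.asarray(tissue_signals), n_tissue_pcs)
        parts.append(pcs)
        labels += [f"tissue_pc{i + 1}" for i in range(pcs.shape[1])]
        n_pcs = pcs.shape[1]
    parts.append(spec)
    labels += spec_labels
    return NuisanceDesign(
        matrix=np.hstack(parts),
        column_labels=labels,
        motion_set=motion_set,
        n_tissue_pcs=n_pcs,
        band_hz=band_hz,
    )


def clean_timeseries(
    ts: ROITimeSeries, design: NuisanceDesign, mask: CensorMask | None = None
) -> CleanSeries:
    """Simultaneous censoring + nuisance regression + bandpass.

    Both data and design are restricted to retained rows before the
    least-squares fit, so censored frames cannot influence any residual.
    """
    if design.frames != ts.frames:
        raise ValueError("design rows must equal time-series frames")
    if mask is not None and mask.frames != ts.frames:
        raise ValueError("censor mask length must equal time-series frames")
    idx = np.arange(ts.frames) if mask is None else mask.retained_index
    X = design.matrix[idx]
    Y = ts.data[idx]
    rank = int(np.linalg.matrix_rank(X))
    dof = idx.size - rank
    if dof < 1:
        raise RankDeficientError(
            f"retained frames ({idx.size}) <= design rank ({rank}); "
            f"dof deficit {rank + 1 - idx.size}"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return CleanSeries(
        data=resid,
        retained_index=idx,
        dof=dof,
        roi_ids=list(ts.roi_ids),
        tr_seconds=ts.tr_seconds,
    )
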