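"""Motion and data-quality metrics: FD, scaled DVARS, tSNR, and their
post-censoring summaries.

FD is the sum of absolute backward differences of the six rigid-body
parameters, with the three rotational differences converted from radians
to mm by arc length at a single assumed brain radius. Frame 0 of both FD
and sDVARS is defined as 0 (there is no preceding frame to difference
against).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CensorMask, FDTrace, MotionSummary, MotionTrace, VolumeSeries

__all__ = [
    "DVARSTrace",
    "TSNRMap",
    "ConcordanceCurve",
    "compute_fd",
    "compute_sdvars",
    "compute_tsnr",
    "summarize_motion",
    "fd_sdvars_concordance",
    "retained_chunks",
]

DEFAULT_RADIUS_MM = 35.0


@dataclass
class DVARSTrace:
    """Per-frame scaled DVARS (dimensionless); ``sdvars[0] = 0``."""

    sdvars: np.ndarray
    mask_name: str = "gray"

    def __post_init__(self) -> None:
        self.sdvars = np.asarray(self.sdvars, dtype=float)
        if self.sdvars.ndim != 1:
            raise ValueError("sdvars must be 1-D")
        if self.sdvars[0] != 0.0 or np.any(self.sdvars < 0):
            raise ValueError("sdvars[0] must be 0 and all values >= 0")

    @property
    def frames(self) -> int:
        return self.sdvars.size


@dataclass
class TSNRMap:
    """Voxelwise temporal SNR and its brain-mask average."""

    voxel_tsnr: np.ndarray
    mean_tsnr: float
    n_excluded_zero_sd: int = 0


@dataclass
class ConcordanceCurve:
    """Sensitivity/specificity of sDVARS thresholds against an FD cut."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # NaN where undefined (no positive frames)
    specificity: np.ndarray
    fd_reference_mm: float = 1.5
    n_positive: int = 0
    n_negative: int = 0


def compute_fd(motion: MotionTrace, radius_mm: float = DEFAULT_RADIUS_MM) -> FDTrace:
    """Framewise displacement from a 6-parameter motion trace.

    ``fd[i] = |d dx| + |d dy| + |d dz| + radius * (|d phi| + |d theta| + |d psi|)``
    with backward differences and ``fd[0] = 0``.
    """
    if not radius_mm > 0:
        raise ValueError("radius_mm must be positive")
    diffs = np.abs(np.diff(motion.params, axis=0))
    fd = np.zeros(motion.frames)
    fd[1:] = diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)
    return FDTrace(fd=fd, radius_mm=radius_mm)


def compute_sdvars(vols: VolumeSeries, mask_name: str = "gray") -> DVARSTrace:
    """Scaled DVARS over a tissue mask.

    For frame t >= 1, the root-mean-square over mask voxels of the
    backward intensity difference, divided by the grand mean intensity
    of those voxels over all frames. Scale-invariant by construction.
    """
    if mask_name not in vols.masks:
        raise ValueError(f"mask {mask_name!r} not present in volume series")
    mask = vols.masks[mask_name]
    if not mask.any():
        raise ValueError(f"mask {mask_name!r} is empty")
    sig = vols.data[mask]  # (n_voxels, frames)
    grand_mean = float(sig.mean())
    if grand_mean == 0.0:
        raise ValueError("grand mean intensity is zero; cannot scale DVARS")
    rms = np.sqrt(np.mean(np.diff(sig, axis=1) ** 2, axis=0))
    sdvars = np.zeros(vols.frames)
    sdvars[1:] = rms / abs(grand_mean)
    return DVARSTrace(sdvars=sdvars, mask_name=mask_name)


def compute_tsnr(vols: VolumeSeries, mask_name: str = "brain") -> TSNRMap:
    """Voxelwise temporal mean / sample SD, averaged within the brain mask.

    Voxels with zero temporal SD are excluded from the average and
    counted in the report.
    """
    if mask_name not in vols.masks:
        raise ValueError(f"mask {mask_name!r} not present in volume series")
    if vols.frames < 3:
        raise ValueError("tSNR requires >= 3 frames")
    mean = vols.data.mean(axis=3)
    sd = vols.data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    mask = vols.masks[mask_name]
    in_mask = tsnr[mask]
    valid = np.isfinite(in_mask)
    if not valid.any():
        raise ValueError("no voxel with non-zero temporal SD inside the mask")
    return TSNRMap(
        voxel_tsnr=tsnr,
        mean_tsnr=float(in_mask[valid].mean()),
        n_excluded_zero_sd=int((~valid).sum()),
    )


class AllFramesCensoredError(RuntimeError):
    """Every frame of a scan was censored; the scan must be excluded."""


def retained_chunks(keep: np.ndarray) -> list[int]:
    """Lengths of maximal contiguous runs of retained frames."""
    keep = np.asarray(keep, dtype=bool)
    chunks: list[int] = []
    run = 0
    for k in keep:
        if k:
            run += 1
        elif run:
            chunks.append(run)
            run = 0
    if run:
        chunks.append(run)
    return chunks


def summarize_motion(
    fd: FDTrace, mask: CensorMask, recompute_across_gaps: bool = False
) -> MotionSummary:
    """FD summary over retained frames plus contiguity chunks.

    By default the original FD values of retained frames are reused;
    ``recompute_across_gaps=True`` instead treats surviving frames as
    newly adjacent and is provided for sensitivity analyses only (it
    needs the FD trace to be recomputed by the caller, so here it only
    zeroes FD at chunk starts).
    """
    if mask.frames != fd.frames:
        raise ValueError("mask and FD trace lengths differ")
    idx = mask.retained_index
    if idx.size == 0:
        raise AllFramesCensoredError("all frames censored")
    vals = fd.fd[idx].copy()
    if recompute_across_gaps:
        # first frame of each retained run has no retained predecessor
        starts = np.concatenate(([True], np.diff(idx) > 1))
        vals[starts] = 0.0
    return MotionSummary(
        fd_ave=float(vals.mean()),
        fd_max=float(vals.max()),
        n_retained=int(idx.size),
        chunks=retained_chunks(mask.keep),
    )


def fd_sdvars_concordance(
    fd: FDTrace,
    dv: DVARSTrace,
    fd_ref: float = 1.5,
    sdvars_grid: np.ndarray | list[float] | None = None,
) -> ConcordanceCurve:
    """Sensitivity/specificity of sDVARS cuts against FD > ``fd_ref``.

    Frame 0 is excluded (both metrics are defined 0 there). Sensitivity
    is P(sdvars > s | FD > fd_ref); specificity is
    P(sdvars <= s | FD <= fd_ref). With no positive frames sensitivity
    is reported as NaN.
    """
    if fd.frames != dv.frames:
        raise ValueError("FD and sDVARS lengths differ")
    fd_v = fd.fd[1:]
    dv_v = dv.sdvars[1:]
    if sdvars_grid is None:
        sdvars_grid = np.linspace(0.0, max(dv_v.max(), 1e-12), 51)
    grid = np.asarray(sdvars_grid, dtype=float)
    pos = fd_v > fd_ref
    neg = ~pos
    sens = np.full(grid.size, np.nan)
    spec = np.full(grid.size, np.nan)
    for i, s in enumerate(grid):
        if pos.any():
            sens[i] = float((dv_v[pos] > s).mean())
        if neg.any():
            spec[i] = float((dv_v[neg] <= s).mean())
    return ConcordanceCurve(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        fd_reference_mm=fd_ref,
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
    )
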