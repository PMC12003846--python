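"""Shared domain types for the motion-QC pipeline.

All array fields are plain numpy arrays; dataclasses validate their
invariants in ``__post_init__`` so that malformed objects fail fast at
construction rather than deep inside an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CensorMetric",
    "MotionTrace",
    "FDTrace",
    "CensorMask",
    "MotionSummary",
    "ROITimeSeries",
    "VolumeSeries",
    "ScanRecord",
    "ROIGeometry",
]


class CensorMetric(str, Enum):
    """Which motion metric a censor mask was thresholded on."""

    FD = "fd"
    SDVARS = "sdvars"
    FD_AND_SDVARS = "both"


@dataclass
class MotionTrace:
    """Per-frame 6-parameter rigid head motion.

    Parameters are ordered ``[dx, dy, dz, phi, theta, psi]`` with
    translations in mm and rotations in radians.
    """

    params: np.ndarray  # (frames, 6)
    tr_seconds: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion params must be (frames, 6), got {self.params.shape}"
            )
        if self.params.shape[0] < 2:
            raise ValueError("motion trace requires at least 2 frames")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion params contain non-finite values")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def frames(self) -> int:
        return self.params.shape[0]


@dataclass
class FDTrace:
    """Framewise displacement in mm; ``fd[0]`` is defined as 0."""

    fd: np.ndarray
    radius_mm: float

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1 or self.fd.size < 2:
            raise ValueError("fd must be a 1-D vector with >= 2 frames")
        if self.fd[0] != 0.0:
            raise ValueError("fd[0] must be 0 by definition")
        if np.any(self.fd < 0) or not np.all(np.isfinite(self.fd)):
            raise ValueError("fd values must be finite and non-negative")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")

    @property
    def frames(self) -> int:
        return self.fd.size


@dataclass
class CensorMask:
    """Boolean frame-retention vector at a stated threshold."""

    keep: np.ndarray
    threshold_mm: float
    metric: CensorMetric = CensorMetric.FD

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1:
            raise ValueError("keep must be 1-D")
        if not self.threshold_mm > 0:
            raise ValueError("threshold_mm must be positive")
        self.metric = CensorMetric(self.metric)

    @property
    def frames(self) -> int:
        return self.keep.size

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def retained_index(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


@dataclass
class MotionSummary:
    """Post-censoring motion summary for one scan."""

    fd_ave: float
    fd_max: float
    n_retained: int
    chunks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.fd_max >= self.fd_ave >= 0):
            raise ValueError("require fd_max >= fd_ave >= 0")
        if sum(self.chunks) != self.n_retained:
            raise ValueError("chunk lengths must sum to n_retained")


@dataclass
class ROITimeSeries:
    """frames x n_roi matrix of region-averaged BOLD values."""

    data: np.ndarray
    roi_ids: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x n_roi)")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("require frames >= 2 and n_roi >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains missing/non-finite values")
        if len(self.roi_ids) != self.data.shape[1]:
            raise ValueError("roi_ids length must equal n_roi")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class VolumeSeries:
    """Small 4-D volume with named tissue masks, for voxel-level QC."""

    data: np.ndarray  # (x, y, z, frames)
    masks: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("volume data must be 4-D (x, y, z, frames)")
        if self.data.shape[3] < 2:
            raise ValueError("volume series requires >= 2 frames")
        spatial = self.data.shape[:3]
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != spatial:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} does not match "
                    f"volume spatial shape {spatial}"
                )
            self.masks[name] = mask
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def frames(self) -> int:
        return self.data.shape[3]


@dataclass
class ScanRecord:
    """Per-scan metadata: age and sex targets plus identifiers."""

    scan_id: str
    ga_weeks: float
    sex: str  # "M" or "F"
    subject_id: str = ""
    ga_range: tuple[float, float] = (18.0, 42.0)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        lo, hi = self.ga_range
        if not (lo <= self.ga_weeks <= hi):
            raise ValueError(
                f"ga_weeks {self.ga_weeks} outside plausible range [{lo}, {hi}]"
            )
        if not self.subject_id:
            self.subject_id = self.scan_id


@dataclass
class ROIGeometry:
    """ROI centroid coordinates in mm."""

    centroids: np.ndarray  # (n_roi, 3)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must be (n_roi, 3)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def n_roi(self) -> int:
        return self.centroids.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Full n_roi x n_roi Euclidean distance matrix."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
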