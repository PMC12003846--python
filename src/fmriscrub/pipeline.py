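"""End-to-end orchestration: censor + clean + connect a whole dataset.

This is the glue the CLI and the evaluation scripts share. A scan is
excluded from a condition when it retains fewer frames than the
scan-level minimum (default 40, i.e. two minutes at TR = 3 s) or too few
frames for the design rank; exclusions are logged, mirroring the
shrinking-N behavior expected at strict thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .censoring import (
    CleanSeries,
    RankDeficientError,
    build_design,
    clean_timeseries,
    make_censor_mask,
)
from .connectivity import FCProfile, compute_fc, fc_profile
from .metrics import compute_fd, summarize_motion
from .simulate import ScanBundle, SyntheticDataset
from .types import CensorMask, CensorMetric, MotionSummary, ScanRecord

__all__ = ["ScanResult", "ConditionResult", "process_scan", "process_dataset", "load_scan_bundles"]

logger = logging.getLogger(__name__)

MIN_RETAINED_FRAMES = 40


@dataclass
class ScanResult:
    record: ScanRecord
    summary: MotionSummary
    clean: CleanSeries
    profile: FCProfile
    mask: CensorMask
    design: "object | None" = None  # NuisanceDesign used for cleaning
    fd: "object | None" = None  # FDTrace


@dataclass
class ConditionResult:
    """All scans surviving one censoring condition."""

    threshold_mm: float | None  # None = no censoring
    scans: list[ScanResult] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def records(self) -> list[ScanRecord]:
        return [s.record for s in self.scans]

    @property
    def summaries(self) -> list[MotionSummary]:
        return [s.summary for s in self.scans]

    @property
    def profiles(self) -> list[FCProfile]:
        return [s.profile for s in self.scans]


def process_scan(
    bundle: ScanBundle,
    threshold_mm: float | None,
    motion_set: int = 12,
    radius_mm: float = 35.0,
    band_hz: tuple[float, float] = (0.01, 0.1),
    n_tissue_pcs: int = 3,
    min_retained: int = MIN_RETAINED_FRAMES,
    corrected_z: bool = True,
) -> ScanResult:
    """Censor, clean, and connect a single scan; raises on exclusion."""
    fd = compute_fd(bundle.motion, radius_mm)
    if threshold_mm is None:
        mask = CensorMask(
            keep=np.ones(fd.frames, dtype=bool),
            threshold_mm=float("inf"),
            metric=CensorMetric.FD,
        )
    else:
        mask = make_censor_mask(fd, threshold_mm)
    if mask.n_retained < min_retained:
        raise RankDeficientError(
            f"{bundle.record.scan_id}: {mask.n_retained} retained frames "
            f"< minimum {min_retained}"
        )
    summary = summarize_motion(fd, mask)
    design = build_design(
        bundle.motion,
        motion_set=motion_set,
        tissue_signals=bundle.tissue_signals,
        n_tissue_pcs=n_tissue_pcs,
        band_hz=band_hz,
        radius_mm=radius_mm,
    )
    clean = clean_timeseries(bundle.bold, design, mask)
    fc = compute_fc(clean, corrected=corrected_z)
    return ScanResult(
        record=bundle.record,
        summary=summary,
        clean=clean,
        profile=fc_profile(fc),
        mask=mask,
        design=design,
        fd=fd,
    )


def process_dataset(
    dataset: SyntheticDataset | list[ScanBundle],
    threshold_mm: float | None,
    **kwargs,
) -> ConditionResult:
    """Run :func:`process_scan` over a dataset, excluding failing scans."""
    bundles = dataset.scans if isinstance(dataset, SyntheticDataset) else dataset
    out = ConditionResult(threshold_mm=threshold_mm)
    for bundle in bundles:
        try:
            out.scans.append(process_scan(bundle, threshold_mm, **kwargs))
        except (RankDeficientError, ValueError) as exc:
            logger.info("excluding %s: %s", bundle.record.scan_id, exc)
            out.excluded.append(bundle.record.scan_id)
    return out


def load_scan_bundles(data_dir, tr_seconds: float = 3.0):
    """Read a written dataset directory back into scan bundles + geometry."""
    from pathlib import Path

    from . import io as fio

    data_dir = Path(data_dir)
    records = fio.read_scan_records(data_dir / "scans.tsv")
    geometry = fio.read_roi_geometry(data_dir / "centroids.tsv")
    bundles = []
    for rec in records:
        motion = fio.read_motion_trace(
            data_dir / f"{rec.scan_id}_motion.par", tr_seconds
        )
        bold = fio.read_roi_timeseries(data_dir / f"{rec.scan_id}_bold.tsv", tr_seconds)
        tissue = np.loadtxt(data_dir / f"{rec.scan_id}_tissue.tsv", ndmin=2)
        bundles.append(
            ScanBundle(record=rec, motion=motion, bold=bold, tissue_signals=tissue)
        )
    return bundles, geometry
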