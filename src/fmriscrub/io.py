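"""Readers and writers for the formats the pipeline touches.

Tabular data is TSV with a header row; reports are JSON; volumes and
masks are NIfTI. Every reader validates enough structure to produce a
useful error (naming the offending line/cell) instead of propagating a
numpy cast failure.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import MotionTrace, ROIGeometry, ROITimeSeries, ScanRecord, VolumeSeries

__all__ = [
    "ParseError",
    "read_motion_trace",
    "write_motion_trace",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_volume_series",
    "write_volume_series",
    "read_scan_records",
    "write_scan_records",
    "read_roi_geometry",
    "write_roi_geometry",
    "write_json",
    "read_json",
]

MOTION_COLUMNS = ("dx", "dy", "dz", "phi", "theta", "psi")


class ParseError(ValueError):
    """A structured input file could not be parsed."""


def read_motion_trace(
    path: str | Path,
    tr_seconds: float,
    column_order: tuple[str, ...] = MOTION_COLUMNS,
) -> MotionTrace:
    """Read a whitespace-delimited 6-column motion parameter file.

    ``column_order`` remaps tool dialects onto the canonical
    ``(dx, dy, dz, phi, theta, psi)`` order (translations mm,
    rotations radians).
    """
    path = Path(path)
    if sorted(column_order) != sorted(MOTION_COLUMNS):
        raise ValueError(f"column_order must be a permutation of {MOTION_COLUMNS}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if len(rows) < 2:
        raise ParseError(f"{path}: motion trace requires >= 2 frames, got {len(rows)}")
    raw = np.asarray(rows, dtype=float)
    order = [column_order.index(c) for c in MOTION_COLUMNS]
    return MotionTrace(params=raw[:, order], tr_seconds=tr_seconds)


def write_motion_trace(path: str | Path, trace: MotionTrace) -> None:
    np.savetxt(path, trace.params, fmt="%.10g", delimiter="\t")


def read_roi_timeseries(path: str | Path, tr_seconds: float = 3.0) -> ROITimeSeries:
    """Read a TSV of ROI time series: header of ROI ids, numeric body."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed TSV ({exc})") from exc
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in range(df.shape[0]) for c in range(df.shape[1])
            if pd.isna(df.iat[r, c])
        )
        raise ParseError(
            f"{path}: missing value at data row {row + 1}, column {df.columns[col]!r}"
        )
    try:
        data = np.asarray([[float(v) for v in row] for row in df.to_numpy()])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return ROITimeSeries(data=data, roi_ids=list(df.columns), tr_seconds=tr_seconds)


def write_roi_timeseries(path: str | Path, ts: ROITimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=ts.roi_ids)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_volume_series(
    path: str | Path, mask_paths: dict[str, str | Path] | None = None
) -> VolumeSeries:
    """Read a 4-D NIfTI plus named 3-D mask images on the same grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ParseError(f"{path}: expected a 4-D image, got shape {data.shape}")
    if data.shape[3] < 2:
        raise ParseError(f"{path}: volume series requires >= 2 frames")
    masks: dict[str, np.ndarray] = {}
    for name, mpath in (mask_paths or {}).items():
        mimg = nib.load(str(mpath))
        mdata = np.asarray(mimg.get_fdata())
        if mdata.shape != data.shape[:3]:
            raise ParseError(
                f"mask {name!r} ({mpath}): shape {mdata.shape} does not match "
                f"image spatial shape {data.shape[:3]}"
            )
        if not np.allclose(mimg.affine, img.affine, atol=1e-4):
            raise ParseError(f"mask {name!r} ({mpath}): affine differs from image")
        masks[name] = mdata > 0
    return VolumeSeries(data=data, masks=masks, affine=np.asarray(img.affine))


def write_volume_series(path: str | Path, vols: VolumeSeries, mask_dir: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(vols.data, vols.affine), str(path))
    if mask_dir is not None:
        mask_dir = Path(mask_dir)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for name, mask in vols.masks.items():
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), vols.affine),
                str(mask_dir / f"mask_{name}.nii"),
            )


def read_scan_records(path: str | Path) -> list[ScanRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"scan_id", "ga_weeks", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ScanRecord(
                scan_id=str(row["scan_id"]),
                ga_weeks=float(row["ga_weeks"]),
                sex=str(row["sex"]),
                subject_id=str(row.get("subject_id", row["scan_id"])),
            )
        )
    return records


def write_scan_records(path: str | Path, records: list[ScanRecord]) -> None:
    df = pd.DataFrame(
        {
            "scan_id": [r.scan_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "ga_weeks": [r.ga_weeks for r in records],
            "sex": [r.sex for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_roi_geometry(path: str | Path) -> ROIGeometry:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing centroid column {col!r}")
    return ROIGeometry(centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float))


def write_roi_geometry(path: str | Path, geom: ROIGeometry, roi_ids: list[str] | None = None) -> None:
    n = geom.n_roi
    df = pd.DataFrame(geom.centroids, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "roi_id", roi_ids if roi_ids is not None else [f"roi{i:03d}" for i in range(n)])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
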