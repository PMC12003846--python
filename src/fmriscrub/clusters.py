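"""Seed-based voxel maps, group t-statistics, and cluster-extent thresholding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .types import MotionSummary, VolumeSeries

__all__ = [
    "StatMap",
    "ClusterResult",
    "seed_map",
    "group_ttest",
    "cluster_threshold",
    "motion_subgroups",
]

Z_R_CAP = 1.0 - 1e-7
T_CAP = 1e6

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """3-D statistic map with degrees of freedom and analysis mask."""

    values: np.ndarray
    df: int
    mask: np.ndarray
    pvals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.mask.shape != self.values.shape:
            raise ValueError("values must be 3-D with a matching mask")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite statistic inside mask")


@dataclass
class ClusterResult:
    """Connected suprathreshold components surviving the extent cut."""

    labels: np.ndarray
    sizes: list[int] = field(default_factory=list)
    n_clusters: int = 0
    frac_significant: float = 0.0  # percent of mask voxels in surviving clusters
    connectivity: int = 6
    min_cluster: int = 40


def seed_map(vols: VolumeSeries, seed_mask: np.ndarray, mask_name: str = "brain") -> StatMap:
    """Voxelwise Fisher-z correlation with the mean seed time course."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != vols.data.shape[:3]:
        raise ValueError("seed mask grid differs from volume grid")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    brain = vols.masks.get(mask_name, np.ones(vols.data.shape[:3], dtype=bool))
    if np.any(seed_mask & ~brain):
        raise ValueError("seed mask extends outside the analysis mask")
    seed_course = vols.data[seed_mask].mean(axis=0)
    if seed_course.std() == 0:
        raise ValueError("seed time course has zero variance")
    n = vols.frames
    flat = vols.data[brain]  # (n_voxels, frames)
    sc = seed_course - seed_course.mean()
    fc = flat - flat.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum() * (fc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (fc @ sc) / np.where(denom > 0, denom, 1.0), 0.0)
    z = np.arctanh(np.clip(r, -Z_R_CAP, Z_R_CAP))
    out = np.zeros(vols.data.shape[:3])
    out[brain] = z
    return StatMap(values=out, df=n - 2, mask=brain)


def group_ttest(
    maps: list[StatMap], groups: np.ndarray | None = None, equal_var: bool = True
) -> StatMap:
    """Voxelwise one-sample (vs 0) or two-sample t over subject maps.

    Zero-variance voxels get t=0, p=1 (flagged by p exactly 1). The
    two-sample test is pooled-variance by default (``equal_var=False``
    switches to Welch).
    """
    if not maps:
        raise ValueError("no maps supplied")
    mask = maps[0].mask
    data = np.stack([m.values for m in maps])  # (n_maps, x, y, z)
    if groups is None:
        if len(maps) < 3:
            raise ValueError("one-sample t-test needs >= 3 maps")
        n = len(maps)
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * np.sqrt(n), 0.0)
        df = n - 1
    else:
        groups = np.asarray(groups)
        a, b = data[groups == 1], data[groups == 0]
        if len(a) < 3 or len(b) < 3:
            raise ValueError("two-sample t-test needs >= 3 maps per group")
        t_arr, _ = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        t = np.nan_to_num(t_arr, nan=0.0, posinf=T_CAP, neginf=-T_CAP)
        df = (len(a) + len(b) - 2) if equal_var else max(3, len(a) + len(b) - 2)
    t = np.clip(t, -T_CAP, T_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(t == 0, 1.0, p)
    return StatMap(values=t, df=df, mask=mask, pvals=p)


def cluster_threshold(
    stat: StatMap,
    p_voxel: float = 0.01,
    min_cluster: int = 40,
    connectivity: int = 6,
) -> ClusterResult:
    """Cluster-extent threshold: binarize at p < p_voxel, keep components
    with at least ``min_cluster`` voxels under the chosen neighborhood."""
    if stat.pvals is None:
        raise ValueError("stat map carries no p-values")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    supra = (stat.pvals < p_voxel) & stat.mask
    labels_all, n_all = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    labels = np.zeros_like(labels_all)
    sizes: list[int] = []
    next_id = 0
    for lab in range(1, n_all + 1):
        size = int((labels_all == lab).sum())
        if size >= min_cluster:
            next_id += 1
            labels[labels_all == lab] = next_id
            sizes.append(size)
    n_mask = int(stat.mask.sum())
    frac = 100.0 * sum(sizes) / n_mask if n_mask else 0.0
    return ClusterResult(
        labels=labels,
        sizes=sizes,
        n_clusters=next_id,
        frac_significant=frac,
        connectivity=connectivity,
        min_cluster=min_cluster,
    )


def motion_subgroups(
    summaries: dict[str, MotionSummary], fraction: float = 0.10
) -> tuple[list[str], list[str]]:
    """Lowest/highest-FD_ave scan ids, each ``floor(fraction * N)`` scans.

    Ties at the boundary are broken by scan id for determinism.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(summaries)
    k = int(np.floor(fraction * n))
    if k < 3:
        raise ValueError(f"subgroup size {k} < 3; t-test infeasible")
    ranked = sorted(summaries.items(), key=lambda kv: (kv[1].fd_ave, kv[0]))
    low = [sid for sid, _ in ranked[:k]]
    high = [sid for sid, _ in ranked[-k:]]
    return low, high
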