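"""Self-contained evaluation experiments on synthetic ground truth.

These drive both the acceptance test suite and the acceptance report:
null-calibration studies, type-I error of the corrected Fisher z on
AR(1) nulls, and the direction-of-effect recovery experiment that
mirrors the study's main findings (motion predictability before vs
after censoring, sex decodability, distance-dependent FC bias, and the
voxel-level high-vs-low-motion contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .censoring import make_censor_mask
from .clusters import cluster_threshold, group_ttest, motion_subgroups, seed_map
from .connectivity import (
    FCProfile,
    compute_fc,
    distance_difference,
    fd_bold_association,
    fd_fc_association,
    summarize_fd_bold,
)
from .metrics import compute_fd
from .pipeline import process_dataset
from .prediction import PredictionSpec, run_prediction
from .simulate import SimulationConfig, simulate_dataset, simulate_volumes
from .types import VolumeSeries

__all__ = [
    "null_calibration",
    "ar1_type_one_error",
    "DirectionOfEffect",
    "direction_of_effect",
]


def null_calibration(
    n_seeds: int = 50,
    n_scans: int = 12,
    n_roi: int = 20,
    frames: int = 120,
    base_seed: int = 0,
) -> dict[str, float]:
    """Pooled p<0.05 fractions of both motion-association screens on
    artifact-free synthetic data (should be ~0.05)."""
    pvals_bold: list[np.ndarray] = []
    fracs_fc: list[float] = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_scans=n_scans, n_roi=n_roi, frames=frames,
            seed=base_seed + i,
            artifact_gain=0.0, ga_effect=0.0, sex_effect=0.0,
        )
        ds = simulate_dataset(cfg)
        cond = process_dataset(ds, None)
        tables = []
        for s in cond.scans:
            tables.append(
                fd_bold_association(
                    s.clean, s.fd, scan_id=s.record.scan_id,
                    design_matrix=s.design.matrix,
                )
            )
        pooled = summarize_fd_bold(tables)
        pvals_bold.append(pooled.table["p_unc"].to_numpy())
        fc_res = fd_fc_association(cond.profiles, cond.summaries)
        fracs_fc.append(fc_res.frac_p05)
    all_bold = np.concatenate(pvals_bold)
    return {
        "fd_bold_frac_p05": float((all_bold < 0.05).mean()),
        "fd_fc_frac_p05": float(np.mean(fracs_fc)),
        "n_bold_tests": int(all_bold.size),
    }


def ar1_type_one_error(
    n_pairs: int = 1000,
    n_frames: int = 200,
    phi: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error of corrected vs naive Fisher z on AR(1) null pairs."""
    from .censoring import CleanSeries

    rng = np.random.default_rng(seed)
    zcrit = stats.norm.isf(alpha / 2.0)
    rej_c = rej_n = 0
    for _ in range(n_pairs):
        e = rng.standard_normal((n_frames, 2))
        x = np.empty((n_frames, 2))
        x[0] = e[0]
        for t in range(1, n_frames):
            x[t] = phi * x[t - 1] + e[t]
        clean = CleanSeries(
            data=x,
            retained_index=np.arange(n_frames),
            dof=n_frames - 1,
            roi_ids=["a", "b"],
            tr_seconds=3.0,
        )
        rej_c += abs(compute_fc(clean, corrected=True).z[0, 1]) > zcrit
        rej_n += abs(compute_fc(clean, corrected=False).z[0, 1]) > zcrit
    return {
        "corrected_type1": rej_c / n_pairs,
        "naive_type1": rej_n / n_pairs,
        "alpha": alpha,
    }


@dataclass
class DirectionOfEffect:
    """Per-seed outcomes of the censoring-benefit experiment."""

    seeds: list[int] = field(default_factory=list)
    fd_perf_unc: list[np.ndarray] = field(default_factory=list)
    fd_null_unc: list[np.ndarray] = field(default_factory=list)
    fd_perf_cen: list[np.ndarray] = field(default_factory=list)
    fd_null_cen: list[np.ndarray] = field(default_factory=list)
    fd_p_unc: list[float] = field(default_factory=list)
    fd_p_cen: list[float] = field(default_factory=list)
    sex_acc_unc: list[float] = field(default_factory=list)
    sex_acc_cen: list[float] = field(default_factory=list)
    dist_diff_r: list[float] = field(default_factory=list)
    clusters_unc: list[int] = field(default_factory=list)
    clusters_cen: list[int] = field(default_factory=list)
    frac_voxels_unc: list[float] = field(default_factory=list)
    frac_voxels_cen: list[float] = field(default_factory=list)

    def pooled_fd_p(self, censored: bool) -> float:
        """One-tailed p (original > null) pooling repeats over all seeds."""
        perf = np.concatenate(self.fd_perf_cen if censored else self.fd_perf_unc)
        null = np.concatenate(self.fd_null_cen if censored else self.fd_null_unc)
        t, p_two = stats.ttest_ind(perf, null, equal_var=False)
        return float(p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0)

    def fd_significant_fraction(self, censored: bool, alpha: float = 0.05) -> float:
        """Fraction of seeds whose permutation test rejects at ``alpha``."""
        ps = np.asarray(self.fd_p_cen if censored else self.fd_p_unc)
        return float((ps < alpha).mean())

    def sex_paired_p(self) -> float:
        """One-tailed paired t: censored accuracy > uncensored, across seeds."""
        t, p_two = stats.ttest_rel(self.sex_acc_cen, self.sex_acc_unc)
        return float(p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0)


def _seed_maps_for_condition(
    cfg: SimulationConfig, ds, threshold: float | None
) -> dict[str, object]:
    maps = {}
    for i, b in enumerate(ds.scans):
        vols = simulate_volumes(cfg, b.motion, i)
        if threshold is not None:
            fd = compute_fd(b.motion, cfg.radius_mm)
            keep = make_censor_mask(fd, threshold).keep
            if keep.sum() < 10:
                continue
            vols = VolumeSeries(
                data=vols.data[..., keep], masks=vols.masks, affine=vols.affine
            )
        maps[b.record.scan_id] = seed_map(vols, vols.masks["seed"])
    return maps


def _cluster_contrast(cond, maps, fraction=0.10, min_cluster=10):
    sums = {s.record.scan_id: s.summary for s in cond.scans if s.record.scan_id in maps}
    low, high = motion_subgroups(sums, fraction)
    stat = group_ttest(
        [maps[sid] for sid in high] + [maps[sid] for sid in low],
        groups=np.array([1] * len(high) + [0] * len(low)),
    )
    return cluster_threshold(stat, p_voxel=0.01, min_cluster=min_cluster)


def direction_of_effect(
    n_seeds: int = 20,
    n_scans: int = 60,
    n_roi: int = 50,
    frames: int = 144,
    threshold: float = 1.5,
    base_seed: int = 0,
    n_repeats: int = 10,
    n_permutations: int = 15,
    with_volumes: bool = True,
) -> DirectionOfEffect:
    """Run the full censoring-benefit experiment over seeded datasets."""
    out = DirectionOfEffect()
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SimulationConfig(n_scans=n_scans, n_roi=n_roi, frames=frames, seed=seed)
        ds = simulate_dataset(cfg)
        unc = process_dataset(ds, None)
        cen = process_dataset(ds, threshold)
        out.seeds.append(seed)

        # (a) FD_ave predictability before/after censoring
        for cond, perf_list, null_list, p_list in [
            (unc, out.fd_perf_unc, out.fd_null_unc, out.fd_p_unc),
            (cen, out.fd_perf_cen, out.fd_null_cen, out.fd_p_cen),
        ]:
            spec = PredictionSpec(
                target="fd_ave", n_repeats=n_repeats,
                n_permutations=n_permutations, seed=seed + 10_000,
            )
            res = run_prediction(cond.profiles, cond.records, cond.summaries, spec)
            perf_list.append(res.per_repeat)
            null_list.append(res.null_perfs)
            p_list.append(res.p_value)

        # (b) sex decodability
        for cond, acc_list in [(unc, out.sex_acc_unc), (cen, out.sex_acc_cen)]:
            spec = PredictionSpec(
                target="sex", n_repeats=n_repeats,
                n_permutations=2, seed=seed + 20_000,
            )
            res = run_prediction(
                cond.profiles, cond.records, cond.summaries, spec, run_null=False
            )
            acc_list.append(res.mean)

        # (c) distance dependence of the censored-minus-uncensored profile
        shared = {s.record.scan_id for s in unc.scans} & {
            s.record.scan_id for s in cen.scans
        }
        prof_u = np.mean(
            [s.profile.values for s in unc.scans if s.record.scan_id in shared], axis=0
        )
        prof_c = np.mean(
            [s.profile.values for s in cen.scans if s.record.scan_id in shared], axis=0
        )
        pairs = unc.scans[0].profile.pair_index
        _, r, _ = distance_difference(
            FCProfile(values=prof_c, pair_index=pairs),
            FCProfile(values=prof_u, pair_index=pairs),
            ds.geometry,
        )
        out.dist_diff_r.append(r)

        # (d) voxel-level high-vs-low-motion contrast
        if with_volumes:
            maps_u = _seed_maps_for_condition(cfg, ds, None)
            maps_c = _seed_maps_for_condition(cfg, ds, threshold)
            clu_u = _cluster_contrast(unc, maps_u)
            clu_c = _cluster_contrast(cen, maps_c)
            out.clusters_unc.append(clu_u.n_clusters)
            out.clusters_cen.append(clu_c.n_clusters)
            out.frac_voxels_unc.append(clu_u.frac_significant)
            out.frac_voxels_cen.append(clu_c.frac_significant)
    return out
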