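"""Functional-connectivity construction and motion-association screens.

Fisher z-scores are variance-corrected for serial autocorrelation so
that scans with different censored lengths remain comparable: the
variance of Pearson's r under dependence is estimated from tapered
autocovariance products, yielding a per-pair effective sample size
``n_eff`` and ``z = atanh(r) * sqrt(n_eff - 3)``. The naive (``n``)
variant stays available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .censoring import CleanSeries
from .types import FDTrace, MotionSummary, ROIGeometry

__all__ = [
    "FCMatrix",
    "FCProfile",
    "AssociationResult",
    "compute_fc",
    "effective_dof",
    "fc_profile",
    "profile_to_matrix",
    "upper_triangle_pairs",
    "fd_bold_association",
    "summarize_fd_bold",
    "fd_fc_association",
    "distance_analysis",
    "distance_difference",
    "bh_fdr",
]

Z_R_CAP = 1.0 - 1e-7  # |r| cap before atanh on degenerate inputs
MIN_EFFECTIVE_DOF = 4.0


@dataclass
class FCMatrix:
    """ROI x ROI connectivity: Pearson r, corrected Fisher z, per-pair dof."""

    r: np.ndarray
    z: np.ndarray
    dof_effective: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r", "z", "dof_effective"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise ValueError(f"{name} must be square")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")

    @property
    def n_roi(self) -> int:
        return self.r.shape[0]


@dataclass
class FCProfile:
    """Row-major upper-triangle vectorization of an FC matrix."""

    values: np.ndarray
    pair_index: np.ndarray  # (n_edges, 2) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        if self.values.size != self.pair_index.shape[0]:
            raise ValueError("values and pair_index lengths differ")
        if np.any(self.pair_index[:, 0] >= self.pair_index[:, 1]):
            raise ValueError("pair_index must be strictly upper-triangular")

    @property
    def n_edges(self) -> int:
        return self.values.size


@dataclass
class AssociationResult:
    """Per-unit correlations with significance summaries."""

    table: pd.DataFrame  # columns: unit keys, r, r2, p_unc, p_fdr, significant_fdr
    frac_p05: float
    frac_p01: float
    frac_fdr05: float
    n_tests: int
    n_skipped: int = 0


def upper_triangle_pairs(n_roi: int) -> np.ndarray:
    """(i, j) pairs of the strict upper triangle in row-major order."""
    iu = np.triu_indices(n_roi, k=1)
    return np.column_stack(iu)


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations (biased, 1/n) of each column, lags 1..max_lag."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    denom = (xc**2).sum(axis=0)
    denom = np.where(denom > 0, denom, 1.0)
    ac = np.empty((max_lag, x.shape[1]))
    for k in range(1, max_lag + 1):
        ac[k - 1] = (xc[k:] * xc[:-k]).sum(axis=0) / denom
    return ac


def effective_dof(data: np.ndarray) -> np.ndarray:
    """Pairwise effective sample size correcting for autocorrelation.

    Under dependence, var(r_ij) ~ (1/n) * sum_k rho_i(k) * rho_j(k); the
    lag sum is truncated at ~4*sqrt(n) and Tukey-tapered. The implied
    ``n_eff = n / factor`` is floored at MIN_EFFECTIVE_DOF.
    """
    n, n_roi = data.shape
    max_lag = min(n - 2, max(1, int(round(4.0 * np.sqrt(n)))))
    ac = _autocorr(data, max_lag)  # (max_lag, n_roi)
    lags = np.arange(1, max_lag + 1)
    taper = 0.5 * (1.0 + np.cos(np.pi * lags / (max_lag + 1)))
    weighted = ac * taper[:, None]
    factor = 1.0 + 2.0 * (weighted.T @ ac)  # (n_roi, n_roi), asymmetric in taper
    factor = 0.5 * (factor + factor.T)
    factor = np.maximum(factor, 1e-3)
    n_eff = n / factor
    return np.maximum(n_eff, MIN_EFFECTIVE_DOF)


def compute_fc(clean: CleanSeries, corrected: bool = True) -> FCMatrix:
    """Pairwise Pearson FC with autocorrelation-corrected Fisher z."""
    data = clean.data
    n, n_roi = data.shape
    if n < 10:
        raise ValueError(f"need >= 10 retained frames, got {n}")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = [clean.roi_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI(s): {bad}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    if corrected:
        dof = effective_dof(data)
    else:
        dof = np.full((n_roi, n_roi), float(n))
    r_capped = np.clip(r, -Z_R_CAP, Z_R_CAP)
    z = np.arctanh(r_capped) * np.sqrt(np.maximum(dof - 3.0, 1.0))
    np.fill_diagonal(z, 0.0)
    return FCMatrix(r=r, z=z, dof_effective=dof)


def fc_profile(fc: FCMatrix | np.ndarray, use: str = "z") -> FCProfile:
    """Vectorize the strict upper triangle (row-major) of an FC matrix."""
    mat = getattr(fc, use) if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    n_roi = mat.shape[0]
    pairs = upper_triangle_pairs(n_roi)
    return FCProfile(values=mat[pairs[:, 0], pairs[:, 1]], pair_index=pairs)


def profile_to_matrix(profile: FCProfile, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`fc_profile` (symmetric fill)."""
    n_roi = int(profile.pair_index.max()) + 1
    mat = np.full((n_roi, n_roi), diag)
    i, j = profile.pair_index[:, 0], profile.pair_index[:, 1]
    mat[i, j] = profile.values
    mat[j, i] = profile.values
    return mat


def _pearson_vec(
    x: np.ndarray, Y: np.ndarray, df: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of a vector against each column of Y.

    ``df`` overrides the default n - 2 (partial-correlation use)."""
    n = x.size
    if df is None:
        df = n - 2
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ Yc) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return r, p


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below)[-1])
        reject[order[: k + 1]] = True
    return reject


def _summarize(table: pd.DataFrame, q: float = 0.05) -> AssociationResult:
    p = table["p_unc"].to_numpy()
    rej = bh_fdr(p, q) if p.size else np.zeros(0, dtype=bool)
    table = table.assign(significant_fdr=rej)
    n = max(p.size, 1)
    return AssociationResult(
        table=table,
        frac_p05=float((p < 0.05).sum()) / n,
        frac_p01=float((p < 0.01).sum()) / n,
        frac_fdr05=float(rej.sum()) / n,
        n_tests=int(p.size),
    )


def fd_bold_association(
    clean: CleanSeries,
    fd: FDTrace,
    fixed_length: int | None = None,
    scan_id: str = "",
    design_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI correlation between FD and cleaned BOLD.

    FD is restricted to the retained frames of ``clean``. When the
    nuisance design is supplied, FD is residualized on the same design
    rows and the partial-correlation degrees of freedom
    (retained - rank - 1) are used, so the test is calibrated against
    residuals that live in the post-regression subspace; without a
    design, plain Pearson with n - 2 df is computed. With
    ``fixed_length`` set, only the first that many retained frames are
    used (data-length control); a scan with fewer raises ValueError so
    the caller can exclude it.
    """
    idx = clean.retained_index
    fd_r = fd.fd[idx]
    data = clean.data
    X = design_matrix[idx] if design_matrix is not None else None
    if fixed_length is not None:
        if clean.n_retained < fixed_length:
            raise ValueError(
                f"scan has {clean.n_retained} retained frames < fixed_length {fixed_length}"
            )
        fd_r = fd_r[:fixed_length]
        data = data[:fixed_length]
        if X is not None:
            X = X[:fixed_length]
    if fd_r.size < 10:
        raise ValueError(f"<10 aligned frames ({fd_r.size}); scan excluded")
    if X is not None:
        beta, *_ = np.linalg.lstsq(X, fd_r, rcond=None)
        fd_r = fd_r - X @ beta
        df = fd_r.size - int(np.linalg.matrix_rank(X)) - 1
        if df < 2:
            raise ValueError("insufficient dof for partial correlation")
        r, p = _pearson_vec(fd_r, data, df=df)
    else:
        r, p = _pearson_vec(fd_r, data)
    return pd.DataFrame(
        {
            "scan_id": scan_id,
            "roi": clean.roi_ids,
            "r": r,
            "r2": r**2,
            "p_unc": p,
        }
    )


def summarize_fd_bold(tables: list[pd.DataFrame], q: float = 0.05) -> AssociationResult:
    """Pool per-scan FD-BOLD tables into one scan x ROI family."""
    pooled = pd.concat(tables, ignore_index=True)
    return _summarize(pooled, q)


def fd_fc_association(
    profiles: list[FCProfile],
    summaries: list[MotionSummary],
    which: str = "fd_ave",
) -> AssociationResult:
    """Across-scan correlation of each edge's strength with FD summary."""
    if len(profiles) < 10:
        raise ValueError("need >= 10 scans")
    if len(profiles) != len(summaries):
        raise ValueError("profiles and summaries must align")
    target = np.array([getattr(s, which) for s in summaries])
    values = np.vstack([p.values for p in profiles])  # (n_scans, n_edges)
    sd = values.std(axis=0)
    ok = sd > 0
    r = np.full(values.shape[1], np.nan)
    p = np.full(values.shape[1], np.nan)
    if ok.any():
        r[ok], p[ok] = _pearson_vec(target, values[:, ok])
    pairs = profiles[0].pair_index
    table = pd.DataFrame(
        {
            "roi_i": pairs[:, 0],
            "roi_j": pairs[:, 1],
            "r": r,
            "r2": r**2,
            "p_unc": p,
        }
    )
    result = _summarize(table.loc[ok].reset_index(drop=True))
    result.n_skipped = int((~ok).sum())
    return result


def distance_analysis(
    mean_profile: FCProfile, geometry: ROIGeometry
) -> tuple[pd.DataFrame, float, float]:
    """Edge FC strength vs centroid distance: table, Pearson r, p."""
    pairs = mean_profile.pair_index
    if pairs.max() >= geometry.n_roi:
        raise ValueError("geometry is missing centroids for some ROIs")
    dmat = geometry.pairwise_distances()
    dist = dmat[pairs[:, 0], pairs[:, 1]]
    if np.std(mean_profile.values) == 0 or np.std(dist) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(dist, mean_profile.values)
    table = pd.DataFrame(
        {
            "roi_i": pairs[:, 0],
            "roi_j": pairs[:, 1],
            "distance_mm": dist,
            "fc_strength": mean_profile.values,
        }
    )
    return table, float(r), float(p)


def distance_difference(
    profile_a: FCProfile, profile_b: FCProfile, geometry: ROIGeometry
) -> tuple[pd.DataFrame, float, float]:
    """Per-edge difference (a - b) vs distance: table, Pearson r, p."""
    if profile_a.n_edges != profile_b.n_edges:
        raise ValueError("profiles have different edge counts")
    diff = FCProfile(
        values=profile_a.values - profile_b.values,
        pair_index=profile_a.pair_index,
    )
    table, r, p = distance_analysis(diff, geometry)
    return table.rename(columns={"fc_strength": "fc_difference"}), r, p
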