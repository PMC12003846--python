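"""Connectome-based prediction of motion and neurobiological targets.

FC profiles are the feature vectors; each repeat draws a random 80/20
holdout split (stratified on the label for classification), selects
features on the training scans only, standardizes with training-set
statistics, and fits a linear-kernel SVR/SVC. Continuous performance is
the Fisher z of the held-out predicted-vs-actual Pearson correlation;
classification performance is percent correct. Significance comes from
a permutation null built with the identical procedure on shuffled
targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC, SVR

from .connectivity import FCProfile
from .types import MotionSummary, ScanRecord

__all__ = [
    "PredictionSpec",
    "PredictionResult",
    "select_features",
    "run_prediction",
    "permutation_test",
    "compare_conditions",
    "extract_target",
]

logger = logging.getLogger(__name__)

CONTINUOUS_TARGETS = ("fd_ave", "fd_max", "ga")
BINARY_TARGETS = ("sex",)


@dataclass
class PredictionSpec:
    target: str  # fd_ave | fd_max | ga | sex
    selection_alpha: float = 0.05
    n_repeats: int = 50
    test_fraction: float = 0.20
    n_permutations: int = 50
    repeats_per_permutation: int = 1
    seed: int = 0
    use_kfold: bool = False  # true 5-fold option instead of repeated holdout

    def __post_init__(self) -> None:
        if self.target not in CONTINUOUS_TARGETS + BINARY_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1 or self.n_permutations < 1:
            raise ValueError("n_repeats and n_permutations must be >= 1")

    @property
    def is_binary(self) -> bool:
        return self.target in BINARY_TARGETS


@dataclass
class PredictionResult:
    target: str
    per_repeat: np.ndarray  # Fisher z (continuous) or percent correct (binary)
    null_perfs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    p_value: float = float("nan")
    selected_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_repeat, ddof=1)) if self.per_repeat.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "mean": self.mean,
            "sd": self.sd,
            "per_repeat": self.per_repeat.tolist(),
            "null_perfs": self.null_perfs.tolist(),
            "p_value": self.p_value,
            "selected_fraction_mean": (
                float(self.selected_fraction.mean()) if self.selected_fraction.size else None
            ),
        }


def extract_target(
    records: list[ScanRecord], summaries: list[MotionSummary], target: str
) -> np.ndarray:
    """Target vector for a prediction task (sex encoded 0/1, F=0, M=1)."""
    if target == "ga":
        return np.array([r.ga_weeks for r in records], dtype=float)
    if target == "sex":
        return np.array([1.0 if r.sex == "M" else 0.0 for r in records])
    if target in ("fd_ave", "fd_max"):
        return np.array([getattr(s, target) for s in summaries], dtype=float)
    raise ValueError(f"unknown target {target!r}")


def select_features(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    binary: bool,
    alpha: float = 0.05,
) -> np.ndarray:
    """Edge indices significantly associated with the training target.

    Continuous targets use two-sided Pearson p < alpha; binary targets a
    two-sample pooled-variance t-test. If nothing survives, the single
    smallest-p edge is selected and a warning logged.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0)
    ok = sd > 0
    p = np.ones(X.shape[1])
    if binary:
        g0, g1 = X[y == 0], X[y == 1]
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError("each class needs >= 2 training scans")
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p_all = stats.ttest_ind(g0, g1, axis=0, equal_var=True)
        p[ok] = np.nan_to_num(p_all, nan=1.0)[ok]
    else:
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((yc**2).sum() * (Xc**2).sum(axis=0))
        r = np.zeros(X.shape[1])
        r[ok] = (yc @ Xc)[ok] / denom[ok]
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)[ok]
    selected = np.flatnonzero(p < alpha)
    if selected.size == 0:
        selected = np.array([int(np.argmin(p))])
        logger.warning("no edge survived selection at alpha=%g; using smallest-p edge", alpha)
    return selected


def _fit_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    binary: bool,
    alpha: float,
) -> tuple[float, float] | None:
    """One split: select, standardize, fit, score. None if degenerate."""
    if np.std(y_test) == 0 or np.std(y_train) == 0:
        return None
    sel = select_features(X_train, y_train, binary, alpha)
    mu = X_train[:, sel].mean(axis=0)
    sd = X_train[:, sel].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr = (X_train[:, sel] - mu) / sd
    Xte = (X_test[:, sel] - mu) / sd
    if binary:
        model = SVC(kernel="linear", C=1.0)
        model.fit(Xtr, y_train)
        perf = 100.0 * float((model.predict(Xte) == y_test).mean())
    else:
        eps = 0.1 * float(np.std(y_train, ddof=1))
        model = SVR(kernel="linear", C=1.0, epsilon=max(eps, 1e-12))
        model.fit(Xtr, y_train)
        pred = model.predict(Xte)
        if np.std(pred) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(y_test, pred)[0, 1])
        r = float(np.clip(r, -1 + 1e-7, 1 - 1e-7))
        perf = float(np.arctanh(r))
    return perf, sel.size / X_train.shape[1]


def _splits(
    n: int, y: np.ndarray, spec_binary: bool, test_fraction: float,
    n_repeats: int, rng: np.random.Generator, use_kfold: bool,
):
    """Yield (train_idx, test_idx) pairs for the requested scheme."""
    if use_kfold:
        for _ in range(max(1, n_repeats // 5)):
            perm = rng.permutation(n)
            folds = np.array_split(perm, 5)
            for f in folds:
                test = np.sort(f)
                train = np.setdiff1d(perm, f)
                yield train, test
        return
    n_test = max(1, int(round(test_fraction * n)))
    for _ in range(n_repeats):
        if spec_binary:
            test_parts = []
            for cls in np.unique(y):
                cls_idx = np.flatnonzero(y == cls)
                k = max(1, int(round(test_fraction * cls_idx.size)))
                test_parts.append(rng.choice(cls_idx, size=k, replace=False))
            test = np.sort(np.concatenate(test_parts))
        else:
            test = np.sort(rng.choice(n, size=n_test, replace=False))
        train = np.setdiff1d(np.arange(n), test)
        yield train, test


def _repeated_cv(
    features: np.ndarray,
    targets: np.ndarray,
    spec: PredictionSpec,
    rng: np.random.Generator,
    n_repeats: int,
) -> tuple[np.ndarray, np.ndarray]:
    perfs, fracs = [], []
    for train, test in _splits(
        features.shape[0], targets, spec.is_binary, spec.test_fraction,
        n_repeats, rng, spec.use_kfold,
    ):
        out = _fit_and_score(
            features[train], targets[train], features[test], targets[test],
            spec.is_binary, spec.selection_alpha,
        )
        if out is None:
            logger.info("degenerate split skipped (constant target)")
            continue
        perfs.append(out[0])
        fracs.append(out[1])
    return np.asarray(perfs), np.asarray(fracs)


def run_prediction(
    profiles: list[FCProfile],
    records: list[ScanRecord],
    summaries: list[MotionSummary],
    spec: PredictionSpec,
    run_null: bool = True,
) -> PredictionResult:
    """Repeated-holdout connectome prediction with a permutation null."""
    if len(profiles) < 20:
        raise ValueError("need >= 20 scans for prediction")
    features = np.vstack([p.values for p in profiles])
    targets = extract_target(records, summaries, spec.target)
    if np.any(~np.isfinite(targets)):
        raise ValueError("targets contain missing values")
    rng = np.random.default_rng(spec.seed)
    perfs, fracs = _repeated_cv(features, targets, spec, rng, spec.n_repeats)
    result = PredictionResult(
        target=spec.target, per_repeat=perfs, selected_fraction=fracs
    )
    if run_null:
        null, p = permutation_test(perfs, features, targets, spec, rng)
        result.null_perfs = null
        result.p_value = p
    return result


def permutation_test(
    original_perfs: np.ndarray,
    features: np.ndarray,
    targets: np.ndarray,
    spec: PredictionSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Null performances from target shuffling + one-tailed t-test p.

    Each permutation shuffles the targets once and reruns the identical
    CV procedure with ``spec.repeats_per_permutation`` repeats; p is the
    one-tailed two-sample t-test of original repeats > null values.
    """
    if spec.n_permutations < 2:
        raise ValueError("need >= 2 permutations")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    null_means = []
    for _ in range(spec.n_permutations):
        shuffled = rng.permutation(targets)
        perfs, _ = _repeated_cv(features, shuffled, spec, rng, spec.repeats_per_permutation)
        if perfs.size:
            null_means.append(float(perfs.mean()))
    null = np.asarray(null_means)
    t, p_two = stats.ttest_ind(original_perfs, null, equal_var=False)
    p = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return null, p


def compare_conditions(
    results: dict[str, PredictionResult],
) -> list[dict]:
    """Pairwise Welch t-tests between conditions, Bonferroni-corrected."""
    names = list(results)
    if len(names) < 2:
        raise ValueError("need >= 2 conditions")
    comparisons = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        xa, xb = results[a].per_repeat, results[b].per_repeat
        if np.std(xa) == 0 and np.std(xb) == 0:
            tied = float(np.mean(xa) == np.mean(xb))
            comparisons.append(
                {"a": a, "b": b, "t": 0.0, "p_unc": 1.0, "p_bonf": 1.0,
                 "note": "zero variance; exact tie" if tied else "zero variance"}
            )
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        comparisons.append(
            {"a": a, "b": b, "t": float(t), "p_unc": float(p),
             "p_bonf": float(min(1.0, p * m)), "note": ""}
        )
    return comparisons
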