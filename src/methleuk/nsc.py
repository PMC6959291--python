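"""Nearest shrunken centroids (NSC / "PAM") classifier for beta-value matrices.

The classifier compares, for every CpG i and class k, the class centroid
x̄_ik against the overall centroid x̄_i on a standardized scale,

    d_ik = (x̄_ik − x̄_i) / (m_k · (s_i + s0)),

with pooled within-class standard deviation s_i (denominator n − K), fudge
constant s0 = median_i s_i, and m_k = sqrt(1/n_k + 1/n).  Soft thresholding
at Δ,

    d'_ik = sign(d_ik) · max(0, |d_ik| − Δ),

moves the class centroids toward the overall centroid and zeroes out
uninformative CpGs, giving embedded feature selection.  Prediction uses the
Gaussian discriminant

    δ_k(x) = Σ_i (x_i − x̄'_ik)² / (s_i + s0)² − 2 log π_k ,

choosing the class minimizing δ_k; posteriors are proportional to
exp(−δ_k/2).  The threshold Δ is chosen by stratified 10-fold
cross-validation over a grid from 0 to max|d_ik|.

Threshold selection: the grid value with the fewest CV misclassifications
wins; among error ties the value with the highest held-out log posterior of
the true class wins; any remaining tie goes to the largest (sparsest) Δ.
The likelihood tie-break matters on strongly separated cohorts, where whole
ranges of Δ achieve zero CV error but only moderate shrinkage keeps every
informative CpG (see docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CentroidStats",
    "CentroidModel",
    "CVResult",
    "fit_centroids",
    "shrink",
    "predict",
    "cross_validate",
    "selected_features",
    "fit_cv",
]


@dataclass
class CentroidStats:
    """Sufficient statistics of the NSC fit (before shrinkage)."""

    classes: list
    cpg_ids: list
    class_centroids: np.ndarray  # (p, K)
    overall_centroid: np.ndarray  # (p,)
    pooled_sd: np.ndarray  # (p,)
    s0: float
    m_k: np.ndarray  # (K,)
    d: np.ndarray  # (p, K) standardized differences
    priors: np.ndarray  # (K,)
    class_sizes: np.ndarray  # (K,)
    n: int


@dataclass
class CentroidModel(CentroidStats):
    """A :class:`CentroidStats` plus a shrinkage threshold and its effects."""

    delta: float = 0.0
    d_shrunk: np.ndarray = field(default_factory=lambda: np.empty(0))
    shrunken_centroids: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "cpg_ids": list(self.cpg_ids),
            "class_centroids": self.class_centroids.tolist(),
            "overall_centroid": self.overall_centroid.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "priors": self.priors.tolist(),
            "class_sizes": self.class_sizes.tolist(),
            "n": self.n,
            "delta": self.delta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "CentroidModel":
        stats = CentroidStats(
            classes=obj["classes"],
            cpg_ids=obj["cpg_ids"],
            class_centroids=np.asarray(obj["class_centroids"], dtype=float),
            overall_centroid=np.asarray(obj["overall_centroid"], dtype=float),
            pooled_sd=np.asarray(obj["pooled_sd"], dtype=float),
            s0=float(obj["s0"]),
            m_k=np.asarray(obj["m_k"], dtype=float),
            d=np.empty(0),
            priors=np.asarray(obj["priors"], dtype=float),
            class_sizes=np.asarray(obj["class_sizes"], dtype=int),
            n=int(obj["n"]),
        )
        stats.d = _standardized_differences(stats)
        return shrink(stats, float(obj["delta"]))

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _standardized_differences(stats: CentroidStats) -> np.ndarray:
    denom = stats.m_k[None, :] * (stats.pooled_sd + stats.s0)[:, None]
    return (stats.class_centroids - stats.overall_centroid[:, None]) / denom


def fit_centroids(X: pd.DataFrame, y, priors: str = "class") -> CentroidStats:
    """Compute NSC statistics from a CpG × sample matrix and class labels.

    Parameters
    ----------
    X : DataFrame, CpGs as rows, samples as columns; no missing values.
    y : class label per sample (aligned with ``X.columns``).
    priors : ``"class"`` (class proportions, default) or ``"uniform"``.
    """
    y = pd.Series(np.asarray(y), index=X.columns)
    if X.isna().any().any():
        raise ValueError("X contains missing values; impute before fitting")
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    sizes = np.array([(y == c).sum() for c in classes])
    if (sizes < 2).any():
        small = [c for c, s in zip(classes, sizes) if s < 2]
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    n = int(sizes.sum())
    K = len(classes)
    Xv = X.values.astype(float)
    p = Xv.shape[0]

    centroids = np.empty((p, K))
    ss = np.zeros(p)  # within-class sum of squares
    for j, c in enumerate(classes):
        block = Xv[:, (y == c).values]
        centroids[:, j] = block.mean(axis=1)
        ss += ((block - centroids[:, [j]]) ** 2).sum(axis=1)
    overall = Xv.mean(axis=1)
    s = np.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    if s0 <= 0.0:
        pos = s[s > 0]
        s0 = float(pos.min()) if pos.size else 1.0  # degenerate constant input
    m_k = np.sqrt(1.0 / sizes + 1.0 / n)
    if priors == "class":
        pri = sizes / n
    elif priors == "uniform":
        pri = np.full(K, 1.0 / K)
    else:
        raise ValueError("priors must be 'class' or 'uniform'")
    stats = CentroidStats(
        classes=list(classes),
        cpg_ids=list(X.index),
        class_centroids=centroids,
        overall_centroid=overall,
        pooled_sd=s,
        s0=s0,
        m_k=m_k,
        d=np.empty(0),
        priors=pri,
        class_sizes=sizes,
        n=n,
    )
    stats.d = _standardized_differences(stats)
    return stats


def shrink(stats: CentroidStats, delta: float) -> CentroidModel:
    """Soft-threshold the standardized differences at ``delta`` ≥ 0."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    d_shrunk = np.sign(stats.d) * np.maximum(0.0, np.abs(stats.d) - delta)
    scale = stats.m_k[None, :] * (stats.pooled_sd + stats.s0)[:, None]
    shrunken = stats.overall_centroid[:, None] + scale * d_shrunk
    return CentroidModel(
        classes=stats.classes,
        cpg_ids=stats.cpg_ids,
        class_centroids=stats.class_centroids,
        overall_centroid=stats.overall_centroid,
        pooled_sd=stats.pooled_sd,
        s0=stats.s0,
        m_k=stats.m_k,
        d=stats.d,
        priors=stats.priors,
        class_sizes=stats.class_sizes,
        n=stats.n,
        delta=float(delta),
        d_shrunk=d_shrunk,
        shrunken_centroids=shrunken,
    )


def _discriminants(model: CentroidModel, Xv: np.ndarray) -> np.ndarray:
    """δ_k for each sample: shape (n_samples, K)."""
    denom = model.pooled_sd + model.s0
    K = len(model.classes)
    out = np.empty((Xv.shape[1], K))
    for j in range(K):
        z = (Xv - model.shrunken_centroids[:, [j]]) / denom[:, None]
        out[:, j] = (z**2).sum(axis=0) - 2.0 * np.log(model.priors[j])
    return out


def _align(model: CentroidModel, x) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.Series):
        x = x.to_frame()
    if isinstance(x, pd.DataFrame):
        missing = [c for c in model.cpg_ids if c not in x.index]
        if missing:
            raise KeyError(f"input is missing model CpGs: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        return x.loc[model.cpg_ids].values.astype(float), list(x.columns)
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[0] != len(model.cpg_ids):
        arr = arr.T
    if arr.shape[0] != len(model.cpg_ids):
        raise ValueError("vector length does not match model CpGs")
    return arr, list(range(arr.shape[1]))


def predict(model: CentroidModel, x) -> tuple[pd.Series, pd.DataFrame]:
    """Classify sample(s) ``x``; returns (labels, per-class posteriors).

    Ties in the discriminant go to the lexicographically first class label
    (``model.classes`` is sorted at fit time).
    """
    Xv, names = _align(model, x)
    delta = _discriminants(model, Xv)
    # softmax of -δ/2, stabilized
    logp = -0.5 * delta
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmin(delta, axis=1)  # first minimum => first class label on ties
    labels = pd.Series([model.classes[i] for i in idx], index=names)
    posteriors = pd.DataFrame(post, index=names, columns=model.classes)
    return labels, posteriors


def selected_features(model: CentroidModel) -> list:
    """CpGs with a nonzero shrunken difference in at least one class."""
    mask = (model.d_shrunk != 0).any(axis=1)
    return [c for c, m in zip(model.cpg_ids, mask) if m]


def default_delta_grid(stats: CentroidStats, n_points: int = 30) -> np.ndarray:
    top = float(np.abs(stats.d).max()) if stats.d.size else 0.0
    if top <= 0:
        return np.array([0.0])
    return np.linspace(0.0, top, n_points)


def stratified_folds(y: pd.Series, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns index arrays per fold."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 61]))
    pos = np.arange(len(y))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for c in sorted(pd.unique(y)):
        members = pos[(y == c).values]
        rng.shuffle(members)
        for i, m in enumerate(members):
            folds[(i + offset) % n_folds].append(m)
        offset += len(members)
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CVResult:
    """Cross-validation profile over the Δ grid."""

    delta_grid: np.ndarray
    cv_errors: np.ndarray  # misclassification rate per delta
    cv_loglik: np.ndarray  # summed held-out log posterior of the true class
    chosen_delta: float
    n_folds: int
    seed: int

    @property
    def min_error(self) -> float:
        return float(self.cv_errors.min())


def cross_validate(
    X: pd.DataFrame,
    y,
    delta_grid=None,
    n_folds: int = 10,
    seed: int = 0,
    priors: str = "class",
) -> CVResult:
    """Stratified k-fold CV of the NSC over a shrinkage grid.

    The grid defaults to 30 equally spaced values from 0 to max|d_ik| of the
    full-data fit.  A class smaller than ``n_folds`` shrinks the fold count
    to the smallest class size (with a warning).
    """
    y = pd.Series(np.asarray(y), index=X.columns)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    min_class = int(y.value_counts().min())
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds "
            f"from {n_folds} to {min_class}",
            stacklevel=2,
        )
        n_folds = min_class
    full = fit_centroids(X, y, priors=priors)
    if delta_grid is None:
        delta_grid = default_delta_grid(full)
    delta_grid = np.asarray(delta_grid, dtype=float)

    folds = stratified_folds(y, n_folds, seed)
    n = len(y)
    errors = np.zeros(len(delta_grid))
    loglik = np.zeros(len(delta_grid))
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        stats = fit_centroids(X.iloc[:, mask], y.iloc[mask], priors=priors)
        X_test = X.iloc[:, test_idx]
        y_test = y.iloc[test_idx].values
        col = {c: j for j, c in enumerate(stats.classes)}
        ti = np.array([col.get(t, -1) for t in y_test])
        rows = np.arange(len(y_test))
        for gi, delta in enumerate(delta_grid):
            model = shrink(stats, delta)
            labels, post = predict(model, X_test)
            errors[gi] += int((labels.values != y_test).sum())
            pv = post.values
            true_p = np.where(ti >= 0, pv[rows, np.clip(ti, 0, None)], 0.0)
            loglik[gi] += float(np.log(np.clip(true_p, 1e-300, None)).sum())
    errors /= n

    best_err = errors.min()
    tied = np.flatnonzero(errors == best_err)
    best_ll = loglik[tied].max()
    tied = tied[loglik[tied] == best_ll]
    chosen = float(delta_grid[tied.max()])  # sparsest among remaining ties
    return CVResult(
        delta_grid=delta_grid,
        cv_errors=errors,
        cv_loglik=loglik,
        chosen_delta=chosen,
        n_folds=n_folds,
        seed=seed,
    )


def fit_cv(
    X: pd.DataFrame,
    y,
    delta_grid=None,
    n_folds: int = 10,
    seed: int = 0,
    priors: str = "class",
) -> tuple[CentroidModel, CVResult]:
    """Convenience: cross-validate Δ then fit the full-data model at it."""
    cv = cross_validate(X, y, delta_grid=delta_grid, n_folds=n_folds,
                        seed=seed, priors=priors)
    model = shrink(fit_centroids(X, y, priors=priors), cv.chosen_delta)
    return model, cv
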