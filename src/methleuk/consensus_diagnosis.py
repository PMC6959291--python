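"""Consensus diagnostic marker selection via repeated 70/30 splits.

For a pairwise comparison (e.g. AML vs normal blood) the cohort is randomly
split 20 times into 70% training / 30% validation, stratified by class.  On
each training split a nearest-shrunken-centroids classifier is tuned by
10-fold cross-validation; the CpGs it keeps are recorded, and the shrunken
model is scored on the held-out validation split (confusion table).  The
consensus panel is the exact intersection of the 20 selected sets — a CpG
must survive every split to enter the panel — which screens out markers
selected by the vagaries of any one split.

Panel evaluation refits the NSC on the consensus CpGs alone and scores
samples by the posterior probability of the case class; ROC/AUC follows.
Heat-map ordering for reporting comes from average-linkage hierarchical
clustering on Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import nsc as _nsc
from .evaluation import ConfusionTable, ROCResult, confusion_metrics, roc_curve

__all__ = [
    "SplitScheme",
    "ConsensusPanel",
    "split_cohort",
    "run_repeated_splits",
    "intersect_markers",
    "evaluate_panel",
    "cluster_order",
]


@dataclass
class SplitScheme:
    """Repeated stratified leave-group-out protocol."""

    train_fraction: float = 0.7
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split_cohort(
    annotation: pd.DataFrame, scheme: SplitScheme, repeat_index: int
) -> tuple[list, list]:
    """One stratified train/validation partition of the sample ids.

    Per class, floor(train_fraction * n_class) samples go to training and
    the remainder to validation.  Deterministic in (scheme.seed,
    repeat_index); disjoint and exhaustive by construction.
    """
    if repeat_index >= scheme.n_repeats or repeat_index < 0:
        raise ValueError("repeat_index out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scheme.seed), 7, int(repeat_index)])
    )
    train, val = [], []
    for c in sorted(annotation["class_label"].unique()):
        ids = annotation.loc[annotation["class_label"] == c, "sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        ids = list(np.array(ids)[rng.permutation(len(ids))])
        n_train = int(np.floor(scheme.train_fraction * len(ids)))
        train.extend(ids[:n_train])
        val.extend(ids[n_train:])
    return train, val


@dataclass
class ConsensusPanel:
    """Per-repeat NSC selections and validation performance."""

    comparison: tuple
    per_repeat_sets: list = field(default_factory=list)  # list of CpG-id sets
    confusions: list = field(default_factory=list)  # ConfusionTable per repeat
    chosen_deltas: list = field(default_factory=list)

    @property
    def intersection(self) -> list:
        return intersect_markers(self)

    @property
    def mean_validation_error(self) -> float:
        errs = [1.0 - ct.accuracy for ct in self.confusions]
        return float(np.mean(errs)) if errs else np.nan


def run_repeated_splits(
    X: pd.DataFrame,
    y,
    scheme: SplitScheme,
    comparison: tuple,
    n_folds: int = 10,
    priors: str = "class",
) -> ConsensusPanel:
    """Run the full repeated-split NSC pipeline for one class pair."""
    y = pd.Series(np.asarray(y), index=X.columns)
    a, b = comparison
    keep = y.isin([a, b])
    if not (y == a).any() or not (y == b).any():
        raise ValueError(f"both classes of {comparison} must be present")
    Xc = X.loc[:, keep.values]
    yc = y[keep]
    annotation = pd.DataFrame(
        {"sample_id": Xc.columns, "class_label": yc.values}
    )
    panel = ConsensusPanel(comparison=(a, b))
    for r in range(scheme.n_repeats):
        train_ids, val_ids = split_cohort(annotation, scheme, r)
        child = int(
            np.random.SeedSequence([int(scheme.seed), 11, r]).generate_state(1)[0]
            % (2**31)
        )
        model, cv = _nsc.fit_cv(
            Xc[train_ids], yc[train_ids].values, n_folds=n_folds,
            seed=child, priors=priors,
        )
        panel.per_repeat_sets.append(set(_nsc.selected_features(model)))
        panel.chosen_deltas.append(cv.chosen_delta)
        labels, _ = _nsc.predict(model, Xc[val_ids])
        panel.confusions.append(
            confusion_metrics(yc[val_ids].values, labels.values,
                              classes=model.classes)
        )
    return panel


def intersect_markers(panel) -> list:
    """Exact intersection of the per-repeat CpG sets, sorted by CpG id.

    Accepts a :class:`ConsensusPanel` or any iterable of sets.  An empty
    intersection returns an empty list with a warning (not an error).
    """
    sets = panel.per_repeat_sets if isinstance(panel, ConsensusPanel) else list(panel)
    if len(sets) == 0:
        raise ValueError("at least one repeat is required")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    if not common:
        warnings.warn("consensus intersection is empty", stacklevel=2)
    return sorted(common)


def evaluate_panel(
    X: pd.DataFrame,
    y,
    panel_cpgs,
    positive_class,
    delta: float = 0.0,
    score: str = "nsc",
) -> ROCResult:
    """ROC/AUC of the consensus panel as a case-vs-rest score.

    Refits the NSC on the panel CpGs only (at shrinkage ``delta``; the panel
    is already selected, so no shrinkage by default) and scores each sample
    by the posterior probability of ``positive_class``.  ``score="logistic"``
    instead uses a logistic regression on the panel betas (Newton-IRLS),
    as a model-free alternative.
    """
    panel_cpgs = list(panel_cpgs)
    if len(panel_cpgs) == 0:
        raise ValueError("panel is empty")
    missing = [c for c in panel_cpgs if c not in X.index]
    if missing:
        raise KeyError(f"panel CpGs absent from X: {missing}")
    y = pd.Series(np.asarray(y), index=X.columns)
    if y.nunique() < 2:
        raise ValueError("need at least two classes to evaluate")
    Xp = X.loc[panel_cpgs]
    labels = (y == positive_class).values
    if score == "nsc":
        model = _nsc.shrink(_nsc.fit_centroids(Xp, y.values), delta)
        _, post = _nsc.predict(model, Xp)
        s = post[positive_class].values
    elif score == "logistic":
        s = _logistic_score(Xp.values.T, labels.astype(float))
    else:
        raise ValueError("score must be 'nsc' or 'logistic'")
    return roc_curve(s, labels)


def _logistic_score(A: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Ridge-stabilized logistic regression scores via IRLS."""
    Z = np.c_[np.ones(len(A)), A]
    w = np.zeros(Z.shape[1])
    for _ in range(50):
        eta = np.clip(Z @ w, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu) + 1e-9
        H = (Z * W[:, None]).T @ Z + 1e-6 * np.eye(Z.shape[1])
        g = Z.T @ (target - mu) - 1e-6 * w
        step = np.linalg.solve(H, g)
        w += step
        if np.abs(step).max() < 1e-10:
            break
    return 1.0 / (1.0 + np.exp(-np.clip(Z @ w, -30, 30)))


def cluster_order(X: pd.DataFrame, cpgs=None) -> tuple[list, list]:
    """Heat-map leaf orders by average-linkage hierarchical clustering.

    Returns (row order of CpG ids, column order of sample ids) from
    Euclidean-distance agglomeration; deterministic for a given matrix.
    A single CpG (or sample) yields a trivial order on that axis.
    """
    sub = X if cpgs is None else X.loc[list(cpgs)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    def _leaves(mat: np.ndarray, names: list) -> list:
        if len(names) < 2:
            return list(names)
        link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="average")
        return [names[i] for i in hierarchy.leaves_list(link)]

    row_order = _leaves(sub.values, list(sub.index))
    col_order = _leaves(sub.values.T, list(sub.columns))
    return row_order, col_order
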