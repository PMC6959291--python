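"""Semisupervised survival stratification on methylation beta values.

The scheme (in the Bair–Tibshirani tradition) turns a censored-survival
cohort into a two-class classification problem:

1. For every CpG, fit a univariate Cox proportional-hazards model of
   survival on the beta value and record the *Cox score* — the absolute
   Wald z statistic |coef| / se (a partial-likelihood score statistic is
   available as an alternative).
2. Sweep 100 equally spaced score cutoffs between the 90th percentile of
   the scores and their maximum.  For each cutoff: keep the CpGs whose
   score exceeds it, 2-means-cluster the patients on those CpGs, log-rank
   test the two clusters' survival, and fit a cross-validated nearest
   shrunken centroids (NSC) classifier on the cluster labels.
3. Choose the cutoff whose clusters both separate survival most
   significantly and classify most reliably: minimize the sum of the
   ascending rank of the log-rank p-value and the ascending rank of the NSC
   CV error; ties prefer fewer CpGs, then a larger cutoff.
4. Name the clusters "good survival" / "bad survival" by within-group
   median survival (Kaplan–Meier survival at the last common event time
   when medians are unreached) and predict validation patients with the
   embedded NSC model.

Cox fits use Breslow tie handling and a safeguarded Newton iteration,
vectorized across CpGs.  The log-rank test and Kaplan–Meier estimator are
implemented directly (they sit inside the cutoff sweep's hot loop);
`lifelines` serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import nsc as _nsc

__all__ = [
    "CoxRanking",
    "SurvivalClassifierModel",
    "KMCurve",
    "cox_score",
    "cox_scores",
    "rank_and_grid",
    "cluster_two_groups",
    "logrank_test",
    "train_survival_classifier",
    "predict_risk_group",
    "kaplan_meier",
]

GOOD, BAD = "good survival", "bad survival"


# ---------------------------------------------------------------------------
# univariate Cox scores
# ---------------------------------------------------------------------------

def _check_surv(surv: pd.DataFrame) -> pd.DataFrame:
    for c in ("time", "event"):
        if c not in surv.columns:
            raise ValueError(f"survival table is missing column {c!r}")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(surv["event"])) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    if int(surv["event"].sum()) < 1:
        raise ValueError("at least one observed event is required")
    return surv


def _cox_sufficient(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and map each event to its risk-set block.

    With ties, the risk set at an event time t is every subject with
    time >= t, i.e. the suffix starting at the first index of the tie block
    (Breslow convention).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    # first index of each tie block, propagated to all members
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    return order, t, e, first


def _cox_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
    beta_cap: float = 30.0,
):
    """Univariate Cox MLE for each row of X simultaneously.

    Returns (beta, info, converged) arrays of shape (p,).  Breslow ties.
    """
    order, t, e, first = _cox_sufficient(time, event)
    Xs = X[:, order]
    p, n = Xs.shape
    ev = np.flatnonzero(e)
    blocks = first[ev]

    beta = np.zeros(p)
    info = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    active = np.ones(p, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        xb = np.clip(beta[idx, None] * Xs[idx], -500, 500)
        w = np.exp(xb)
        # suffix sums: S_r(position j) = sum_{k >= j} w * x^r
        s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
        s1 = np.cumsum((w * Xs[idx])[:, ::-1], axis=1)[:, ::-1]
        s2 = np.cumsum((w * Xs[idx] ** 2)[:, ::-1], axis=1)[:, ::-1]
        r0 = s0[:, blocks]
        r1 = s1[:, blocks]
        r2 = s2[:, blocks]
        U = (Xs[idx][:, ev] - r1 / r0).sum(axis=1)
        I = (r2 / r0 - (r1 / r0) ** 2).sum(axis=1)
        info[idx] = I
        flat = I <= 1e-12  # constant covariate or fully shrunk risk set
        step = np.zeros(len(idx))
        ok = ~flat
        step[ok] = U[ok] / I[ok]
        step = np.clip(step, -2.0, 2.0)
        beta[idx] += np.where(flat, 0.0, step)
        done = flat | (np.abs(step) < tol)
        diverged = np.abs(beta[idx]) > beta_cap
        converged[idx[done & ~diverged]] = True
        beta[idx[flat]] = 0.0
        info[idx[flat]] = 0.0
        active[idx[done | diverged]] = False
    return beta, info, converged | ~np.isfinite(info)


def cox_scores(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    statistic: str = "wald",
) -> pd.Series:
    """Per-CpG Cox scores (absolute standardized statistics), vectorized.

    ``statistic="wald"``: |beta_hat| * sqrt(I(beta_hat)) from the Newton
    fit; non-converged fits score 0 with a warning.  ``statistic="score"``:
    the partial-likelihood score test U(0)/sqrt(I(0)) in absolute value
    (no iteration).
    """
    surv = _check_surv(surv)
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    common = [s for s in X.columns if s in surv.index]
    if len(common) != X.shape[1]:
        raise KeyError("survival table does not cover every sample in X")
    time = surv.loc[common, "time"].to_numpy(dtype=float)
    event = surv.loc[common, "event"].to_numpy(dtype=int)
    Xv = X.loc[:, common].to_numpy(dtype=float)
    if statistic == "score":
        order, t, e, first = _cox_sufficient(time, event)
        Xs = Xv[:, order]
        ev = np.flatnonzero(e)
        blocks = first[ev]
        ones = np.ones_like(Xs)
        s0 = np.cumsum(ones[:, ::-1], axis=1)[:, ::-1][:, blocks]
        s1 = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1][:, blocks]
        s2 = np.cumsum((Xs**2)[:, ::-1], axis=1)[:, ::-1][:, blocks]
        U = (Xs[:, ev] - s1 / s0).sum(axis=1)
        I = (s2 / s0 - (s1 / s0) ** 2).sum(axis=1)
        z = np.zeros(len(Xv))
        ok = I > 1e-12
        z[ok] = np.abs(U[ok]) / np.sqrt(I[ok])
        return pd.Series(z, index=X.index, name="cox_score")
    if statistic != "wald":
        raise ValueError("statistic must be 'wald' or 'score'")
    beta, info, converged = _cox_newton(Xv, time, event)
    z = np.abs(beta) * np.sqrt(np.maximum(info, 0.0))
    if not converged.all():
        bad = int((~converged).sum())
        warnings.warn(
            f"{bad} Cox fit(s) did not converge; their scores are set to 0",
            stacklevel=2,
        )
        z[~converged] = 0.0
    return pd.Series(z, index=X.index, name="cox_score")


def cox_score(beta_row, surv: pd.DataFrame, statistic: str = "wald") -> float:
    """Cox score of a single CpG (see :func:`cox_scores`)."""
    if isinstance(beta_row, pd.Series):
        X = beta_row.to_frame().T
    else:
        X = pd.DataFrame(np.atleast_2d(np.asarray(beta_row, dtype=float)))
        if "sample_id" in surv.columns:
            X.columns = list(surv["sample_id"])
    return float(cox_scores(X, surv, statistic=statistic).iloc[0])


@dataclass
class CoxRanking:
    """Cox scores with their rank order and empirical percentile function."""

    scores: pd.Series

    @property
    def ranked(self) -> pd.Series:
        return self.scores.sort_values(ascending=False)

    def percentile(self, q: float) -> float:
        """Linear-interpolation percentile of the score distribution."""
        return float(np.percentile(self.scores.to_numpy(), q))


def rank_and_grid(
    scores, lower_pct: float = 90.0, n_points: int = 100
) -> np.ndarray:
    """Equally spaced cutoff grid from the ``lower_pct`` percentile to the max."""
    s = scores.scores if isinstance(scores, CoxRanking) else pd.Series(scores)
    vals = s.to_numpy(dtype=float)
    if len(np.unique(vals)) < 2:
        raise ValueError("all Cox scores equal: degenerate cutoff grid")
    lo = float(np.percentile(vals, lower_pct))
    hi = float(vals.max())
    return np.linspace(lo, hi, n_points)


# ---------------------------------------------------------------------------
# 2-means clustering of patients
# ---------------------------------------------------------------------------

def cluster_two_groups(X_selected: pd.DataFrame, seed: int = 0,
                       n_restarts: int = 20) -> pd.Series:
    """2-means clustering of patients on the selected CpGs' beta values.

    Patients are the observations (``X_selected`` is CpG × patient and is
    transposed internally); features are unscaled beta values.  Lloyd's
    algorithm with ``n_restarts`` seeded restarts, keeping the lowest
    within-cluster sum of squares.  Returns 0/1 labels per patient.
    """
    P = X_selected.to_numpy(dtype=float).T  # patients × features
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 patients")
    if np.unique(P, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct patient profiles")
    best_labels, best_wss = None, np.inf
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    for _ in range(n_restarts):
        while True:  # distinct initial centers
            i, j = rng.choice(n, size=2, replace=False)
            if not np.array_equal(P[i], P[j]):
                break
        centers = np.stack([P[i], P[j]])
        labels = np.full(n, -1, dtype=int)
        for _it in range(100):
            d = ((P[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new = d.argmin(axis=1)
            for k in (0, 1):  # re-seed an emptied cluster with the farthest point
                if not (new == k).any():
                    new[d.min(axis=1).argmax()] = k
            if np.array_equal(new, labels):
                break
            labels = new
            for k in (0, 1):
                centers[k] = P[labels == k].mean(axis=0)
        wss = sum(
            ((P[labels == k] - centers[k]) ** 2).sum() for k in (0, 1)
        )
        if wss < best_wss - 1e-12:
            best_wss, best_labels = wss, labels.copy()
    return pd.Series(best_labels, index=X_selected.columns, name="cluster")


# ---------------------------------------------------------------------------
# log-rank test and Kaplan–Meier estimator
# ---------------------------------------------------------------------------

def logrank_test(surv: pd.DataFrame, labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Observed vs expected events in group 1 accumulated over the pooled
    event times; the statistic is (O1 − E1)² / V1 ~ χ²(1).
    """
    surv = _check_surv(surv)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("exactly two non-empty groups are required")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    g1 = lab == groups[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & g1).sum())
        d_j = int(((time == t) & (event == 1)).sum())
        d1_j = int(((time == t) & (event == 1) & g1).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += (
                d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
            )
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit curve for one group."""

    group: str
    times: np.ndarray  # event-time grid (0 prepended)
    survival: np.ndarray  # S(t) steps, starting at 1.0
    at_risk: np.ndarray  # subjects at risk just before each time
    censor_times: np.ndarray  # times of censored observations

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    @property
    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_at_risk": self.at_risk,
                "group": self.group,
            }
        )


def _km_one(time: np.ndarray, event: np.ndarray, name: str) -> KMCurve:
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    ts = [0.0]
    surv = [1.0]
    at_risk = [len(t)]
    s = 1.0
    for u in np.unique(t[e]):
        n_j = int((t >= u).sum())
        d_j = int(((t == u) & e).sum())
        s *= 1.0 - d_j / n_j
        ts.append(float(u))
        surv.append(s)
        at_risk.append(n_j)
    return KMCurve(
        group=name,
        times=np.asarray(ts),
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        censor_times=np.sort(t[~e]),
    )


def kaplan_meier(surv: pd.DataFrame, labels=None) -> dict[str, KMCurve]:
    """Kaplan–Meier curves per group (one curve named "all" if no labels)."""
    for c in ("time", "event"):
        if c not in surv.columns:
            raise ValueError(f"survival table is missing column {c!r}")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if labels is None:
        return {"all": _km_one(time, event, "all")}
    lab = np.asarray(labels)
    out = {}
    for g in np.unique(lab):
        m = lab == g
        if not m.any():
            raise ValueError(f"group {g!r} is empty")
        out[str(g)] = _km_one(time[m], event[m], str(g))
    return out


# ---------------------------------------------------------------------------
# the semisupervised classifier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalClassifierModel:
    """Trained good/bad-survival classifier.

    ``selected_cpgs`` are exactly the CpGs whose Cox score exceeds
    ``cutoff``; ``signature_cpgs`` are the subset the embedded NSC model
    keeps after shrinkage (nonzero shrunken difference).
    """

    cutoff: float
    selected_cpgs: list
    cluster_labels: pd.Series  # training patients -> GOOD/BAD
    centroid_model: _nsc.CentroidModel
    cox_ranking: CoxRanking
    logrank_stat: float
    logrank_p: float
    cv_error: float
    seed: int

    @property
    def signature_cpgs(self) -> list:
        return _nsc.selected_features(self.centroid_model)

    def to_json(self, path) -> None:
        obj = {
            "cutoff": self.cutoff,
            "selected_cpgs": list(self.selected_cpgs),
            "cluster_labels": {k: v for k, v in self.cluster_labels.items()},
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "cv_error": self.cv_error,
            "seed": self.seed,
            "centroid_model": self.centroid_model.to_dict(),
        }
        with open(path, "w") as out:
            json.dump(obj, out, indent=1)

    @classmethod
    def from_json(cls, path) -> "SurvivalClassifierModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            cutoff=float(obj["cutoff"]),
            selected_cpgs=list(obj["selected_cpgs"]),
            cluster_labels=pd.Series(obj["cluster_labels"]),
            centroid_model=_nsc.CentroidModel.from_dict(obj["centroid_model"]),
            cox_ranking=CoxRanking(pd.Series(dtype=float)),
            logrank_stat=float(obj["logrank_stat"]),
            logrank_p=float(obj["logrank_p"]),
            cv_error=float(obj["cv_error"]),
            seed=int(obj["seed"]),
        )


def _name_groups(surv: pd.DataFrame, labels01: pd.Series) -> pd.Series:
    """Map 0/1 cluster ids to GOOD/BAD by median (or late-time KM) survival."""
    curves = kaplan_meier(surv, labels01.loc[surv["sample_id"]].values
                          if "sample_id" in surv.columns else labels01.values)
    meds = {g: c.median for g, c in curves.items()}
    if all(np.isinf(m) for m in meds.values()):
        # medians unreached: compare KM survival at the last common event time
        last = min(c.times[-1] for c in curves.values())
        meds = {g: c.survival_at(last) for g, c in curves.items()}
    ordered = sorted(meds, key=lambda g: meds[g])  # worst first
    mapping = {int(ordered[0]): BAD, int(ordered[1]): GOOD}
    return labels01.map(mapping)


def train_survival_classifier(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    seed: int = 0,
    lower_pct: float = 90.0,
    n_points: int = 100,
    n_folds: int = 10,
    statistic: str = "wald",
) -> SurvivalClassifierModel:
    """Fit the full semisupervised survival classifier on a training cohort.

    See the module docstring for the procedure.  ``surv`` must carry
    ``sample_id`` matching ``X.columns`` (or be aligned positionally).
    """
    surv = surv.copy()
    if "sample_id" not in surv.columns:
        surv.insert(0, "sample_id", list(X.columns))
    surv = surv.set_index("sample_id").loc[list(X.columns)].reset_index()
    _check_surv(surv)

    scores = cox_scores(X, surv, statistic=statistic)
    ranking = CoxRanking(scores)
    grid = rank_and_grid(ranking, lower_pct=lower_pct, n_points=n_points)

    # cutoffs selecting the same CpG set are equivalent; evaluate each
    # distinct selection once and remember the largest cutoff producing it
    candidates: dict[tuple, dict] = {}
    for cutoff in grid:
        sel = tuple(sorted(scores.index[scores > cutoff]))
        if len(sel) == 0:
            continue
        if sel in candidates:
            candidates[sel]["cutoff"] = max(candidates[sel]["cutoff"], float(cutoff))
        else:
            candidates[sel] = {"cutoff": float(cutoff)}

    feasible = []
    for sel, info in candidates.items():
        X_sel = X.loc[list(sel)]
        try:
            labels01 = cluster_two_groups(X_sel, seed=seed)
        except ValueError:
            continue
        sizes = labels01.value_counts()
        if sizes.min() < 2:
            continue  # NSC needs >= 2 samples per class
        stat, p = logrank_test(surv, labels01.values)
        named = _name_groups(surv, labels01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = _nsc.cross_validate(
                X_sel, named.values, n_folds=min(n_folds, int(sizes.min())),
                seed=seed,
            )
        feasible.append(
            {
                "selected": sel,
                "cutoff": info["cutoff"],
                "labels": named,
                "logrank_stat": stat,
                "logrank_p": p,
                "cv_error": cv.min_error,
                "chosen_delta": cv.chosen_delta,
            }
        )
    if not feasible:
        raise ValueError("no cutoff produced a feasible two-group model")

    p_ranks = sps.rankdata([f["logrank_p"] for f in feasible], method="average")
    e_ranks = sps.rankdata([f["cv_error"] for f in feasible], method="average")
    keys = [
        (p_ranks[i] + e_ranks[i], len(f["selected"]), -f["cutoff"])
        for i, f in enumerate(feasible)
    ]
    best = feasible[min(range(len(feasible)), key=keys.__getitem__)]

    X_best = X.loc[list(best["selected"])]
    model = _nsc.shrink(
        _nsc.fit_centroids(X_best, best["labels"].values), best["chosen_delta"]
    )
    return SurvivalClassifierModel(
        cutoff=best["cutoff"],
        selected_cpgs=list(best["selected"]),
        cluster_labels=best["labels"],
        centroid_model=model,
        cox_ranking=ranking,
        logrank_stat=best["logrank_stat"],
        logrank_p=best["logrank_p"],
        cv_error=best["cv_error"],
        seed=seed,
    )


def predict_risk_group(model: SurvivalClassifierModel, X_new: pd.DataFrame) -> pd.Series:
    """Assign GOOD/BAD survival labels to new patients via the embedded NSC."""
    labels, _ = _nsc.predict(model.centroid_model, X_new)
    labels.name = "risk_group"
    return labels
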