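"""Synthetic methylation cohorts with planted diagnostic and prognostic truth.

The generator emulates the statistical structure a CpG-panel analysis
assumes: a CpG × sample matrix of beta values in [0, 1], class labels
(e.g. AML / ALL / normal), survival outcomes whose hazard depends on a
planted CpG subset, and per-CpG per-sample read-count tables with UMIs.

Beta values are drawn from Beta distributions parameterized by
(mean, concentration): a = mean·c, b = (1 − mean)·c, so an effect size is a
shift of the mean at fixed dispersion.  Background CpGs each get a baseline
mean (drawn once, class-independent) and the same concentration; planted
diagnostic markers shift the mean in their target class only.  Prognostic
markers are bimodal: a latent per-patient risk group sets each planted
CpG's mean high or low, and the survival generator's hazard is
proportional-hazards in the beta values, so the latent group carries a
configurable total log hazard ratio.

One global seed expands into independent per-stage child seeds
(`numpy.random.SeedSequence`), so matrices, survival times and read counts
are individually reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSpec",
    "PrognosticSpec",
    "CohortConfig",
    "TruthPanel",
    "simulate_beta_cohort",
    "simulate_survival",
    "simulate_read_counts",
    "default_diagnostic_config",
    "default_prognostic_config",
]


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


@dataclass
class MarkerSpec:
    """A block of diagnostic markers for one class.

    Betas at these CpGs have mean ``mean_beta_case`` in ``class_label`` and
    ``mean_beta_other`` everywhere else, at the given Beta concentration.
    """

    class_label: str
    n_markers: int
    mean_beta_case: float
    mean_beta_other: float
    concentration: float


@dataclass
class PrognosticSpec:
    """Bimodal prognostic markers driven by a latent binary risk group.

    Half of the ``n_markers`` CpGs are hypermethylated-in-risk (positive
    log-hazard coefficient), the other half hypomethylated-in-risk
    (negative): high-risk patients sit at the risk-raising mode of every
    marker (``high_mean`` for positive markers, ``low_mean`` for negative
    ones), low-risk patients at the opposite mode.  Mixing signs keeps the
    cohort's linear predictor centred and matches real signatures, which
    contain both hyper- and hypomethylated CpGs.

    ``group_log_hr`` is the total log hazard ratio between the risk
    groups; it is split evenly over the markers, so each CpG's coefficient
    has magnitude group_log_hr / (n_markers·(high_mean − low_mean)).

    The default concentration of 0.5 makes each planted CpG strongly
    bimodal — mass piled near 0 and 1, the shape real array beta values
    take at variably methylated CpGs — with the risk group only shifting
    the probability of the methylated state (0.65 vs 0.35).  A single
    marker therefore stratifies the risk groups poorly, and reliable
    stratification needs the joint panel: the
    individually-weak/jointly-strong regime a semisupervised survival
    signature exists for.
    """

    n_markers: int = 10
    low_mean: float = 0.35
    high_mean: float = 0.65
    concentration: float = 0.5
    high_fraction: float = 0.5
    group_log_hr: float = 3.0


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    Default class sizes mirror a typical discovery setting for acute
    leukemias: 194 AML, 136 ALL and 754 normal-blood samples over a
    729-CpG panel.
    """

    n_cpgs: int = 729
    n_per_class: dict = field(
        default_factory=lambda: {"AML": 194, "ALL": 136, "normal": 754}
    )
    marker_spec: list = field(default_factory=list)
    prognostic_spec: PrognosticSpec | None = None
    background_concentration: float = 30.0
    background_mean_range: tuple = (0.1, 0.9)
    seed: int = 0

    def validate(self) -> None:
        n_planted = sum(m.n_markers for m in self.marker_spec)
        if self.prognostic_spec is not None:
            n_planted += self.prognostic_spec.n_markers
        if n_planted > self.n_cpgs:
            raise ValueError(
                f"{n_planted} planted markers exceed the {self.n_cpgs}-CpG panel"
            )
        for m in self.marker_spec:
            if not (0 < m.mean_beta_case < 1 and 0 < m.mean_beta_other < 1):
                raise ValueError("marker mean betas must lie in (0, 1)")
            if m.concentration <= 0:
                raise ValueError("marker concentration must be positive")
            if m.class_label not in self.n_per_class:
                raise ValueError(f"marker class {m.class_label!r} not in cohort")
        if self.background_concentration <= 0:
            raise ValueError("background concentration must be positive")


@dataclass
class TruthPanel:
    """Ground truth of a simulated cohort, for recovery testing.

    ``planted_diagnostic`` maps each marker class label to its CpG ids; the
    markers relevant to a comparison (A, B) are the union of the two
    classes' sets.  ``effect_sizes`` gives each prognostic CpG's log-hazard
    coefficient per unit beta; ``risk_group`` is the latent per-sample
    high-risk indicator driving the bimodal prognostic betas.
    """

    planted_diagnostic: dict
    planted_prognostic: set
    effect_sizes: dict
    risk_group: pd.Series | None = None

    def diagnostic_for(self, class_a: str, class_b: str) -> set:
        out: set = set()
        out |= set(self.planted_diagnostic.get(class_a, ()))
        out |= set(self.planted_diagnostic.get(class_b, ()))
        return out

    def to_json(self, path) -> None:
        obj = {
            "planted_diagnostic": {
                k: sorted(v) for k, v in self.planted_diagnostic.items()
            },
            "planted_prognostic": sorted(self.planted_prognostic),
            "effect_sizes": dict(self.effect_sizes),
            "risk_group": (
                None if self.risk_group is None
                else {k: int(v) for k, v in self.risk_group.items()}
            ),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _beta_draw(rng, mean, concentration, size):
    a = np.asarray(mean) * concentration
    b = (1.0 - np.asarray(mean)) * concentration
    return rng.beta(a, b, size=size)


def simulate_beta_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthPanel]:
    """Draw a (BetaMatrix, SampleAnnotation, TruthPanel) triple.

    Deterministic given ``config.seed``.  The beta matrix has CpGs as rows
    ("cg00000001", ...) and samples as columns ("AML_0001", ...).
    """
    config.validate()
    rng = _rng(config.seed, 1)

    cpg_ids = [f"cg{i + 1:08d}" for i in range(config.n_cpgs)]
    classes = list(config.n_per_class)
    sample_ids, labels = [], []
    for c in classes:
        for i in range(config.n_per_class[c]):
            sample_ids.append(f"{c}_{i + 1:04d}")
            labels.append(c)
    n_samples = len(sample_ids)
    y = pd.Series(labels, index=sample_ids, name="class_label")

    # assign planted CpG positions without replacement
    n_diag = sum(m.n_markers for m in config.marker_spec)
    n_prog = config.prognostic_spec.n_markers if config.prognostic_spec else 0
    planted_pos = rng.choice(config.n_cpgs, size=n_diag + n_prog, replace=False)
    cursor = 0
    planted_diagnostic: dict[str, set] = {}
    marker_rows: list[tuple[MarkerSpec, np.ndarray]] = []
    for m in config.marker_spec:
        rows = planted_pos[cursor:cursor + m.n_markers]
        cursor += m.n_markers
        planted_diagnostic.setdefault(m.class_label, set()).update(
            cpg_ids[r] for r in rows
        )
        marker_rows.append((m, rows))
    prog_rows = planted_pos[cursor:cursor + n_prog]

    # background: per-CpG baseline mean, one class-independent law per CpG
    lo, hi = config.background_mean_range
    base_mean = rng.uniform(lo, hi, size=config.n_cpgs)
    X = _beta_draw(
        rng,
        base_mean[:, None],
        config.background_concentration,
        (config.n_cpgs, n_samples),
    )

    # overwrite planted diagnostic rows
    for m, rows in marker_rows:
        case = (y == m.class_label).values
        X[np.ix_(rows, np.flatnonzero(case))] = _beta_draw(
            rng, m.mean_beta_case, m.concentration, (len(rows), int(case.sum()))
        )
        X[np.ix_(rows, np.flatnonzero(~case))] = _beta_draw(
            rng, m.mean_beta_other, m.concentration, (len(rows), int((~case).sum()))
        )

    # overwrite planted prognostic rows from the latent risk group
    effect_sizes: dict[str, float] = {}
    risk_group = None
    if config.prognostic_spec is not None and n_prog > 0:
        ps = config.prognostic_spec
        high = rng.random(n_samples) < ps.high_fraction
        risk_group = pd.Series(high.astype(int), index=sample_ids, name="risk_group")
        signs = np.where(np.arange(n_prog) % 2 == 0, 1.0, -1.0)
        # risk-raising mode: high_mean for +markers, low_mean for -markers
        risk_mode = np.where(signs > 0, ps.high_mean, ps.low_mean)
        safe_mode = np.where(signs > 0, ps.low_mean, ps.high_mean)
        means = np.where(high[None, :], risk_mode[:, None], safe_mode[:, None])
        X[prog_rows, :] = _beta_draw(
            rng, means, ps.concentration, (n_prog, n_samples)
        )
        mag = ps.group_log_hr / (ps.n_markers * (ps.high_mean - ps.low_mean))
        for r, sgn in zip(prog_rows, signs):
            effect_sizes[cpg_ids[r]] = float(sgn * mag)

    beta = pd.DataFrame(X, index=cpg_ids, columns=sample_ids)
    beta.index.name = "cpg_id"
    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "class_label": labels, "cohort": "synthetic"}
    )
    truth = TruthPanel(
        planted_diagnostic=planted_diagnostic,
        planted_prognostic={cpg_ids[r] for r in prog_rows},
        effect_sizes=effect_sizes,
        risk_group=risk_group,
    )
    return beta, annotation, truth


def simulate_survival(
    beta: pd.DataFrame,
    truth: TruthPanel,
    baseline_hazard: float = 0.06,
    censor_horizon: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival times from beta values.

    hazard_i = baseline_hazard · exp(Σ_j coef_j · beta_ji) over the truth
    panel's prognostic CpGs (the prognostic coefficients are centred, so
    the default baseline of 0.06/month puts the cohort median near one
    year, an aggressive-leukemia timescale).  Censoring is at min(censor_horizon,
    Uniform(0, 2·censor_horizon)), i.e. administrative follow-up plus
    random early dropout.  Times are in months.
    """
    if baseline_hazard <= 0 or censor_horizon <= 0:
        raise ValueError("baseline_hazard and censor_horizon must be positive")
    rng = _rng(seed, 2)
    n = beta.shape[1]
    log_hr = np.zeros(n)
    if truth.effect_sizes:
        missing = [c for c in truth.effect_sizes if c not in beta.index]
        if missing:
            raise KeyError(f"prognostic CpGs absent from beta matrix: {missing}")
        for cpg, coef in truth.effect_sizes.items():
            log_hr += coef * beta.loc[cpg].values
    else:
        warnings.warn("empty prognostic set: all samples share the baseline hazard",
                      stacklevel=2)
    hazard = baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.minimum(censor_horizon,
                             rng.uniform(0.0, 2.0 * censor_horizon, size=n))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {"sample_id": beta.columns, "time": time, "event": event}
    )


def simulate_read_counts(
    beta: pd.DataFrame,
    depth_mean: float,
    seed: int = 0,
    duplication_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-read padlock-style count records with UMI tags.

    For each (CpG, sample) cell the number of UMI-distinct molecules is
    Poisson(``depth_mean``) and each molecule is methylated with probability
    beta.  With ``duplication_rate`` > 0, each molecule is additionally
    re-observed (same UMI, same call) with that probability, emulating PCR
    duplicates.  Returns a raw record table with columns
    ``cpg_id, sample_id, umi, methylated``.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = _rng(seed, 3)
    alphabet = np.array(list("ACGT"))
    recs_cpg, recs_sample, recs_umi, recs_meth = [], [], [], []
    for cpg, row in beta.iterrows():
        for sample, b in row.items():
            total = rng.poisson(depth_mean)
            if total == 0:
                continue
            total = min(total, 4096)
            codes = rng.choice(4096, size=total, replace=False)
            digits = (codes[:, None] // 4 ** np.arange(6)[None, :]) % 4
            umis = ["".join(t) for t in alphabet[digits]]
            meth = rng.random(total) < b
            dup = rng.random(total) < duplication_rate
            recs_cpg.extend([cpg] * total + [cpg] * int(dup.sum()))
            recs_sample.extend([sample] * total + [sample] * int(dup.sum()))
            recs_umi.extend(umis + [u for u, d in zip(umis, dup) if d])
            recs_meth.extend(list(meth.astype(int)) +
                             [int(m) for m, d in zip(meth, dup) if d])
    return pd.DataFrame(
        {
            "cpg_id": recs_cpg,
            "sample_id": recs_sample,
            "umi": recs_umi,
            "methylated": recs_meth,
        }
    )


def default_diagnostic_config(seed: int = 0) -> CohortConfig:
    """The default two-class marker-recovery cohort.

    Five AML markers (mean 0.85 in AML vs 0.10 in normal, concentration 50)
    planted in a 729-CpG panel; 100 samples per class.
    """
    return CohortConfig(
        n_cpgs=729,
        n_per_class={"AML": 100, "normal": 100},
        marker_spec=[MarkerSpec("AML", 5, 0.85, 0.10, 50.0)],
        background_concentration=30.0,
        seed=seed,
    )


def default_prognostic_config(seed: int = 0, n_patients: int = 210) -> CohortConfig:
    """The default survival-recovery cohort.

    A single-disease cohort (AML-like) with 10 bimodal prognostic CpGs whose
    latent risk group carries a total log hazard ratio of 3.
    """
    return CohortConfig(
        n_cpgs=729,
        n_per_class={"AML": n_patients},
        marker_spec=[],
        prognostic_spec=PrognosticSpec(),
        background_concentration=30.0,
        seed=seed,
    )


def write_cohort(out_dir, beta, annotation, truth, surv=None) -> None:
    """Write the cohort artifacts as TSV/CSV/JSON under ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta.to_csv(out / "beta.tsv", sep="\t")
    annotation.to_csv(out / "annotation.csv", index=False)
    truth.to_json(out / "truth.json")
    if surv is not None:
        surv.to_csv(out / "survival.csv", index=False)
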