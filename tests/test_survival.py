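"""Cox scores, 2-means, log-rank, Kaplan-Meier and the survival classifier.

`lifelines` serves as the independent oracle for the Cox and log-rank
implementations; tiny instances are checked against hand-worked values and
exhaustive enumeration.
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from methleuk import survival as sv
from methleuk import synthetic_cohort as sc


class TestCoxScore:
    def test_constant_covariate_scores_zero(self, toy_surv):
        assert sv.cox_score(np.full(8, 0.5), toy_surv) == 0.0

    def test_matches_lifelines_wald_z(self, surv_cohort):
        from lifelines import CoxPHFitter

        surv, group = surv_cohort
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            np.vstack([group + rng.normal(0, 0.3, len(group)),
                       rng.uniform(0, 1, len(group))]),
            index=["signal", "noise"],
            columns=surv["sample_id"],
        )
        ours = sv.cox_scores(X, surv)
        for cpg in X.index:
            df = pd.DataFrame(
                {"T": surv["time"].values, "E": surv["event"].values,
                 "x": X.loc[cpg].values}
            )
            cph = CoxPHFitter()
            cph.fit(df, duration_col="T", event_col="E")
            z_ll = float(np.abs(cph.summary["z"].iloc[0]))
            assert ours[cpg] == pytest.approx(z_ll, rel=1e-3)

    def test_binary_covariate_matches_logrank_chisq(self, surv_cohort):
        surv, group = surv_cohort
        X = pd.DataFrame([group.astype(float)], index=["g"],
                         columns=surv["sample_id"])
        z = float(sv.cox_scores(X, surv).iloc[0])
        stat, _ = sv.logrank_test(surv, group)
        # classical asymptotic equivalence of score/Wald/log-rank
        assert z**2 == pytest.approx(stat, rel=0.15)

    def test_score_statistic_variant(self, surv_cohort):
        surv, group = surv_cohort
        X = pd.DataFrame([group.astype(float)], index=["g"],
                         columns=surv["sample_id"])
        z_score = float(sv.cox_scores(X, surv, statistic="score").iloc[0])
        stat, _ = sv.logrank_test(surv, group)
        # the partial-likelihood score test on a binary covariate IS the
        # log-rank statistic (up to tie handling)
        assert z_score**2 == pytest.approx(stat, rel=0.02)

    def test_no_events_rejected(self):
        surv = pd.DataFrame(
            {"sample_id": ["a", "b"], "time": [1.0, 2.0], "event": [0, 0]}
        )
        with pytest.raises(ValueError, match="event"):
            sv.cox_score(np.array([0.1, 0.9]), surv)


class TestRankAndGrid:
    def test_linear_interpolation_percentile_span(self):
        scores = pd.Series(np.arange(1.0, 101.0))
        grid = sv.rank_and_grid(scores)
        assert grid[0] == pytest.approx(90.1)
        assert grid[-1] == pytest.approx(100.0)
        assert len(grid) == 100
        assert np.diff(grid) == pytest.approx((100 - 90.1) / 99)

    def test_two_point_grid(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0])
        grid = sv.rank_and_grid(scores, n_points=2)
        assert grid[0] == pytest.approx(np.percentile(scores, 90))
        assert grid[1] == pytest.approx(10.0)

    def test_percentile_count_consistency(self):
        # selecting "score > P96" retains 4% of the CpGs (within rounding)
        rng = np.random.default_rng(2)
        for m in (100, 729, 1000):
            scores = pd.Series(np.abs(rng.normal(size=m)))
            cut = sv.CoxRanking(scores).percentile(96)
            n_above = int((scores > cut).sum())
            assert abs(n_above - int(np.ceil(0.04 * m))) <= 1

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sv.rank_and_grid(pd.Series([1.0, 1.0, 1.0]))


class TestTwoMeans:
    def brute_force_best_partition(self, P):
        """Exhaustive minimum-WSS 2-partition of rows of P."""
        n = len(P)
        best, best_wss = None, np.inf
        for bits in itertools.product([0, 1], repeat=n - 1):
            labels = np.array((0,) + bits)
            if labels.min() == labels.max():
                continue
            wss = sum(
                ((P[labels == k] - P[labels == k].mean(axis=0)) ** 2).sum()
                for k in (0, 1)
            )
            if wss < best_wss:
                best_wss, best = wss, labels
        return best, best_wss

    def test_matches_exhaustive_minimum_wss(self):
        rng = np.random.default_rng(3)
        for trial in range(12):
            n = int(rng.integers(4, 10))
            p = int(rng.integers(1, 4))
            P = rng.uniform(0, 1, (n, p))
            X = pd.DataFrame(P.T, columns=[f"p{i}" for i in range(n)])
            labels = sv.cluster_two_groups(X, seed=trial).values
            _, best_wss = self.brute_force_best_partition(P)
            got_wss = sum(
                ((P[labels == k] - P[labels == k].mean(axis=0)) ** 2).sum()
                for k in (0, 1)
            )
            assert got_wss == pytest.approx(best_wss)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        P = np.vstack([rng.normal(0, 0.05, (10, 3)), rng.normal(1, 0.05, (8, 3))])
        X = pd.DataFrame(P.T, columns=[f"p{i}" for i in range(18)])
        labels = sv.cluster_two_groups(X, seed=0).values
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_patients_consistent(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0, 1, (6, 2))
        X = pd.DataFrame(
            np.hstack([P.T, P.T]), columns=[f"p{i}" for i in range(12)]
        )
        labels = sv.cluster_two_groups(X, seed=1).values
        assert (labels[:6] == labels[6:]).all()

    def test_indistinct_profiles_rejected(self):
        X = pd.DataFrame(np.full((3, 5), 0.4), columns=[f"p{i}" for i in range(5)])
        with pytest.raises(ValueError, match="distinct"):
            sv.cluster_two_groups(X, seed=0)


class TestLogrank:
    def test_hand_worked_six_subjects(self):
        # group A: deaths at 1, 2, 3; group B: deaths at 10, 20, 30
        # accumulating O-E for B: -(0.5 + 0.6 + 0.75) + 3 - 3 = -1.85
        # V = 0.25 + 0.24 + 0.1875 = 0.6775 -> chi2 = 1.85^2 / 0.6775
        surv = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "time": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                "event": [1] * 6,
            }
        )
        stat, p = sv.logrank_test(surv, ["A", "A", "A", "B", "B", "B"])
        assert stat == pytest.approx(1.85**2 / 0.6775)
        assert 0 < p < 0.05

    def test_matches_lifelines(self, surv_cohort):
        from lifelines.statistics import logrank_test as ll_logrank

        surv, group = surv_cohort
        stat, p = sv.logrank_test(surv, group)
        res = ll_logrank(
            surv.loc[group == 0, "time"], surv.loc[group == 1, "time"],
            surv.loc[group == 0, "event"], surv.loc[group == 1, "event"],
        )
        assert stat == pytest.approx(res.test_statistic, rel=1e-6)
        assert p == pytest.approx(res.p_value, rel=1e-6)

    def test_proportional_event_split_zero_statistic(self):
        # both groups identical time/event patterns -> statistic 0
        surv = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "time": [5.0, 9.0, 5.0, 9.0],
                "event": [1, 1, 1, 1],
            }
        )
        stat, p = sv.logrank_test(surv, ["A", "A", "B", "B"])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self, toy_surv):
        with pytest.raises(ValueError, match="two non-empty groups"):
            sv.logrank_test(toy_surv, ["A"] * 8)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        surv = pd.DataFrame(
            {"sample_id": list("abc"), "time": [1.0, 2.0, 3.0], "event": [1, 1, 1]}
        )
        km = sv.kaplan_meier(surv)["all"]
        assert km.survival == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])
        assert km.times == pytest.approx([0.0, 1.0, 2.0, 3.0])

    def test_all_censored_flat(self):
        surv = pd.DataFrame(
            {"sample_id": list("abc"), "time": [1.0, 2.0, 3.0], "event": [0, 0, 0]}
        )
        km = sv.kaplan_meier(surv)["all"]
        assert km.survival == pytest.approx([1.0])
        assert km.median == np.inf

    def test_hand_worked_mixed_censoring(self, toy_surv):
        # events at 1,3,4,6,7 with censorings at 2,5,8:
        # S = 7/8, *5/6, *4/5, *2/3, *1/2
        km = sv.kaplan_meier(toy_surv)["all"]
        expected = [1.0, 7 / 8, 7 / 8 * 5 / 6, 7 / 8 * 5 / 6 * 4 / 5]
        expected += [expected[-1] * 2 / 3, expected[-1] * 2 / 3 * 1 / 2]
        assert km.survival == pytest.approx(expected)
        assert list(km.at_risk) == [8, 8, 6, 5, 3, 2]

    def test_matches_lifelines(self, surv_cohort):
        from lifelines import KaplanMeierFitter

        surv, _ = surv_cohort
        km = sv.kaplan_meier(surv)["all"]
        kmf = KaplanMeierFitter().fit(surv["time"], surv["event"])
        for t, s in zip(km.times[1:], km.survival[1:]):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_zero_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 40)
        surv = pd.DataFrame(
            {"sample_id": [f"p{i}" for i in range(40)], "time": t,
             "event": np.ones(40, dtype=int)}
        )
        km = sv.kaplan_meier(surv)["all"]
        for u, s in zip(km.times[1:], km.survival[1:]):
            assert s == pytest.approx((t > u).mean())


@pytest.fixture(scope="module")
def trained_model():
    cfg = sc.default_prognostic_config(seed=20, n_patients=150)
    beta, _, truth = sc.simulate_beta_cohort(cfg)
    surv = sc.simulate_survival(beta, truth, seed=20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sv.train_survival_classifier(beta, surv, seed=20)
    return beta, surv, truth, model


class TestSurvivalClassifier:
    def test_selected_exactly_above_cutoff(self, trained_model):
        beta, surv, truth, model = trained_model
        scores = model.cox_ranking.scores
        expected = sorted(scores.index[scores > model.cutoff])
        assert sorted(model.selected_cpgs) == expected

    def test_selected_count_nonincreasing_in_cutoff(self, trained_model):
        beta, surv, truth, model = trained_model
        scores = model.cox_ranking.scores
        grid = sv.rank_and_grid(model.cox_ranking)
        counts = [(scores > c).sum() for c in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bad_group_has_worse_survival(self, trained_model):
        beta, surv, truth, model = trained_model
        curves = sv.kaplan_meier(
            surv, model.cluster_labels.loc[surv["sample_id"]].values
        )
        t = min(c.times[-1] for c in curves.values())
        assert curves[sv.BAD].survival_at(t) < curves[sv.GOOD].survival_at(t)

    def test_group_naming_stable_under_relabel(self, trained_model):
        beta, surv, truth, model = trained_model
        labels01 = pd.Series(
            (model.cluster_labels == sv.BAD).astype(int).values,
            index=model.cluster_labels.index,
        )
        named = sv._name_groups(surv, labels01)
        flipped = sv._name_groups(surv, 1 - labels01)
        assert (named == flipped).all()

    def test_resubstitution_consistency(self, trained_model):
        beta, surv, truth, model = trained_model
        pred = sv.predict_risk_group(model, beta)
        agree = (pred.loc[model.cluster_labels.index] == model.cluster_labels).mean()
        assert agree > 0.9

    def test_training_logrank_significant(self, trained_model):
        _, _, _, model = trained_model
        assert model.logrank_p < 1e-6

    def test_signature_subset_of_selected(self, trained_model):
        _, _, _, model = trained_model
        assert set(model.signature_cpgs) <= set(model.selected_cpgs)
        assert len(model.signature_cpgs) >= 1

    def test_missing_cpgs_named_on_predict(self, trained_model):
        beta, _, _, model = trained_model
        dropped = model.selected_cpgs[0]
        with pytest.raises(KeyError, match=dropped):
            sv.predict_risk_group(model, beta.drop(index=dropped))

    def test_single_feasible_cutoff_grid(self):
        # two informative CpGs, tiny grid: the one feasible cutoff is chosen
        rng = np.random.default_rng(30)
        n = 40
        group = np.r_[np.zeros(20), np.ones(20)]
        X = pd.DataFrame(
            np.vstack(
                [np.where(group, 0.8, 0.2) + rng.normal(0, 0.05, n) for _ in range(2)]
                + [rng.uniform(0, 1, n) for _ in range(18)]
            ),
            index=[f"cg{i}" for i in range(20)],
            columns=[f"p{i}" for i in range(n)],
        )
        t = rng.exponential(1.0 / (0.02 * np.exp(2.0 * group)))
        surv = pd.DataFrame(
            {"sample_id": X.columns, "time": np.minimum(t, 60.0),
             "event": (t <= 60.0).astype(int)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sv.train_survival_classifier(X, surv, seed=0, n_points=2)
        assert model.cutoff in sv.rank_and_grid(model.cox_ranking, n_points=2)

    def test_model_json_roundtrip(self, tmp_path, trained_model):
        beta, _, _, model = trained_model
        path = str(tmp_path / "surv_model.json")
        model.to_json(path)
        back = sv.SurvivalClassifierModel.from_json(path)
        p1 = sv.predict_risk_group(model, beta)
        p2 = sv.predict_risk_group(back, beta)
        assert (p1 == p2).all()
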