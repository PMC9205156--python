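"""Classifier training, metrics, evaluation schemes, and sweeps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from strokefall.evaluation import (
    EvaluationError,
    compute_metrics,
    decision_scores,
    enumerate_severity_subgroups,
    feature_importance_report,
    lead_time_sweep,
    run_control_trained,
    run_logo_severity,
    run_loso_stroke,
    train_classifier,
)
from strokefall.feature_extraction import FEATURE_COLUMNS
from strokefall.synthetic_data import SubjectProfile


def toy_matrix(n_per_class=30, n_subjects=6, separation=6.0, seed=0, cohort="stroke"):
    """Two Gaussian clusters in feature space with subject structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        fall = i < n_per_class
        x = rng.normal(separation if fall else 0.0, 1.0, len(FEATURE_COLUMNS))
        rows.append(x)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.insert(0, "event_id", [f"e{i:03d}" for i in range(len(df))])
    df.insert(1, "subject_id", [f"s{i % n_subjects}" for i in range(len(df))])
    df["cohort"] = cohort
    df["activity_class"] = ["fall"] * n_per_class + ["non_fall"] * n_per_class
    df["subtype"] = ["lateral_fall"] * n_per_class + ["adl"] * n_per_class
    df["lead_time_ms"] = 75.0
    return df


class TestTrainClassifier:
    def test_separable_clusters_fit_perfectly(self):
        df = toy_matrix()
        model = train_classifier(df, seed=0)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        assert (model.predict(X) == (df["activity_class"] == "fall").to_numpy()).all()

    def test_single_class_rejected(self):
        df = toy_matrix()
        with pytest.raises(EvaluationError, match="single class"):
            train_classifier(df[df["activity_class"] == "fall"], seed=0)

    def test_deterministic_given_seed(self):
        df = toy_matrix(separation=1.0)
        probe = toy_matrix(separation=1.0, seed=9)
        s1 = decision_scores(train_classifier(df, seed=4), probe)
        s2 = decision_scores(train_classifier(df, seed=4), probe)
        assert np.array_equal(s1, s2)

    def test_permuted_labels_give_chance_auc(self):
        """Held-out AUC near 0.5 when labels carry no signal."""
        from sklearn.metrics import roc_auc_score

        aucs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            df = toy_matrix(n_per_class=40, separation=4.0, seed=rep)
            df["activity_class"] = rng.permutation(df["activity_class"].to_numpy())
            if df["activity_class"].nunique() < 2:
                continue
            train = df.iloc[: len(df) // 2]
            test = df.iloc[len(df) // 2 :]
            if train["activity_class"].nunique() < 2 or test["activity_class"].nunique() < 2:
                continue
            model = train_classifier(train, seed=rep)
            aucs.append(
                roc_auc_score(
                    (test["activity_class"] == "fall").to_numpy(), decision_scores(model, test)
                )
            )
        assert abs(np.mean(aucs) - 0.5) < 0.1


def brute_force_concordance(scores, truths):
    """Mann-Whitney AUC: P(score_fall > score_nonfall) + 0.5 ties."""
    pairs = [
        1.0 if sf > sn else (0.5 if sf == sn else 0.0)
        for sf, t1 in zip(scores, truths) if t1
        for sn, t0 in zip(scores, truths) if not t0
    ]
    return float(np.mean(pairs))


class TestComputeMetrics:
    def test_closed_form_counts(self):
        scores = [1.0] * 9 + [-1.0] + [-1.0] * 5
        pred = [True] * 9 + [False] + [False] * 5
        true = [True] * 10 + [False] * 5
        m = compute_metrics(scores, pred, true)
        assert m.recall == pytest.approx(0.9)
        assert m.precision == pytest.approx(1.0)
        assert m.f1 == pytest.approx(2 * 0.9 * 1.0 / 1.9)

    def test_f1_equals_p_when_recall_equals_precision(self):
        # tp=3, fn=1, fp=1 -> recall = precision = 0.75 -> f1 = 0.75
        scores = [1, 1, 1, 1, -1, -1]
        pred = [True, True, True, True, False, False]
        true = [True, True, True, False, True, False]
        m = compute_metrics(scores, pred, true)
        assert m.recall == m.precision == m.f1 == pytest.approx(0.75)

    def test_perfect_separation_auc_and_concordance(self):
        scores = [3.0, 2.5, 2.0, -1.0, -2.0, -3.0]
        true = [True, True, True, False, False, False]
        m = compute_metrics(scores, [s > 0 for s in scores], true)
        assert m.auc == 1.0
        assert m.auc == brute_force_concordance(scores, true)

    def test_auc_matches_concordance_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 50))
            true = rng.random(n) < 0.5
            if true.all() or not true.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties
            m = compute_metrics(scores, scores > 0, true)
            assert m.auc == pytest.approx(brute_force_concordance(scores, true))

    def test_undefined_metrics_flagged(self):
        m = compute_metrics([-1.0, -2.0], [False, False], [True, True])
        assert m.undefined.get("precision") and m.undefined.get("auc")
        assert not m.undefined.get("recall")
        assert m.recall == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics([], [], [])


class TestSchemes:
    def test_loso_iteration_structure(self, small_matrix):
        stroke = small_matrix[small_matrix["cohort"] == "stroke"]
        report = run_loso_stroke(stroke, seed=0)
        subjects = sorted(stroke["subject_id"].unique())
        assert report.iteration_ids() == subjects
        assert report.scheme == "loso_stroke"

    def test_duplicated_subjects_yield_identical_metrics(self):
        df = toy_matrix(n_per_class=20, n_subjects=1, seed=3)
        df2 = df.copy()
        df2["subject_id"] = "dup"
        df2["event_id"] = df2["event_id"] + "b"
        both = pd.concat([df, df2, toy_matrix(n_per_class=10, n_subjects=1, seed=4)
                          .assign(subject_id="s_other")], ignore_index=True)
        report = run_loso_stroke(both, seed=1)
        by_id = {it.test_unit_id: it for it in report.iterations}
        a, b = by_id["s0"], by_id["dup"]
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)
        assert a.auc == pytest.approx(b.auc)

    def test_control_trained_pairs_with_loso(self, small_matrix):
        stroke = small_matrix[small_matrix["cohort"] == "stroke"]
        control = small_matrix[small_matrix["cohort"] == "control"]
        loso = run_loso_stroke(stroke, seed=0)
        ctrl = run_control_trained(control, stroke, seed=0)
        assert ctrl.iteration_ids() == loso.iteration_ids()

    def test_high_separability_recall(self):
        """Near-noiseless vivid falls: LOSO mean recall >= 0.95."""
        from strokefall.feature_extraction import build_feature_matrix
        from strokefall.studies import high_separability_config
        from strokefall.synthetic_data import generate_cohort_dataset

        ds = generate_cohort_dataset(high_separability_config(11))
        matrix = build_feature_matrix(ds, 75.0, "both", seed=11)
        report = run_loso_stroke(matrix[matrix["cohort"] == "stroke"], seed=11)
        assert report.mean("recall") >= 0.95


def _profiles(n_unstable=5, n_stable=15):
    out = [SubjectProfile(f"u{i}", "stroke", "unstable", 1.0) for i in range(n_unstable)]
    out += [SubjectProfile(f"t{i}", "stroke", "stable", 1.0) for i in range(n_stable)]
    return out


class TestSeveritySubgroups:
    @pytest.mark.parametrize("k,expected", [(4, 75), (5, 1)])
    def test_exhaustive_counts_at_high_k(self, k, expected):
        groups = enumerate_severity_subgroups(_profiles(), k)
        assert len(groups) == expected
        assert len(set(groups)) == expected
        assert expected == math.comb(5, k) * math.comb(15, 5 - k)

    def test_sampled_when_combinations_exceed_cap(self):
        groups = enumerate_severity_subgroups(_profiles(), 2, max_groups=100, seed=3)
        assert math.comb(5, 2) * math.comb(15, 3) == 4550
        assert len(groups) == 100
        assert len(set(groups)) == 100
        unstable = {f"u{i}" for i in range(5)}
        for g in groups:
            assert len(g) == 5
            assert sum(s in unstable for s in g) == 2

    def test_sampled_groups_subset_of_exhaustive(self):
        all_groups = {
            tuple(sorted(u + s))
            for u in itertools.combinations([f"u{i}" for i in range(5)], 1)
            for s in itertools.combinations([f"t{i}" for i in range(15)], 4)
        }
        sampled = enumerate_severity_subgroups(_profiles(), 1, max_groups=50, seed=0)
        assert set(sampled) <= all_groups

    def test_infeasible_k_rejected(self):
        with pytest.raises(EvaluationError, match="infeasible"):
            enumerate_severity_subgroups(_profiles(n_unstable=2), 4)


class TestLogoSeverity:
    def test_no_subgroup_leakage_and_counts(self):
        from strokefall.feature_extraction import build_feature_matrix
        from strokefall.synthetic_data import DatasetConfig, generate_cohort_dataset

        ds = generate_cohort_dataset(
            DatasetConfig(n_control=3, n_stroke=8, n_unstable=2, repetitions=2, seed=13)
        )
        matrix = build_feature_matrix(ds, 75.0, "both", seed=13)
        stroke = matrix[matrix["cohort"] == "stroke"]
        control = matrix[matrix["cohort"] == "control"]
        logo = run_logo_severity(
            control, stroke, ds.profiles, seed=0, ks=(1, 2), max_groups=2,
        )
        for k, (ctrl_rep, stroke_rep) in logo.items():
            assert ctrl_rep.iteration_ids() == stroke_rep.iteration_ids()
            for gid in stroke_rep.iteration_ids():
                members = set(gid.split("+"))
                assert len(members) == 5
                n_unstable = sum(
                    p.severity == "unstable"
                    for p in ds.profiles
                    if p.subject_id in members
                )
                assert n_unstable == k


class TestLeadTimeSweep:
    def test_default_grid_has_seven_points(self, small_dataset):
        sweeps = lead_time_sweep(small_dataset, fall_subtype="ap", seed=0)
        for res in sweeps.values():
            assert len(res.mean_auc) == 7
            assert res.lead_times_ms == [50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0]

    def test_optimal_tie_breaks_to_smallest_lead(self):
        from strokefall.evaluation import LeadTimeSweepResult

        res = LeadTimeSweepResult(
            "m", [50.0, 100.0, 150.0], [1.0, 1.0, 0.9], [False] * 3
        )
        assert res.optimal_lead_time_ms == 50.0

    def test_negative_lead_rejected(self, small_dataset):
        with pytest.raises(EvaluationError):
            lead_time_sweep(small_dataset, grid=[-5.0], seed=0)


class TestFeatureImportance:
    def test_normalized_ranked_full_length(self):
        df = toy_matrix(separation=2.0)
        model = train_classifier(df, seed=0)
        report = feature_importance_report(model)
        assert len(report) == 126
        assert sum(w for _, w in report) == pytest.approx(1.0, abs=1e-9)
        weights = [w for _, w in report]
        assert weights == sorted(weights, reverse=True)

    def test_planted_informative_feature_ranked_first(self):
        rng = np.random.default_rng(5)
        df = toy_matrix(separation=0.0, seed=5)
        planted = FEATURE_COLUMNS[17]
        df[planted] = np.where(
            df["activity_class"] == "fall", 5.0, -5.0
        ) + rng.normal(0, 0.1, len(df))
        model = train_classifier(df, seed=0)
        assert feature_importance_report(model)[0][0] == planted

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import AdaBoostClassifier

        with pytest.raises(EvaluationError):
            feature_importance_report(AdaBoostClassifier())
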