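"""Cohort-dependent boosting classifiers and cross-validated evaluation.

Two identical adaptive-boosting ensembles (decision-tree base learners, 50
estimators, learning rate 1) are compared on their ability to pre-detect
falls of stroke-cohort subjects:

* stroke-trained — leave-one-subject-out (LOSO) over the stroke cohort;
* control-trained — one model fit on all control subjects, tested
  iteratively on each stroke subject so metrics pair 1:1 with LOSO;
* severity-stratified leave-one-group-out (LOGO) — five-subject stroke
  subgroups stratified by their count of unstable ambulators.

Per-iteration recall, precision, F1 and AUC-ROC are collected; metrics that
are undefined on an iteration (no predicted falls, or a single-class test
set for AUC) are flagged and excluded from means and downstream paired
tests rather than imputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_auc_score

from .feature_extraction import FEATURE_COLUMNS, build_feature_matrix
from .preprocessing import PreprocessedDataset, preprocess_dataset
from .synthetic_data import Dataset, SubjectProfile

N_ESTIMATORS = 50
LEARNING_RATE = 1.0
DEFAULT_LEAD_TIME_MS = 75.0
DEFAULT_LEAD_GRID_MS = (50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0)
METRICS = ("recall", "precision", "f1", "auc")

POSITIVE = "fall"


class EvaluationError(ValueError):
    pass


def _xy(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = matrix[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    y = (matrix["activity_class"] == POSITIVE).to_numpy()
    return X, y


def train_classifier(train_matrix: pd.DataFrame, seed: int) -> AdaBoostClassifier:
    """Fit the adaptive-boosting ensemble on a feature matrix."""
    X, y = _xy(train_matrix)
    if len(np.unique(y)) < 2:
        raise EvaluationError("training data contains a single class")
    model = AdaBoostClassifier(
        n_estimators=N_ESTIMATORS, learning_rate=LEARNING_RATE, random_state=seed
    )
    model.fit(X, y)
    return model


def decision_scores(model: AdaBoostClassifier, matrix: pd.DataFrame) -> np.ndarray:
    """Continuous decision score (margin for the fall class)."""
    X = matrix[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    return model.decision_function(X)


@dataclass
class IterationMetrics:
    test_unit_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision: float
    f1: float
    auc: float
    undefined: dict[str, bool] = field(default_factory=dict)

    def value(self, metric: str) -> float:
        if self.undefined.get(metric, False):
            return float("nan")
        return getattr(self, metric)


def compute_metrics(
    scores: Sequence[float],
    predicted_labels: Sequence[bool],
    true_labels: Sequence[bool],
    test_unit_id: str = "",
) -> IterationMetrics:
    """Recall, precision, F1 and AUC-ROC for one test iteration.

    Recall = detected falls / true falls; precision = detected falls /
    predicted falls; F1 is their harmonic mean; AUC is computed from the
    continuous scores (trapezoidal ROC with tied thresholds sharing a
    point).  Metrics whose denominator is empty — precision with no
    predicted falls, AUC on a single-class test set — are flagged
    undefined, as is F1 when either component is.
    """
    s = np.asarray(scores, dtype=float)
    p = np.asarray(predicted_labels, dtype=bool)
    t = np.asarray(true_labels, dtype=bool)
    if not (len(s) == len(p) == len(t)):
        raise EvaluationError("scores, predictions and labels must align")
    if len(s) == 0:
        raise EvaluationError("empty test iteration")

    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    undefined: dict[str, bool] = {}

    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined["recall"] = float("nan"), True
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined["precision"] = float("nan"), True
    if not undefined.get("recall") and not undefined.get("precision") and recall + precision > 0:
        f1 = 2 * recall * precision / (recall + precision)
    elif undefined.get("recall") or undefined.get("precision"):
        f1, undefined["f1"] = float("nan"), True
    else:
        f1 = 0.0
    if t.any() and (~t).any():
        auc = float(roc_auc_score(t, s))
    else:
        auc, undefined["auc"] = float("nan"), True
    return IterationMetrics(test_unit_id, tp, fp, fn, tn, recall, precision, f1, auc, undefined)


@dataclass
class EvaluationReport:
    scheme: str
    iterations: list[IterationMetrics]
    config: dict = field(default_factory=dict)

    def iteration_ids(self) -> list[str]:
        return [it.test_unit_id for it in self.iterations]

    def values(self, metric: str) -> np.ndarray:
        """Per-iteration values with undefined iterations as NaN."""
        if metric not in METRICS:
            raise EvaluationError(f"unknown metric {metric!r}")
        return np.array([it.value(metric) for it in self.iterations])

    def mean(self, metric: str) -> float:
        vals = self.values(metric)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    def sd(self, metric: str) -> float:
        vals = self.values(metric)
        vals = vals[~np.isnan(vals)]
        return float(vals.std(ddof=1)) if vals.size > 1 else float("nan")

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in METRICS:
            vals = self.values(m)
            rows.append(
                {
                    "metric": m,
                    "mean": self.mean(m),
                    "sd": self.sd(m),
                    "n_defined": int(np.sum(~np.isnan(vals))),
                    "n_iterations": len(self.iterations),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            row = {
                "test_unit_id": it.test_unit_id,
                "tp": it.tp,
                "fp": it.fp,
                "fn": it.fn,
                "tn": it.tn,
            }
            for m in METRICS:
                row[m] = it.value(m)
            rows.append(row)
        return pd.DataFrame(rows)


def _assert_no_leakage(train: pd.DataFrame, test: pd.DataFrame) -> None:
    overlap = set(train["subject_id"]) & set(test["subject_id"])
    if overlap:
        raise EvaluationError(f"subject-level leakage: {sorted(overlap)}")


def _evaluate_on(model: AdaBoostClassifier, test: pd.DataFrame, unit_id: str) -> IterationMetrics:
    scores = decision_scores(model, test)
    pred = model.predict(test[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64))
    true = (test["activity_class"] == POSITIVE).to_numpy()
    return compute_metrics(scores, pred, true, unit_id)


def run_loso_stroke(stroke_matrix: pd.DataFrame, seed: int) -> EvaluationReport:
    """Leave-one-subject-out over the stroke cohort: each subject is held
    out once while every other stroke subject trains the model."""
    subjects = sorted(stroke_matrix["subject_id"].unique())
    if len(subjects) < 3:
        raise EvaluationError("LOSO requires at least 3 stroke subjects")
    iterations = []
    for sid in subjects:
        train = stroke_matrix[stroke_matrix["subject_id"] != sid]
        test = stroke_matrix[stroke_matrix["subject_id"] == sid]
        _assert_no_leakage(train, test)
        model = train_classifier(train, seed)
        iterations.append(_evaluate_on(model, test, sid))
    return EvaluationReport("loso_stroke", iterations, {"seed": seed})


def run_control_trained(
    control_matrix: pd.DataFrame, stroke_matrix: pd.DataFrame, seed: int
) -> EvaluationReport:
    """One model fit on all control subjects, tested per stroke subject.

    Iteration ids match :func:`run_loso_stroke` so the two reports pair
    1:1 for the paired statistics.
    """
    if control_matrix.empty or stroke_matrix.empty:
        raise EvaluationError("both cohort matrices must be non-empty")
    _assert_no_leakage(control_matrix, stroke_matrix)
    model = train_classifier(control_matrix, seed)
    iterations = []
    for sid in sorted(stroke_matrix["subject_id"].unique()):
        test = stroke_matrix[stroke_matrix["subject_id"] == sid]
        iterations.append(_evaluate_on(model, test, sid))
    return EvaluationReport("control_trained", iterations, {"seed": seed})


GROUP_SIZE = 5


def enumerate_severity_subgroups(
    stroke_profiles: Sequence[SubjectProfile],
    k_unstable: int,
    max_groups: int = 100,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Unique 5-subject stroke subgroups with exactly ``k_unstable``
    unstable ambulators.

    All combinations are returned when their number is at most
    ``max_groups``; otherwise ``max_groups`` are sampled without
    replacement (seeded).
    """
    unstable = sorted(p.subject_id for p in stroke_profiles if p.severity == "unstable")
    stable = sorted(p.subject_id for p in stroke_profiles if p.severity == "stable")
    if not 0 <= k_unstable <= GROUP_SIZE:
        raise EvaluationError("k_unstable must be between 0 and 5")
    if k_unstable > len(unstable) or GROUP_SIZE - k_unstable > len(stable):
        raise EvaluationError(
            f"k={k_unstable} infeasible with {len(unstable)} unstable / {len(stable)} stable"
        )
    total = math.comb(len(unstable), k_unstable) * math.comb(len(stable), GROUP_SIZE - k_unstable)
    groups = [
        tuple(sorted(u + s))
        for u in itertools.combinations(unstable, k_unstable)
        for s in itertools.combinations(stable, GROUP_SIZE - k_unstable)
    ]
    assert len(groups) == total
    if total <= max_groups:
        return groups
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=max_groups, replace=False)
    return [groups[i] for i in sorted(idx)]


def run_logo_severity(
    control_matrix: pd.DataFrame,
    stroke_matrix: pd.DataFrame,
    profiles: Sequence[SubjectProfile],
    seed: int = 0,
    ks: Sequence[int] = (0, 1, 2, 3, 4, 5),
    max_groups: int = 100,
) -> dict[int, tuple[EvaluationReport, EvaluationReport]]:
    """Severity-stratified LOGO: for each subgroup, the stroke-trained model
    trains on the stroke subjects outside the subgroup and the control-
    trained model on all controls; both test on the subgroup.

    Returns ``{k: (control_report, stroke_report)}`` with matching
    iteration ids per k.
    """
    stroke_profiles = [p for p in profiles if p.cohort == "stroke"]
    control_model = train_classifier(control_matrix, seed)
    out: dict[int, tuple[EvaluationReport, EvaluationReport]] = {}
    for k in ks:
        groups = enumerate_severity_subgroups(stroke_profiles, k, max_groups, seed + k)
        ctrl_iters, stroke_iters = [], []
        for group in groups:
            gid = "+".join(group)
            test = stroke_matrix[stroke_matrix["subject_id"].isin(group)]
            if test.empty:
                raise EvaluationError(f"subgroup {gid} has no feature rows")
            train = stroke_matrix[~stroke_matrix["subject_id"].isin(group)]
            _assert_no_leakage(train, test)
            stroke_model = train_classifier(train, seed)
            ctrl_iters.append(_evaluate_on(control_model, test, gid))
            stroke_iters.append(_evaluate_on(stroke_model, test, gid))
        out[k] = (
            EvaluationReport("logo_severity_control", ctrl_iters, {"k": k, "seed": seed}),
            EvaluationReport("logo_severity_stroke", stroke_iters, {"k": k, "seed": seed}),
        )
    return out


@dataclass
class LeadTimeSweepResult:
    model: str
    lead_times_ms: list[float]
    mean_auc: list[float]
    infeasible: list[bool]

    @property
    def optimal_lead_time_ms(self) -> float:
        """Argmax of mean AUC; ties resolve to the smallest lead time."""
        aucs = np.asarray(self.mean_auc)
        if np.all(np.isnan(aucs)):
            raise EvaluationError("no feasible grid point")
        best = np.nanmax(aucs)
        for t_l, auc in sorted(zip(self.lead_times_ms, aucs)):
            if not np.isnan(auc) and auc >= best - 1e-12:
                return t_l
        raise AssertionError("unreachable")


def lead_time_sweep(
    dataset: Dataset | PreprocessedDataset,
    fall_subtype: str = "ap",
    nonfall_filter: str = "both",
    grid: Sequence[float] = DEFAULT_LEAD_GRID_MS,
    seed: int = 0,
) -> dict[str, LeadTimeSweepResult]:
    """Re-run the full pipeline per lead time and collect mean AUC curves
    for the control-trained and stroke-trained (LOSO) models.

    A lead time at which no fall window is extractable is flagged
    infeasible (NaN AUC) rather than silently dropped.
    """
    if any(g < 0 for g in grid):
        raise EvaluationError("lead times must be non-negative")
    pre = dataset if isinstance(dataset, PreprocessedDataset) else preprocess_dataset(dataset)
    results: dict[str, list] = {"control_trained": [], "stroke_trained": []}
    infeasible: list[bool] = []
    for t_l in grid:
        matrix = build_feature_matrix(pre, t_l, nonfall_filter, seed, fall_subtype)
        stroke = matrix[matrix["cohort"] == "stroke"]
        control = matrix[matrix["cohort"] == "control"]
        if not (stroke["activity_class"] == POSITIVE).any():
            infeasible.append(True)
            results["control_trained"].append(float("nan"))
            results["stroke_trained"].append(float("nan"))
            continue
        infeasible.append(False)
        ctrl_report = run_control_trained(control, stroke, seed)
        loso_report = run_loso_stroke(stroke, seed)
        results["control_trained"].append(ctrl_report.mean("auc"))
        results["stroke_trained"].append(loso_report.mean("auc"))
    return {
        name: LeadTimeSweepResult(name, [float(g) for g in grid], aucs, list(infeasible))
        for name, aucs in results.items()
    }


def feature_importance_report(
    model: AdaBoostClassifier, feature_names: Sequence[str] = FEATURE_COLUMNS
) -> list[tuple[str, float]]:
    """Importances normalized to sum to 1, descending, ties broken by name."""
    if not hasattr(model, "feature_importances_"):
        raise EvaluationError("model is not fitted")
    imp = np.asarray(model.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise EvaluationError("feature name count does not match the model")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return sorted(zip(feature_names, imp.tolist()), key=lambda kv: (-kv[1], kv[0]))
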