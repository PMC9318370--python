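"""Patient-disjoint evaluation harness for the AF/SR classifiers.

Responsibilities owned here: the per-database 2/3 patient split, the
metaparameter grid search by stratified 5-fold cross-validation on the
training segments, blindfold validation on segments from entirely held-out
patients (with a hard leakage guard), diagnostic metrics (accuracy,
sensitivity, specificity, PPV, diagnostic odds ratio), and the full
experiment matrix over 7 classifier families x 1..6-feature prefix sets x
{cv5, blindfold} x {full pool, pool without pRR50}.

The classifier families themselves come from scikit-learn behind a uniform
fit/predict contract; scale-sensitive families (KNN, SVM, ANN) are wrapped
with a z-score standardizer fitted on training folds only.  AF is the
positive class throughout.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._errors import LeakageError
from .ranking import RankingResult, ranked_prefixes

log = logging.getLogger(__name__)

POSITIVE_CLASS = "AF"
FAMILIES = ("DT", "KNN", "SVM_linear", "SVM_RBF", "ADA", "RF", "ANN")


# ---------------------------------------------------------------------------
# patient split


@dataclass
class SplitAssignment:
    seed: int
    train_patients: set[tuple[str, str]]  # (patient_id, database_tag)
    test_patients: set[tuple[str, str]]
    train_fraction: float = 2.0 / 3.0

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise LeakageError("train and test patient sets overlap")


def split_by_patient(manifest: pd.DataFrame, train_fraction: float = 2.0 / 3.0,
                     seed: int = 0) -> SplitAssignment:
    """Seeded per-database split of patients into train/test sets.

    For each database tag, ``round(train_fraction * n)`` patients are drawn
    without replacement into the training set.  Requires at least 3
    patients per database so both sides are non-empty.
    """
    rng = np.random.default_rng(seed)
    train, test = set(), set()
    for db, grp in manifest.groupby("database_tag", sort=True):
        pids = sorted(grp["patient_id"].astype(str).unique())
        if len(pids) < 3:
            raise ValueError(f"database {db!r} has fewer than 3 patients")
        n_train = int(round(train_fraction * len(pids)))
        n_train = min(max(n_train, 1), len(pids) - 1)
        chosen = rng.choice(len(pids), size=n_train, replace=False)
        chosen_set = {pids[i] for i in chosen}
        for pid in pids:
            (train if pid in chosen_set else test).add((pid, str(db)))
    return SplitAssignment(seed=seed, train_patients=train, test_patients=test,
                           train_fraction=train_fraction)


def table_split(table: pd.DataFrame, split: SplitAssignment,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a feature table's rows by the patient split."""
    keys = list(zip(table["patient_id"].astype(str), table["database_tag"].astype(str)))
    in_train = np.array([k in split.train_patients for k in keys])
    in_test = np.array([k in split.test_patients for k in keys])
    return table[in_train].reset_index(drop=True), table[in_test].reset_index(drop=True)


# ---------------------------------------------------------------------------
# classifier specs


@dataclass
class ClassifierSpec:
    family: str
    build: Callable[[dict, int], object]   # params, seed -> estimator
    grid: list[dict]                       # declared order = tie-break order
    scaling: bool

    def estimator(self, params: dict, seed: int):
        est = self.build(params, seed)
        if self.scaling:
            return make_pipeline(StandardScaler(), est)
        return est


def default_classifier_specs(*, compact: bool = False) -> dict[str, ClassifierSpec]:
    """The seven classifier families with their metaparameter grids.

    ``compact=True`` substitutes small grids (for structural tests and quick
    smoke runs); the defaults are the full search ranges.
    """
    def grid1(name, values):
        return [{name: v} for v in values]

    depths = [4, 10, 16] if compact else list(range(2, 21))
    ks = [1, 5, 15] if compact else list(range(1, 52, 2))
    cs = [0.1, 1.0] if compact else [0.01, 0.1, 1.0, 10.0, 100.0]
    gammas = [0.1, 1.0] if compact else [0.001, 0.01, 0.1, 1.0, 10.0]
    rf_depths = [4, 10] if compact else list(range(4, 17))
    rf_trees = [50] if compact else [50, 100, 200]
    ada_n = [25, 50] if compact else [25, 50, 100, 200]
    ann_h = [8, 32] if compact else [4, 8, 16, 32, 64]

    return {
        "DT": ClassifierSpec(
            "DT", lambda p, s: DecisionTreeClassifier(max_depth=p["max_depth"], random_state=s),
            grid1("max_depth", depths), scaling=False),
        "KNN": ClassifierSpec(
            "KNN", lambda p, s: KNeighborsClassifier(n_neighbors=p["n_neighbors"]),
            grid1("n_neighbors", ks), scaling=True),
        "SVM_linear": ClassifierSpec(
            "SVM_linear", lambda p, s: SVC(kernel="linear", C=p["C"], random_state=s),
            grid1("C", cs), scaling=True),
        "SVM_RBF": ClassifierSpec(
            "SVM_RBF", lambda p, s: SVC(kernel="rbf", C=p["C"], gamma=p["gamma"], random_state=s),
            [{"C": c, "gamma": g} for c in cs for g in gammas], scaling=True),
        "ADA": ClassifierSpec(
            "ADA", lambda p, s: AdaBoostClassifier(n_estimators=p["n_estimators"], random_state=s),
            grid1("n_estimators", ada_n), scaling=False),
        "RF": ClassifierSpec(
            "RF", lambda p, s: RandomForestClassifier(
                max_depth=p["max_depth"], n_estimators=p["n_estimators"], random_state=s),
            [{"max_depth": d, "n_estimators": n} for d in rf_depths for n in rf_trees],
            scaling=False),
        "ANN": ClassifierSpec(
            "ANN", lambda p, s: MLPClassifier(
                hidden_layer_sizes=(p["hidden_units"],), activation="relu",
                max_iter=600, random_state=s),
            grid1("hidden_units", ann_h), scaling=True),
    }


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive: str = POSITIVE_CLASS) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with AF as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, fp, tn, fn


def diagnostic_odds_ratio(tp: float, fp: float, tn: float, fn: float,
                          correction: str = "haldane") -> float:
    """(TP*TN)/(FP*FN); DOR = 1 means no diagnostic information.

    With a zero cell: ``haldane`` adds 0.5 to every cell (keeping the ratio
    finite), ``strict`` returns NaN.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if min(tp, fp, tn, fn) == 0:
        if correction == "haldane":
            tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
        elif correction == "strict":
            return float("nan")
        else:
            raise ValueError(f"unknown DOR correction {correction!r}")
    return (tp * tn) / (fp * fn)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        dor_correction: str = "haldane") -> dict[str, float]:
    total = tp + fp + tn + fn
    return {
        "accuracy_pct": 100.0 * (tp + tn) / total if total else float("nan"),
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "ppv_pct": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "dor": diagnostic_odds_ratio(tp, fp, tn, fn, dor_correction),
    }


# ---------------------------------------------------------------------------
# tuning and blindfold evaluation


@dataclass
class TuningResult:
    family: str
    chosen_params: dict
    fold_accuracies: list[float]
    cv_counts: tuple[int, int, int, int]   # pooled out-of-fold confusion
    grid_mean_accuracies: list[float] = field(repr=False, default_factory=list)

    @property
    def cv_accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def cv_accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def _fold_indices(y: np.ndarray, k_folds: int, seed: int):
    counts = pd.Series(y).value_counts()
    if counts.min() < k_folds:
        raise ValueError("a class has fewer segments than folds; cannot stratify")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def tune_classifier(spec: ClassifierSpec, train_table: pd.DataFrame,
                    feature_set: Sequence[str], *, k_folds: int = 5,
                    seed: int = 0) -> TuningResult:
    """Grid search by stratified k-fold CV on training segments.

    Scaling (when the family needs it) is fitted on the k-1 training folds
    only.  The grid point with the highest mean fold accuracy wins; ties go
    to the earlier point in declared grid order.  Fold accuracies and the
    pooled out-of-fold confusion counts of the winner are reported.
    """
    X = train_table[list(feature_set)].to_numpy(dtype=float)
    y = train_table["rhythm_class"].to_numpy()
    folds = _fold_indices(y, k_folds, seed)

    grid_means: list[float] = []
    per_point_accs: list[list[float]] = []
    for params in spec.grid:
        accs = []
        for tr, va in folds:
            est = spec.estimator(params, seed)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[va]) == y[va])))
        per_point_accs.append(accs)
        grid_means.append(float(np.mean(accs)))
    best = int(np.argmax(grid_means))  # first max in declared order
    best_params = spec.grid[best]

    # recompute out-of-fold predictions of the winner for confusion counts
    y_pred = np.empty(len(y), dtype=object)
    for tr, va in folds:
        est = spec.estimator(best_params, seed)
        est.fit(X[tr], y[tr])
        y_pred[va] = est.predict(X[va])
    return TuningResult(spec.family, dict(best_params), per_point_accs[best],
                        confusion_counts(y, y_pred), grid_means)


def assert_patient_disjoint(train_table: pd.DataFrame, test_table: pd.DataFrame) -> None:
    a = set(zip(train_table["patient_id"].astype(str), train_table["database_tag"].astype(str)))
    b = set(zip(test_table["patient_id"].astype(str), test_table["database_tag"].astype(str)))
    overlap = a & b
    if overlap:
        raise LeakageError(f"patients present in both fit and evaluation data: {sorted(overlap)}")


def evaluate_blindfold(spec: ClassifierSpec, params: dict,
                       train_table: pd.DataFrame, test_table: pd.DataFrame,
                       feature_set: Sequence[str], *, seed: int = 0,
                       dor_correction: str = "haldane") -> dict:
    """Fit on the full training split; predict every held-out segment.

    Aborts with :class:`LeakageError` if any patient appears on both sides.
    """
    assert_patient_disjoint(train_table, test_table)
    X_tr = train_table[list(feature_set)].to_numpy(dtype=float)
    y_tr = train_table["rhythm_class"].to_numpy()
    X_te = test_table[list(feature_set)].to_numpy(dtype=float)
    y_te = test_table["rhythm_class"].to_numpy()
    est = spec.estimator(params, seed)
    est.fit(X_tr, y_tr)
    tp, fp, tn, fn = confusion_counts(y_te, est.predict(X_te))
    out = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    out.update(metrics_from_counts(tp, fp, tn, fn, dor_correction))
    return out


# ---------------------------------------------------------------------------
# experiment matrix


def run_experiment_matrix(table: pd.DataFrame, split: SplitAssignment,
                          rankings: dict[str, RankingResult],
                          specs: dict[str, ClassifierSpec] | None = None, *,
                          k_max: int = 6,
                          modes: Iterable[str] = ("cv5", "blindfold"),
                          seed: int = 0, k_folds: int = 5,
                          dor_correction: str = "haldane") -> pd.DataFrame:
    """The full evaluation cross product, one report row per cell.

    ``rankings`` maps pool names (e.g. ``full``, ``no_pRR50``) to rankings
    computed on the training split.  Each (family x k x pool) cell is tuned
    independently by k-fold CV; the chosen metaparameters are then reused
    for the blindfold row, mirroring tune-then-validate.
    """
    specs = specs or default_classifier_specs()
    modes = list(modes)
    train_table, test_table = table_split(table, split)
    if "blindfold" in modes:
        assert_patient_disjoint(train_table, test_table)

    rows = []
    for pool_name, ranking in rankings.items():
        if ranking is None:
            raise ValueError(f"missing ranking for pool {pool_name!r}")
        prefixes = ranked_prefixes(ranking, min(k_max, len(ranking.pool)))
        for family, spec in specs.items():
            for k, feats in enumerate(prefixes, start=1):
                tuning = tune_classifier(spec, train_table, feats,
                                         k_folds=k_folds, seed=seed)
                base = {
                    "family": family, "n_features": k, "pool": pool_name,
                    "features": ";".join(feats),
                    "chosen_params": json.dumps(tuning.chosen_params, sort_keys=True),
                    "cv_accuracy_mean_pct": 100.0 * tuning.cv_accuracy_mean,
                    "cv_accuracy_sd_pct": 100.0 * tuning.cv_accuracy_sd,
                }
                if "cv5" in modes:
                    tp, fp, tn, fn = tuning.cv_counts
                    row = dict(base, mode="cv5", TP=tp, FP=fp, TN=tn, FN=fn)
                    row.update(metrics_from_counts(tp, fp, tn, fn, dor_correction))
                    rows.append(row)
                if "blindfold" in modes:
                    res = evaluate_blindfold(spec, tuning.chosen_params,
                                             train_table, test_table, feats,
                                             seed=seed, dor_correction=dor_correction)
                    rows.append(dict(base, mode="blindfold", **res))
                log.info("evaluated %s k=%d pool=%s", family, k, pool_name)
    cols = ["family", "n_features", "mode", "pool", "features", "TP", "FP",
            "TN", "FN", "accuracy_pct", "sensitivity_pct", "specificity_pct",
            "ppv_pct", "dor", "cv_accuracy_mean_pct", "cv_accuracy_sd_pct",
            "chosen_params"]
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "POSITIVE_CLASS", "FAMILIES", "SplitAssignment", "split_by_patient",
    "table_split", "ClassifierSpec", "default_classifier_specs",
    "confusion_counts", "diagnostic_odds_ratio", "metrics_from_counts",
    "TuningResult", "tune_classifier", "assert_patient_disjoint",
    "evaluate_blindfold", "run_experiment_matrix",
]
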