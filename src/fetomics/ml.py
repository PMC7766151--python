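"""Radiomics classification workflow.

Patient-grouped stratified 70/30 split of the augmented feature table (every
patient's three segmentation rows stay on one side), recursive feature
elimination with random-forest importances down to at most four features,
random-forest training with a small hyperparameter grid selected by
patient-grouped 5-fold cross-validated accuracy, and evaluation on the
untouched test rows.  Rows are sorted canonically before any fit, so results
depend only on the table content and the seeds, not on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import GroupKFold

from .stats import POSITIVE, ClassificationMetrics

__all__ = [
    "SplitSpec",
    "SelectionConfig",
    "ModelReport",
    "split_cohort",
    "select_features",
    "fit_and_evaluate",
    "run_pipeline",
]

_KEY_COLUMNS = ("patient_id", "segmentation_threshold", "label")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    group_by_patient: bool = True  # augmented rows never straddle the split
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.group_by_patient:
            raise ValueError("patient grouping is mandatory (augmentation leaks otherwise)")


@dataclass(frozen=True)
class SelectionConfig:
    max_features: int = 4
    cv_folds: int = 5
    n_trees: int = 100
    seed: int = 0
    rfe_step: float = 0.1  # fraction of features eliminated per round
    #: (n_estimators, max_depth) candidates, tried in order
    grid: tuple[tuple[int, int | None], ...] = ((100, None), (100, 5), (500, None), (500, 5))

    def __post_init__(self) -> None:
        if self.max_features > 4:
            raise ValueError("max_features is capped at 4 to limit overfitting")


@dataclass
class ModelReport:
    selected_features: list[str]
    classifier: str
    classifier_params: dict
    train_metrics: ClassificationMetrics
    test_metrics: ClassificationMetrics
    n_train_rows: int
    n_test_rows: int

    def as_dict(self) -> dict:
        from . import __version__

        return {
            "version": __version__,
            "selected_features": self.selected_features,
            "classifier": self.classifier,
            "classifier_params": self.classifier_params,
            "train_metrics": self.train_metrics.as_dict(),
            "test_metrics": self.test_metrics.as_dict(),
            "n_train_rows": self.n_train_rows,
            "n_test_rows": self.n_test_rows,
        }


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _KEY_COLUMNS]


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(["patient_id", "segmentation_threshold"]).reset_index(drop=True)


def split_cohort(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-grouped stratified split of the augmented table.

    Per class, round((1 - train_fraction) * n_patients) patients go to the
    test side; with the 18/16 cohort this yields 24 training patients
    (72 rows) and 10 test patients (5 per class, 30 rows).
    """
    spec = spec or SplitSpec()
    counts = table.groupby("patient_id").size()
    if not (counts == 3).all():
        raise ValueError("expected exactly 3 augmented rows per patient")
    rng = np.random.default_rng(spec.seed)
    test_patients: list = []
    per_patient = table.drop_duplicates("patient_id")[["patient_id", "label"]]
    for label in sorted(per_patient["label"].unique()):
        pats = sorted(per_patient.loc[per_patient["label"] == label, "patient_id"])
        n_test = int(round((1.0 - spec.train_fraction) * len(pats)))
        order = rng.permutation(len(pats))
        test_patients += [pats[i] for i in order[:n_test]]
    in_test = table["patient_id"].isin(test_patients)
    train, test = table[~in_test], table[in_test]
    overlap = set(train["patient_id"]) & set(test["patient_id"])
    if overlap:
        raise ValueError(f"patient grouping violated: {sorted(overlap)}")
    return _canonical(train), _canonical(test)


def _rf(config: SelectionConfig, n_estimators=None, max_depth=None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators or config.n_trees,
        max_depth=max_depth,
        random_state=config.seed,
        n_jobs=1,
    )


def select_features(
    train_table: pd.DataFrame, config: SelectionConfig | None = None
) -> list[str]:
    """Recursive feature elimination (RF importance) down to <= max_features."""
    config = config or SelectionConfig()
    train = _canonical(train_table)
    cols = feature_columns(train)
    if len(cols) <= config.max_features:
        return cols
    X = train[cols].to_numpy(dtype=float)
    y = (train["label"] == POSITIVE).to_numpy()
    rfe = RFE(_rf(config), n_features_to_select=config.max_features, step=config.rfe_step)
    rfe.fit(X, y)
    return [c for c, keep in zip(cols, rfe.support_) if keep]


def _metrics_from(y_true, y_pred, scores=None) -> ClassificationMetrics:
    m = ClassificationMetrics.from_predictions(y_true, y_pred)
    if scores is not None and 0 < y_true.sum() < y_true.size:
        from scipy.stats import rankdata

        ranks = rankdata(scores)
        n1 = int(y_true.sum())
        n2 = int(y_true.size - n1)
        u = ranks[y_true].sum() - n1 * (n1 + 1) / 2.0
        m.auc = float(u / (n1 * n2))
    return m


def fit_and_evaluate(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    features: list[str],
    config: SelectionConfig | None = None,
    aggregate: str = "row",
) -> ModelReport:
    """Grid-select, fit and test the random forest on the chosen features.

    Training metrics come from the pooled hold-out predictions of the
    patient-grouped 5-fold cross-validation of the winning configuration;
    test metrics from a single application to the untouched test rows.
    ``aggregate='patient'`` majority-votes the three augmented rows per test
    patient instead of scoring rows individually.
    """
    config = config or SelectionConfig()
    if aggregate not in ("row", "patient"):
        raise ValueError("aggregate must be 'row' or 'patient'")
    train = _canonical(train_table)
    test = _canonical(test_table)
    X = train[features].to_numpy(dtype=float)
    y = (train["label"] == POSITIVE).to_numpy()
    groups = train["patient_id"].to_numpy()

    cv = GroupKFold(n_splits=config.cv_folds)
    best = None
    for n_est, depth in config.grid:
        preds = np.zeros(y.size, dtype=bool)
        probs = np.zeros(y.size)
        for tr_idx, ho_idx in cv.split(X, y, groups):
            clf = _rf(config, n_est, depth).fit(X[tr_idx], y[tr_idx])
            preds[ho_idx] = clf.predict(X[ho_idx])
            probs[ho_idx] = clf.predict_proba(X[ho_idx])[:, list(clf.classes_).index(True)]
        acc = float((preds == y).mean())
        if best is None or acc > best[0]:
            best = (acc, (n_est, depth), preds.copy(), probs.copy())
    _, (n_est, depth), cv_preds, cv_probs = best
    train_metrics = _metrics_from(y, cv_preds, cv_probs)

    model = _rf(config, n_est, depth).fit(X, y)
    Xt = test[features].to_numpy(dtype=float)
    yt = (test["label"] == POSITIVE).to_numpy()
    pt = model.predict(Xt)
    st = model.predict_proba(Xt)[:, list(model.classes_).index(True)]
    if aggregate == "patient":
        df = pd.DataFrame(
            {"pid": test["patient_id"], "y": yt, "p": pt, "s": st}
        ).groupby("pid").agg({"y": "first", "p": lambda v: v.sum() >= 2, "s": "mean"})
        yt, pt, st = df["y"].to_numpy(), df["p"].to_numpy(), df["s"].to_numpy()
    test_metrics = _metrics_from(yt, pt, st)

    return ModelReport(
        selected_features=list(features),
        classifier="random_forest",
        classifier_params={"n_estimators": n_est, "max_depth": depth,
                           "random_state": config.seed},
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        n_train_rows=len(train),
        n_test_rows=len(test),
    )


def run_pipeline(
    feature_table: pd.DataFrame,
    split: SplitSpec | None = None,
    config: SelectionConfig | None = None,
    aggregate: str = "row",
) -> ModelReport:
    """Split, select features on the training side only, fit and evaluate."""
    train, test = split_cohort(feature_table, split)
    features = select_features(train, config)
    return fit_and_evaluate(train, test, features, config, aggregate=aggregate)
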