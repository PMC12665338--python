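"""Random-forest classification of subjects from TOI + SOI features.

The classifier mirrors a fixed, deliberately small model: 100 trees, Gini
splitting, depth 4, min 2 samples to split / 1 per leaf, sqrt feature
subsampling, bootstrap on, fixed random state.  Subjects are split 80/20
(stratified) into training and held-out validation; the training cohort is
evaluated with stratified 5-fold cross-validation.  Feature selection
removes the least Gini-important feature one round at a time, keeping the
reduced set only while fold-averaged accuracy does not degrade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

log = logging.getLogger(__name__)

DEFAULT_HYPERPARAMETERS = dict(
    n_estimators=100,
    criterion="gini",
    max_depth=4,
    min_samples_split=2,
    min_samples_leaf=1,
    max_features="sqrt",
    bootstrap=True,
)


@dataclass
class FeatureMatrix:
    """Named feature columns with aligned binary labels.

    ``positive_class`` is the patient group (for bvFTD-vs-ALS-FTD tasks,
    bvFTD is treated as positive).  Subjects with missing values are
    dropped, never imputed silently (logged).
    """

    X: pd.DataFrame
    y: pd.Series
    positive_class: str

    def __post_init__(self):
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and labels must share an index")
        bad = self.X.isna().any(axis=1) | self.y.isna()
        if bad.any():
            log.info("FeatureMatrix: dropping %d subjects with missing values",
                     int(bad.sum()))
            self.X = self.X[~bad]
            self.y = self.y[~bad]
        if self.positive_class not in set(self.y):
            raise ValueError(f"positive class {self.positive_class!r} absent from labels")


@dataclass
class ForestResult:
    """Fold-averaged metrics, held-out metrics and the importance ranking."""

    cv_accuracy: float
    cv_sensitivity: float
    cv_specificity: float
    importances: pd.Series
    fold_accuracies: list = field(default_factory=list)
    validation_accuracy: float | None = None
    validation_sensitivity: float | None = None
    validation_specificity: float | None = None

    @property
    def ranking(self) -> list[str]:
        return list(self.importances.sort_values(ascending=False).index)


def _make_forest(seed: int, hyperparameters=None) -> RandomForestClassifier:
    hp = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        hp.update(hyperparameters)
    return RandomForestClassifier(random_state=seed, **hp)


def split_cohort(features: FeatureMatrix, seed: int, validation_fraction=0.2):
    """Stratified 80/20 train/validation split, deterministic given seed."""
    counts = features.y.value_counts()
    if (counts < 5).any():
        raise ValueError("each class needs >= 5 subjects for an 80/20 split")
    idx_train, idx_val = train_test_split(
        features.X.index, test_size=validation_fraction, random_state=seed,
        stratify=features.y)
    log.info("split_cohort: train %s validation %s",
             features.y.loc[idx_train].value_counts().to_dict(),
             features.y.loc[idx_val].value_counts().to_dict())
    train = FeatureMatrix(features.X.loc[idx_train], features.y.loc[idx_train],
                          features.positive_class)
    val = FeatureMatrix(features.X.loc[idx_val], features.y.loc[idx_val],
                        features.positive_class)
    return train, val


def _metrics(y_true, y_pred, positive):
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    acc = (tp + tn) / max(len(y_true), 1)
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return acc, sens, spec


def train_eval_cv(train: FeatureMatrix, seed: int, k_folds: int = 5,
                  hyperparameters=None,
                  validation: FeatureMatrix | None = None) -> ForestResult:
    """Stratified k-fold cross-validated fit of the fixed random forest.

    Per fold the model fits on k-1 folds and is evaluated on the held-out
    fold; accuracy, sensitivity and specificity (patient class positive) are
    fold-averaged.  Gini importances are averaged across fold models and
    renormalized to sum to 1.  When a held-out ``validation`` cohort is
    given the final model (fit on all training rows) is also evaluated
    there, labeled separately.
    """
    y = train.y.to_numpy()
    if min(np.unique(y, return_counts=True)[1]) < k_folds:
        raise ValueError(f"smallest class has fewer than {k_folds} members; "
                         "stratified folds impossible")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs, sens, specs, imps = [], [], [], []
    xv = train.X.to_numpy()
    for tr, te in skf.split(xv, y):
        clf = _make_forest(seed, hyperparameters)
        clf.fit(xv[tr], y[tr])
        a, s, sp = _metrics(y[te], clf.predict(xv[te]), train.positive_class)
        accs.append(a)
        sens.append(s)
        specs.append(sp)
        imps.append(clf.feature_importances_)
    imp = np.mean(imps, axis=0)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    result = ForestResult(
        cv_accuracy=float(np.mean(accs)),
        cv_sensitivity=float(np.mean(sens)),
        cv_specificity=float(np.mean(specs)),
        importances=pd.Series(imp, index=train.X.columns, name="gini_importance"),
        fold_accuracies=[float(a) for a in accs],
    )
    if validation is not None:
        clf = _make_forest(seed, hyperparameters)
        clf.fit(xv, y)
        a, s, sp = _metrics(validation.y.to_numpy(),
                            clf.predict(validation.X.to_numpy()),
                            train.positive_class)
        result.validation_accuracy = float(a)
        result.validation_sensitivity = float(s)
        result.validation_specificity = float(sp)
    return result


def gini_eliminate(train: FeatureMatrix, seed: int, k_folds: int = 5,
                   tolerance: float = 0.0, min_features: int = 2,
                   hyperparameters=None):
    """Iterative Gini-importance-based backward feature elimination.

    Each round drops the single least-important feature and refits with CV;
    the reduced set is kept iff fold-averaged accuracy is at least the
    previous accuracy minus ``tolerance``.  Stops when a drop degrades
    accuracy or ``min_features`` remain.  Returns
    ``(final FeatureMatrix, final ForestResult, audit trail DataFrame)``.
    Terminates in at most ``n_features`` rounds.
    """
    current = train
    result = train_eval_cv(current, seed, k_folds, hyperparameters)
    trail = [dict(round=0, n_features=current.X.shape[1],
                  cv_accuracy=result.cv_accuracy, dropped=None, kept=True)]
    rnd = 0
    while current.X.shape[1] > min_features:
        rnd += 1
        weakest = result.importances.idxmin()
        reduced = FeatureMatrix(current.X.drop(columns=[weakest]), current.y,
                                current.positive_class)
        cand = train_eval_cv(reduced, seed, k_folds, hyperparameters)
        keep = cand.cv_accuracy >= result.cv_accuracy - tolerance
        trail.append(dict(round=rnd, n_features=reduced.X.shape[1],
                          cv_accuracy=cand.cv_accuracy, dropped=weakest, kept=keep))
        if not keep:
            break
        current, result = reduced, cand
    return current, result, pd.DataFrame(trail)


def build_feature_matrix(tfas_values: pd.DataFrame, volumes: pd.DataFrame,
                         cohort: pd.DataFrame, task: tuple[str, str]) -> FeatureMatrix:
    """Join TOI mean-FA and SOI volume features for one pairwise task.

    ``task`` is (positive group, negative group); baseline rows only.
    Feature columns are prefixed ``FA:`` and ``VOL:``.
    """
    cohort = cohort.set_index("subject") if "subject" in cohort.columns else cohort
    base = cohort[cohort.timepoint == "baseline"]
    ids = base.index[base.group.isin(task)]
    fa = tfas_values.add_prefix("FA:")
    vol = volumes.add_prefix("VOL:")
    x = fa.join(vol, how="inner")
    x = x.loc[x.index.intersection(ids)]
    y = base.loc[x.index, "group"]
    return FeatureMatrix(x, y, positive_class=task[0])
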