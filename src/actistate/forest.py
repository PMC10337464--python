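"""Independent per-week random-forest classifier.

Each patient-week's 105-slot feature vector (15 features x 7 days) is
classified into the PRO's ordinal state independently of neighboring
weeks.  The forest serves two roles: a baseline model in its own right,
and the source of per-state posterior probabilities that the forward
filter Bayes-inverts into emission scores.

Hyperparameters default to the study values: 100 trees, Gini splitting,
maximum depth 25, minimum 10 samples to split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import RfSpec
from .preprocess import WeeklyObservations, slot_columns

__all__ = ["RfSpec", "RfEmissionModel", "train_rf", "predict_posterior", "feature_importance"]


@dataclass
class RfEmissionModel:
    """A fitted forest plus the state space it predicts over.

    ``predict_posterior`` always returns vectors over all ``n_states``
    states, with zero mass on classes absent from training (downstream
    flooring handles those).
    """

    clf: RandomForestClassifier
    n_states: int
    features: list[str]

    @property
    def slots(self) -> list[str]:
        return slot_columns(self.features)


def train_rf(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    n_states: int,
    spec: RfSpec | None = None,
    features: Sequence[str] | None = None,
) -> RfEmissionModel:
    """Fit the per-week forest on imputed, non-dropped training weeks.

    Raises on NaN features (imputation is upstream) and on a single-class
    training set (no posterior can be learned).
    """
    spec = spec or RfSpec()
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=int)
    if Xa.ndim != 2 or len(Xa) != len(ya):
        raise ValueError("X must be 2-D with one row per training label")
    if not np.isfinite(Xa).all():
        raise ValueError("training features contain missing values; impute first")
    classes = np.unique(ya)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single state ({classes.tolist()}); "
            "cannot fit a classifier"
        )
    if classes.min() < 0 or classes.max() >= n_states:
        raise ValueError("training states fall outside 0..n_states-1")
    clf = RandomForestClassifier(
        n_estimators=spec.n_estimators,
        criterion=spec.criterion,
        max_depth=spec.max_depth,
        min_samples_split=spec.min_samples_split,
        random_state=spec.seed,
    )
    clf.fit(Xa, ya)
    if features is None:
        n_feat = Xa.shape[1] // 7
        features = [f"f{i + 1}" for i in range(n_feat)]
    return RfEmissionModel(clf=clf, n_states=n_states, features=list(features))


def predict_posterior(model: RfEmissionModel, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-state posterior probabilities, shape (n_weeks, n_states).

    The baseline forest prediction is the argmax of each row (ties break
    toward the lower state index).
    """
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(Xa).all():
        raise ValueError("feature vector contains missing values; impute first")
    proba = model.clf.predict_proba(Xa)
    out = np.zeros((len(Xa), model.n_states))
    out[:, model.clf.classes_] = proba
    return out


def rf_predict(model: RfEmissionModel, X) -> np.ndarray:
    """Argmax state per week, lowest index on ties."""
    return np.argmax(predict_posterior(model, X), axis=1)


def feature_importance(model: RfEmissionModel) -> pd.DataFrame:
    """Per-feature impurity importance, day columns summed.

    Slot-level Gini importances are summed over each feature's 7 day
    columns and renormalized to sum to 1, then sorted descending —
    yielding the 15-row ranked importance table.
    """
    imp = model.clf.feature_importances_
    n_feat = len(model.features)
    if imp.size != 7 * n_feat:
        raise ValueError("model importances do not match 7 slots per feature")
    per_feature = imp.reshape(n_feat, 7).sum(axis=1)
    total = per_feature.sum()
    if total > 0:
        per_feature = per_feature / total
    tbl = pd.DataFrame({"feature": model.features, "importance": per_feature})
    return tbl.sort_values("importance", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def training_matrix(
    weekly: WeeklyObservations, rows: pd.Series | np.ndarray | None = None
) -> np.ndarray:
    """Extract the 105-slot design matrix (optionally row-masked)."""
    df = weekly.data if rows is None else weekly.data[rows]
    return df[weekly.slots].to_numpy(dtype=float)
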