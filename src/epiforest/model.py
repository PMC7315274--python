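"""Random-forest immunogenicity classifier, repeated CV, ROC, model bundle.

The classifier is a random forest over the assembled feature table
(antigen mode: 24 features, mtry 15; neoantigen mode: 27 features,
mtry 14; 500 trees).  Its score for a record is the fraction of trees
voting immunogenic, banded into three categories:

* positive-high — score > 0.5 (predicted immunogenic),
* positive-low  — 0.4 <= score <= 0.5 (borderline),
* negative-high — score < 0.4 (predicted non-immunogenic).

Generalization is estimated by repeated stratified 5-fold cross-validation
(3 repeats): out-of-fold scores are pooled within a repeat, an AUC is
computed per repeat, and the reported AUC is the mean over repeats.  AUC
uses the rank-sum (Mann-Whitney) formulation with ties counted half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from hashlib import sha256
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import ANTIGEN_FEATURES, NEOANTIGEN_FEATURES, FrequencyModel
from .peptides import POSITIVE

SCHEMA_VERSION = 1

POSITIVE_HIGH = "positive-high"
POSITIVE_LOW = "positive-low"
NEGATIVE_HIGH = "negative-high"

#: default score bands: [0, 0.4) negative-high, [0.4, 0.5] positive-low,
#: (0.5, 1] positive-high
DEFAULT_THRESHOLDS = (0.4, 0.5)

DEFAULT_MTRY = {"antigen": 15, "neoantigen": 14}
MODE_FEATURES = {
    "antigen": list(ANTIGEN_FEATURES),
    "neoantigen": list(NEOANTIGEN_FEATURES),
}


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank-sum (Mann-Whitney) formulation.

    Equals (number of concordant positive/negative pairs + half the tied
    pairs) / (n_pos * n_neg).  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binarize(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires scores from both classes")
    ranks = rankdata(scores)  # mid-ranks: ties contribute half a pair each
    rank_sum_pos = ranks[y == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting."""
    y = _binarize(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _binarize(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def categorize(scores, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Band scores into negative-high / positive-low / positive-high.

    The boundaries are closed into the middle band: a score of exactly 0.4
    or 0.5 is positive-low.
    """
    low, high = thresholds
    scores = np.asarray(scores, dtype=float)
    out = np.where(scores > high, POSITIVE_HIGH,
                   np.where(scores >= low, POSITIVE_LOW, NEGATIVE_HIGH))
    return out.astype(object)


class ImmunogenicityClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest classifier over the assembled feature table.

    scikit-learn estimator: ``fit(X, y)`` on a feature DataFrame (or
    array) and string or 0/1 labels; ``predict_score`` returns the
    fraction of trees voting immunogenic, ``predict_category`` the banded
    call, and ``predict`` the binary label at the upper threshold.

    Parameters
    ----------
    mode : {"antigen", "neoantigen"}
        Chooses the default mtry (15 / 14).
    mtry : int or None
        Number of features tried per split; None uses the mode default,
        capped at the number of available features.
    n_trees : int, default 500
        Forest size.
    class_weight : None or "balanced"
        Optional reweighting for imbalanced corpora (off by default).
    thresholds : (low, high), default (0.4, 0.5)
        Score-band boundaries.
    random_state : int or None
        Seed for forest construction.
    """

    def __init__(
        self,
        mode: str = "antigen",
        mtry: int | None = None,
        n_trees: int = 500,
        class_weight: str | None = None,
        thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
        random_state: int | None = None,
    ) -> None:
        self.mode = mode
        self.mtry = mtry
        self.n_trees = n_trees
        self.class_weight = class_weight
        self.thresholds = thresholds
        self.random_state = random_state

    def fit(self, X, y) -> "ImmunogenicityClassifier":
        if self.mode not in DEFAULT_MTRY:
            raise ValueError(f"mode must be 'antigen' or 'neoantigen', got {self.mode!r}")
        X_arr, names = _as_feature_array(X)
        y_bin = _binarize(y)
        if len(np.unique(y_bin)) < 2:
            raise ValueError("training requires records of both classes")
        mtry = self.mtry if self.mtry is not None else DEFAULT_MTRY[self.mode]
        mtry = min(mtry, X_arr.shape[1])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=mtry,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X_arr, y_bin)
        self.feature_names_ = names
        self.classes_ = self.forest_.classes_
        self.mtry_ = mtry
        return self

    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X_arr, names = _as_feature_array(X)
        if names is not None and self.feature_names_ is not None:
            missing = [f for f in self.feature_names_ if f not in names]
            extra = [f for f in names if f not in self.feature_names_]
            if missing or extra:
                raise ValueError(
                    f"feature schema mismatch: missing {missing}, unexpected {extra}"
                )
            X_arr = pd.DataFrame(X_arr, columns=names)[self.feature_names_].to_numpy()
        return X_arr

    def predict_proba(self, X) -> np.ndarray:
        return self.forest_.predict_proba(self._validate_X(X))

    def predict_score(self, X) -> np.ndarray:
        """Fraction of trees voting immunogenic, in [0, 1]."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def predict_category(self, X) -> np.ndarray:
        return categorize(self.predict_score(X), self.thresholds)

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) > self.thresholds[1]).astype(int)


def _as_feature_array(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.asarray(X, dtype=float), None


@dataclass
class CVResult:
    """Out-of-fold scores and summary metrics of repeated stratified CV.

    ``oof`` has one row per record per repeat with columns repeat, fold,
    id, label, score.  ``fold_aucs`` is indexed by (repeat, fold);
    ``repeat_aucs`` pools out-of-fold scores within each repeat; ``auc``
    is their mean.  Sensitivity and specificity are evaluated at the
    upper score threshold on the pooled scores.
    """

    oof: pd.DataFrame
    fold_aucs: pd.Series
    repeat_aucs: pd.Series
    auc: float
    sensitivity: float
    specificity: float
    n_splits: int
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        return self.oof


def repeated_cv(
    estimator: ImmunogenicityClassifier,
    X: pd.DataFrame,
    y,
    n_splits: int = 5,
    n_repeats: int = 3,
    random_state: int | None = None,
    score_threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold out-of-fold evaluation.

    Each record is scored exactly once per repeat by a forest that never
    saw it; fold models are clones of ``estimator`` seeded deterministically
    from ``random_state``.
    """
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    y_bin = _binarize(y)
    n_min = np.bincount(y_bin).min() if len(np.unique(y_bin)) == 2 else 0
    if len(y_bin) < 5 * n_splits or n_min < n_splits:
        raise ValueError(
            f"dataset too small for {n_repeats}x{n_splits}-fold CV: "
            f"{len(y_bin)} records, minority class {n_min}"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=random_state
    )
    seed_seq = np.random.SeedSequence(random_state)
    fold_seeds = seed_seq.generate_state(n_splits * n_repeats) % (2**31 - 1)

    rows = []
    fold_aucs = {}
    ids = np.asarray(X_df.index)
    for i, (train_idx, test_idx) in enumerate(splitter.split(X_df, y_bin)):
        repeat, fold = divmod(i, n_splits)
        model = clone(estimator)
        model.set_params(random_state=int(fold_seeds[i]))
        model.fit(X_df.iloc[train_idx], y_bin[train_idx])
        scores = model.predict_score(X_df.iloc[test_idx])
        fold_aucs[(repeat, fold)] = roc_auc(scores, y_bin[test_idx])
        for j, idx in enumerate(test_idx):
            rows.append((repeat, fold, ids[idx], int(y_bin[idx]), float(scores[j])))

    oof = pd.DataFrame(rows, columns=["repeat", "fold", "id", "label", "score"])
    repeat_aucs = (
        oof.groupby("repeat")
        .apply(lambda g: roc_auc(g["score"], g["label"]), include_groups=False)
        .rename("auc")
    )
    pooled = oof  # all repeats pooled for the operating-point metrics
    pred_pos = pooled["score"] > score_threshold
    is_pos = pooled["label"] == 1
    sensitivity = float((pred_pos & is_pos).sum() / max(is_pos.sum(), 1))
    specificity = float((~pred_pos & ~is_pos).sum() / max((~is_pos).sum(), 1))
    return CVResult(
        oof=oof,
        fold_aucs=pd.Series(fold_aucs).rename_axis(["repeat", "fold"]).rename("auc"),
        repeat_aucs=repeat_aucs,
        auc=float(repeat_aucs.mean()),
        sensitivity=sensitivity,
        specificity=specificity,
        n_splits=n_splits,
        n_repeats=n_repeats,
    )


class BundleSchemaError(RuntimeError):
    """Raised when loading a model archive with an incompatible schema."""


@dataclass
class ModelBundle:
    """The persisted prediction artifact.

    Carries the fitted classifier, the frequency model snapshot used to
    assemble its features, the (post-selection) feature list, the mode,
    score thresholds and the master seed, plus free-form metadata
    (training date, data fingerprint).  Saved as a directory with a
    serialized forest (``model.joblib``) and JSON metadata
    (``bundle.json``); loading refuses a schema-version mismatch.
    """

    classifier: ImmunogenicityClassifier
    frequency_model: FrequencyModel
    feature_names: list[str]
    mode: str
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Score a feature table; returns id, score and category columns."""
        missing = [f for f in self.feature_names if f not in features.columns]
        extra = [c for c in features.columns if c not in self.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {missing}, unexpected {extra}"
            )
        scores = self.classifier.predict_score(features[self.feature_names])
        return pd.DataFrame(
            {
                "id": features.index.astype(str),
                "score": scores,
                "category": categorize(scores, self.thresholds),
            }
        ).reset_index(drop=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {"classifier": self.classifier, "frequency_model": self.frequency_model},
            path / "model.joblib",
        )
        meta = {
            "schema_version": SCHEMA_VERSION,
            "mode": self.mode,
            "feature_names": self.feature_names,
            "thresholds": list(self.thresholds),
            "seed": self.seed,
            "metadata": self.metadata,
        }
        (path / "bundle.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads((path / "bundle.json").read_text())
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise BundleSchemaError(
                f"model archive schema version {meta.get('schema_version')} is not "
                f"supported (expected {SCHEMA_VERSION}); retrain the model"
            )
        payload = joblib.load(path / "model.joblib")
        return cls(
            classifier=payload["classifier"],
            frequency_model=payload["frequency_model"],
            feature_names=list(meta["feature_names"]),
            mode=meta["mode"],
            thresholds=tuple(meta["thresholds"]),
            seed=meta["seed"],
            metadata=meta["metadata"],
        )


def data_fingerprint(features: pd.DataFrame, labels) -> str:
    """Stable content hash of a training table, recorded in bundle metadata."""
    h = sha256()
    h.update(features.round(12).to_csv().encode())
    h.update(np.asarray(labels).astype(str).tobytes())
    return h.hexdigest()[:16]


def train(
    features: pd.DataFrame,
    labels,
    mode: str,
    frequency_model: FrequencyModel,
    mtry: int | None = None,
    n_trees: int = 500,
    seed: int | None = None,
    n_splits: int = 5,
    n_repeats: int = 3,
    class_weight: str | None = None,
    feature_names: Sequence[str] | None = None,
    record_date: bool = True,
) -> tuple[ModelBundle, CVResult]:
    """Cross-validate and fit the final model on the full table.

    Out-of-fold performance comes from repeated stratified CV; the bundled
    forest is then refit on all data with the same hyperparameters.
    """
    if feature_names is not None:
        features = features[list(feature_names)]
    estimator = ImmunogenicityClassifier(
        mode=mode, mtry=mtry, n_trees=n_trees,
        class_weight=class_weight, random_state=seed,
    )
    cv = repeated_cv(estimator, features, labels, n_splits=n_splits,
                     n_repeats=n_repeats, random_state=seed)
    final = clone(estimator).fit(features, labels)
    metadata = {"data_fingerprint": data_fingerprint(features, labels),
                "n_records": int(len(features)),
                "cv_auc": cv.auc}
    if record_date:
        metadata["date"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    bundle = ModelBundle(
        classifier=final,
        frequency_model=frequency_model,
        feature_names=list(features.columns),
        mode=mode,
        thresholds=final.thresholds,
        seed=seed,
        metadata=metadata,
    )
    return bundle, cv
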