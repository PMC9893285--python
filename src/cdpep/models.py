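"""Composition-based classifier panel, training protocol, persistence.

Eight classifier families are supported over the 20-dimensional AAC
feature vector: decision tree (dt), random forest (rf), logistic
regression (lr), gradient-boosted trees (xgb), k-nearest neighbours
(knn), Gaussian naive Bayes (gnb), extremely randomized trees (et, the
deployed default) and a linear-kernel-free SVC (svc).  Hyperparameters
are sensible fixed defaults, recorded with the saved model.

The evaluation protocol is a stratified 80:20 hold-out; the training
report is the unweighted mean over five stratified cross-validation folds
of the 80% portion, after which the model is refit on the full 80% and
scored once on the held-out 20%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .features import FEATURE_SPEC, AACTransformer
from .metrics import MetricsReport, auroc, compute_metrics, confusion, make_split, mean_report
from .sequences import PeptideDataset

MODEL_FORMAT_VERSION = 1

CLASSIFIER_KINDS = ("dt", "rf", "lr", "xgb", "knn", "gnb", "et", "svc")

#: Default deployed classifier: extremely randomized trees, the panel's
#: strongest member on composition features.
DEFAULT_KIND = "et"


def _base_estimator(kind: str, random_state: int):
    if kind == "dt":
        # leaf-size floor so a single tree emits graded probabilities
        # rather than memorized 0/1 leaves
        return DecisionTreeClassifier(min_samples_leaf=10, random_state=random_state)
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=500, random_state=random_state, n_jobs=1
        )
    if kind == "lr":
        return LogisticRegression(max_iter=2000, random_state=random_state)
    if kind == "xgb":
        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.3,
            random_state=random_state,
            n_jobs=1,
            eval_metric="logloss",
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if kind == "gnb":
        return GaussianNB()
    if kind == "et":
        return ExtraTreesClassifier(
            n_estimators=500, random_state=random_state, n_jobs=1
        )
    if kind == "svc":
        return SVC(kernel="rbf", random_state=random_state)
    raise ValueError(
        f"unknown classifier kind {kind!r}; valid kinds: {', '.join(CLASSIFIER_KINDS)}"
    )


class CompositionClassifier(BaseEstimator, ClassifierMixin):
    """A classifier over raw peptide strings via AAC features.

    Parameters
    ----------
    kind : str, default "et"
        One of ``dt, rf, lr, xgb, knn, gnb, et, svc``.
    score_threshold : float, default 0.5
        Decision threshold on the class-1 score (label = score >= threshold).
    random_state : int, default 0

    Attributes
    ----------
    estimator_ : fitted underlying sklearn/xgboost estimator.
    classes_ : ndarray ``[0, 1]``.
    score_range_ : (min, max) of training decision values, kept only for
        estimators without ``predict_proba`` (min-max scaling to [0, 1]).
    """

    def __init__(
        self,
        kind: str = DEFAULT_KIND,
        score_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.kind = kind
        self.score_threshold = score_threshold
        self.random_state = random_state

    def fit(self, X: Sequence[str], y):
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self._transformer = AACTransformer()
        F = self._transformer.transform(X)
        self.estimator_ = _base_estimator(self.kind, self.random_state)
        self.estimator_.fit(F, y)
        self.classes_ = np.array([0, 1])
        if not hasattr(self.estimator_, "predict_proba"):
            d = self.estimator_.decision_function(F)
            lo, hi = float(d.min()), float(d.max())
            self.score_range_ = (lo, hi if hi > lo else lo + 1.0)
        else:
            self.score_range_ = None
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """Class-1 score in [0, 1]: a probability where the underlying
        estimator provides one, otherwise a min-max-scaled decision value.
        """
        check_is_fitted(self, "estimator_")
        F = AACTransformer().transform(X)
        if self.score_range_ is None:
            return self.estimator_.predict_proba(F)[:, 1]
        lo, hi = self.score_range_
        return np.clip((self.estimator_.decision_function(F) - lo) / (hi - lo), 0, 1)

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.decision_function(X) >= self.score_threshold).astype(int)


@dataclass
class EvaluationResult:
    model: CompositionClassifier
    training: MetricsReport  # five-fold CV mean on the 80% portion
    validation: MetricsReport  # single evaluation on the held-out 20%


def _evaluate(model: CompositionClassifier, seqs, y) -> MetricsReport:
    scores = model.decision_function(seqs)
    preds = (scores >= model.score_threshold).astype(int)
    return compute_metrics(confusion(y, preds), auroc=auroc(y, scores.tolist()))


def train_and_evaluate(
    dataset: PeptideDataset, kind: str = DEFAULT_KIND, seed: int = 0
) -> EvaluationResult:
    """Run the full protocol for one classifier kind.

    Stratified 80:20 split; five-fold CV on the training portion (metric
    means reported as the training performance, at the model's 0.5 score
    threshold); refit on the full training portion; one evaluation on the
    held-out 20%.  Deterministic given (dataset, kind, seed).
    """
    _base_estimator(kind, 0)  # validate kind early
    y_all = dataset.y()
    for cls in (0, 1):
        if y_all.count(cls) < 10:
            raise ValueError("need at least 10 items per class")
    plan = make_split(dataset, seed)
    by_id = {r.id: (r.sequence, yv) for r, yv in zip(dataset, y_all)}

    fold_reports = []
    train_set = set(plan.train_ids)
    for fold in plan.folds:
        fold_set = set(fold)
        tr = [i for i in plan.train_ids if i not in fold_set]
        model = CompositionClassifier(kind=kind, random_state=seed)
        model.fit([by_id[i][0] for i in tr], [by_id[i][1] for i in tr])
        fold_reports.append(
            _evaluate(model, [by_id[i][0] for i in fold], [by_id[i][1] for i in fold])
        )
    training = mean_report(fold_reports)

    final = CompositionClassifier(kind=kind, random_state=seed)
    final.fit(
        [by_id[i][0] for i in plan.train_ids],
        [by_id[i][1] for i in plan.train_ids],
    )
    validation = _evaluate(
        final,
        [by_id[i][0] for i in plan.validation_ids],
        [by_id[i][1] for i in plan.validation_ids],
    )
    return EvaluationResult(final, training, validation)


def predict_scores(
    model: CompositionClassifier, peptides: PeptideDataset
) -> list[tuple[str, float, str]]:
    """(id, class-1 score, label) per peptide, order preserved."""
    scores = model.decision_function(peptides.sequences())
    return [
        (rid, float(s), "positive" if s >= model.score_threshold else "negative")
        for rid, s in zip(peptides.ids(), scores)
    ]


def save_model(model, path) -> None:
    """Persist a fitted model as a single-file bundle with format version,
    classifier kind, hyperparameters, feature spec and score threshold.
    """
    bundle = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_spec": FEATURE_SPEC,
        "params": model.get_params(deep=False),
        "model": model,
    }
    joblib.dump(bundle, Path(path))


def load_model(path):
    try:
        bundle = joblib.load(Path(path))
    except Exception as exc:  # corrupted / not a joblib file
        raise ValueError(f"{path}: not a readable model bundle ({exc})") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ValueError(f"{path}: not a model bundle")
    if bundle["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {bundle['format_version']} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    return bundle["model"]
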