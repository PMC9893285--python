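"""Motif-first ensemble: motif hit asserts positive, ML decides the rest.

The two-tier rule: if a query contains any motif from the ensemble's
motif set it is called positive outright (provenance "motif", recording
the first matching motif in set order); only motif-free queries fall
through to the composition classifier (provenance "ML").  Motifs can only
assert positives — there is no negative-motif veto.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import DEFAULT_KIND, CompositionClassifier
from .motifs import (
    DEFAULT_MOTIFS,
    CoverageTable,
    Motif,
    coverage_table,
    discover_motifs,
    first_match,
)
from .sequences import PeptideDataset


@dataclass(frozen=True)
class EnsemblePrediction:
    id: str
    label: str  # "positive" / "negative"
    provenance: str  # "motif" / "ML"
    matched_motif: Optional[str] = None
    ml_score: Optional[float] = None


class MotifEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ordered motif set + trained composition classifier + score threshold.

    Parameters
    ----------
    motifs : sequence of str or Motif, or None
        The motif tier.  None (default) uses the curated published set;
        the empty-ish sentinel ``"discover"`` runs class-exclusive
        discovery on the training data at fit time.
    classifier_kind : str, default "et"
        Kind of the composition-classifier tier.
    ml_threshold : float, default 0.5
        Score threshold of the ML tier.
    random_state : int, default 0

    Attributes
    ----------
    motifs_ : list of str
        The fitted motif tier, ordered by positive support on the
        training data (descending, ties lexicographic) — the attribution
        order used for coverage reporting.
    ml_model_ : fitted CompositionClassifier.
    """

    def __init__(
        self,
        motifs=None,
        classifier_kind: str = DEFAULT_KIND,
        ml_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.motifs = motifs
        self.classifier_kind = classifier_kind
        self.ml_threshold = ml_threshold
        self.random_state = random_state

    def fit(self, X: Sequence[str], y):
        y = np.asarray(y, dtype=int)
        pos = [s for s, yv in zip(X, y) if yv == 1]
        neg = [s for s, yv in zip(X, y) if yv == 0]
        if self.motifs == "discover":
            from .sequences import PeptideRecord

            pos_ds = PeptideDataset(
                [PeptideRecord(f"p{i}", s, "positive") for i, s in enumerate(pos)]
            )
            neg_ds = PeptideDataset(
                [PeptideRecord(f"n{i}", s, "negative") for i, s in enumerate(neg)]
            )
            discovered = discover_motifs(pos_ds, neg_ds)
            patterns = [m.pattern for m in discovered]
        else:
            source = DEFAULT_MOTIFS if self.motifs is None else self.motifs
            patterns = [m.pattern if isinstance(m, Motif) else str(m) for m in source]
            # order by positive support on the training data
            support = {p: sum(1 for s in pos if p in s) for p in patterns}
            patterns = sorted(patterns, key=lambda p: (-support[p], p))
        if not patterns:
            raise ValueError("ensemble motif set is empty")
        self.motifs_ = patterns
        self.ml_model_ = CompositionClassifier(
            kind=self.classifier_kind,
            score_threshold=self.ml_threshold,
            random_state=self.random_state,
        )
        self.ml_model_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_detail(
        self, X: Sequence[str], ids: Optional[Sequence[str]] = None
    ) -> list[EnsemblePrediction]:
        """Per-query prediction with provenance."""
        check_is_fitted(self, "motifs_")
        if ids is None:
            ids = [f"query{i + 1}" for i in range(len(X))]
        out = []
        ml_scores = self.ml_model_.decision_function(X)
        for rid, seq, score in zip(ids, X, ml_scores):
            hit = first_match(seq, self.motifs_)
            if hit is not None:
                out.append(EnsemblePrediction(rid, "positive", "motif", hit, None))
            else:
                label = "positive" if score >= self.ml_threshold else "negative"
                out.append(EnsemblePrediction(rid, label, "ML", None, float(score)))
        return out

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.array(
            [1 if p.label == "positive" else 0 for p in self.predict_detail(X)]
        )

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """Score in [0, 1]: 1.0 on a motif hit, else the ML score."""
        check_is_fitted(self, "motifs_")
        ml = self.ml_model_.decision_function(X)
        return np.array(
            [
                1.0 if first_match(seq, self.motifs_) else s
                for seq, s in zip(X, ml)
            ]
        )

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        s = self.decision_function(X)
        return np.column_stack([1.0 - s, s])


def predict_ensemble(
    model: MotifEnsembleClassifier, peptides: PeptideDataset
) -> list[EnsemblePrediction]:
    """Batch prediction with provenance over a dataset."""
    return model.predict_detail(peptides.sequences(), peptides.ids())


def coverage_report(
    model: MotifEnsembleClassifier, positives: PeptideDataset
) -> CoverageTable:
    """Coverage of the positive set by the ensemble's motif tier, in its
    stored attribution order; the residual row is the ML-handled fraction.
    """
    check_is_fitted(model, "motifs_")
    return coverage_table(model.motifs_, positives)
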