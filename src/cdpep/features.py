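"""Amino-acid composition featurization for the classifier panel."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequences import AMINO_ACIDS, PeptideDataset, amino_acid_composition

#: Feature column order, fixed and documented: alphabetical one-letter codes.
FEATURE_COLUMNS: tuple[str, ...] = tuple(AMINO_ACIDS)
FEATURE_SPEC = "AAC-20, alphabetical"


class AACTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer: raw peptide strings -> 20 composition
    percentages per row, columns in fixed alphabetical residue order.
    Each row sums to 100.
    """

    def fit(self, X: Sequence[str], y=None):
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        rows = np.empty((len(X), 20), dtype=float)
        for i, seq in enumerate(X):
            comp = amino_acid_composition(seq)
            rows[i] = [comp[aa] for aa in FEATURE_COLUMNS]
        return rows

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_COLUMNS)


def featurize(dataset: PeptideDataset) -> pd.DataFrame:
    """One AAC row per record, indexed by record id, order preserved.

    Adds a ``label`` column (0/1) when every record is labeled.
    """
    X = AACTransformer().transform(dataset.sequences())
    df = pd.DataFrame(X, index=dataset.ids(), columns=list(FEATURE_COLUMNS))
    if all(r.label is not None for r in dataset) and len(dataset) > 0:
        df["label"] = dataset.y()
    return df
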