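"""Whole-protein scanning and single-substitution analog design.

Scanning slides a fixed-length window over a protein and scores every
window with any fitted predictor (ensemble, composition classifier or
PQ-density rule), flagging candidate disease-associated regions.  Analog
design enumerates all 19L single-residue substitution variants of a
peptide and re-scores each, for mapping which residues the prediction
hinges on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble import MotifEnsembleClassifier
from .sequences import AMINO_ACIDS, PeptideRecord


@dataclass(frozen=True)
class ScanRow:
    start: int  # 1-based
    end: int  # inclusive
    subsequence: str
    score: float
    label: str
    provenance: Optional[str] = None


@dataclass(frozen=True)
class ScanResult:
    protein_id: str
    window_length: int
    step: int
    rows: tuple[ScanRow, ...]


@dataclass(frozen=True)
class AnalogRow:
    position: Optional[int]  # 1-based; None for the parent row
    original: Optional[str]
    substituted: Optional[str]
    sequence: str
    score: float
    label: str


@dataclass(frozen=True)
class AnalogSet:
    parent: str
    rows: tuple[AnalogRow, ...]  # parent first, then 19L analogs


def _score_batch(predictor, seqs: Sequence[str]):
    """(scores, labels, provenances) from any fitted predictor.

    Ensembles report per-window provenance; other predictors report None.
    """
    if isinstance(predictor, MotifEnsembleClassifier):
        details = predictor.predict_detail(seqs)
        scores = predictor.decision_function(seqs)
        return (
            np.asarray(scores, dtype=float),
            [d.label for d in details],
            [d.provenance for d in details],
        )
    scores = np.asarray(predictor.decision_function(seqs), dtype=float)
    labels = ["positive" if p == 1 else "negative" for p in predictor.predict(seqs)]
    return scores, labels, [None] * len(seqs)


def scan_protein(
    protein: PeptideRecord,
    predictor,
    window_length: int = 9,
    step: int = 1,
) -> ScanResult:
    """Score every length-``window_length`` window of a protein.

    Windows advance by ``step`` (default 1, fully overlapping); rows are
    in N->C order with 1-based inclusive coordinates.  Row count is
    ``floor((L - w)/step) + 1``.
    """
    L = len(protein)
    if window_length > L:
        raise ValueError(f"window length {window_length} exceeds protein length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = list(range(0, L - window_length + 1, step))
    seqs = [protein.sequence[s : s + window_length] for s in starts]
    scores, labels, prov = _score_batch(predictor, seqs)
    rows = tuple(
        ScanRow(s + 1, s + window_length, seq, float(sc), lab, pv)
        for s, seq, sc, lab, pv in zip(starts, seqs, scores, labels, prov)
    )
    return ScanResult(protein.id, window_length, step, rows)


def design_analogs(peptide: PeptideRecord, predictor) -> AnalogSet:
    """All single-position substitution analogs of a peptide, scored.

    Exactly 19 * L analogs (every position to each of the 19 other
    residues), each at Hamming distance 1 from the parent; the parent is
    scored and reported first.
    """
    parent = peptide.sequence
    variants: list[tuple[Optional[int], Optional[str], Optional[str], str]] = [
        (None, None, None, parent)
    ]
    for i, orig in enumerate(parent):
        for aa in AMINO_ACIDS:
            if aa == orig:
                continue
            variants.append((i + 1, orig, aa, parent[:i] + aa + parent[i + 1 :]))
    seqs = [v[3] for v in variants]
    scores, labels, _ = _score_batch(predictor, seqs)
    rows = tuple(
        AnalogRow(pos, orig, sub, seq, float(sc), lab)
        for (pos, orig, sub, seq), sc, lab in zip(variants, scores, labels)
    )
    return AnalogSet(parent, rows)
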