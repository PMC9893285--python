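"""Class-exclusive ungapped motif discovery, scanning and coverage.

A motif here is an exact amino-acid substring that recurs in
disease-associated (positive) peptides while being absent from — or very
rare in — the negative set.  Discovery enumerates every substring in a
length band, filters by per-sequence support in each class, and
post-filters redundant patterns.  Scanning maps a motif list onto query
sequences with 1-based coordinates; the coverage table attributes each
positive sequence to the first motif (in listed order) that it contains,
which is how the motif tier of the ensemble is audited.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .sequences import PeptideDataset

#: Curated default motif set: ungapped patterns recurrently reported as
#: (near-)exclusive to celiac-disease-associated peptides, ordered by their
#: published occurrence in positives (highest first).  Shipped as the
#: pretrained motif tier of the ensemble.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "QPF",
    "PQQP",
    "PYP",
    "QPQQ",
    "PFP",
    "PEQ",
    "FPQP",
    "FPQQ",
    "PQLP",
    "QQPF",
    "QPQ",
    "PQPQ",
    "QQPQ",
    "PQL",
)


@dataclass(frozen=True)
class Motif:
    """An ungapped pattern with per-sequence occurrence counts."""

    pattern: str
    positive_count: int
    negative_count: int = 0


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    sequence_id: str
    start: int  # 1-based


@dataclass(frozen=True)
class CoverageRow:
    pattern: str
    count: int
    percentage: float
    cumulative: float


@dataclass(frozen=True)
class CoverageTable:
    rows: tuple[CoverageRow, ...]
    residual_count: int
    residual_percentage: float


def _substrings(seq: str, kmin: int, kmax: int) -> set[str]:
    subs = set()
    L = len(seq)
    for k in range(kmin, min(kmax, L) + 1):
        for i in range(L - k + 1):
            subs.add(seq[i : i + k])
    return subs


def _pq_fraction(pattern: str) -> float:
    return sum(1 for c in pattern if c in "PQ") / len(pattern)


def discover_motifs(
    positives: PeptideDataset,
    negatives: PeptideDataset,
    kmin: int = 3,
    kmax: int = 6,
    min_positive: Optional[int] = None,
    max_negative: int = 0,
) -> list[Motif]:
    """Enumerate class-exclusive ungapped motifs.

    Every distinct substring of length ``kmin..kmax`` occurring in at
    least ``min_positive`` positive sequences (default: 1% of the positive
    set, rounded up) and at most ``max_negative`` negative sequences is a
    candidate.  Counts are per-sequence: a sequence containing a pattern
    twice contributes once.

    Two post-filters remove redundancy:

    1. a candidate containing another candidate as a proper substring is
       dropped (the substring necessarily covers a superset of its
       positive sequences);
    2. candidates whose positive-coverage sets are identical are collapsed
       to one canonical representative — the most P/Q-dense pattern, then
       the shortest, then the lexicographically smallest.  The second rule
       reflects what the discovery is for: among support-equivalent
       patterns from the same sequence context, the proline/glutamine-rich
       core is the biologically meaningful one.

    Results are sorted by positive support descending, ties broken
    lexicographically.
    """
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmin > kmax:
        raise ValueError("kmin must be <= kmax")
    if len(positives) == 0:
        raise ValueError("positive set must be non-empty")
    if min_positive is None:
        min_positive = math.ceil(0.01 * len(positives))

    pos_subs = [_substrings(r.sequence, kmin, kmax) for r in positives]
    pos_counts: Counter[str] = Counter()
    for subs in pos_subs:
        pos_counts.update(subs)

    neg_counts: Counter[str] = Counter()
    for r in negatives:
        neg_counts.update(_substrings(r.sequence, kmin, kmax))

    candidates = {
        p: c
        for p, c in pos_counts.items()
        if c >= min_positive and neg_counts.get(p, 0) <= max_negative
    }
    if not candidates:
        return []

    # post-filter 1: drop candidates containing another candidate
    by_len: dict[int, set[str]] = {}
    for p in candidates:
        by_len.setdefault(len(p), set()).add(p)
    kept = []
    for p in candidates:
        has_sub = False
        for k in range(kmin, len(p)):
            pool = by_len.get(k)
            if not pool:
                continue
            if any(p[i : i + k] in pool for i in range(len(p) - k + 1)):
                has_sub = True
                break
        if not has_sub:
            kept.append(p)

    # post-filter 2: collapse identical positive-coverage classes
    coverage = {
        p: frozenset(i for i, subs in enumerate(pos_subs) if p in subs) for p in kept
    }
    best_by_cov: dict[frozenset, str] = {}
    for p in kept:
        key = coverage[p]
        rank = (-_pq_fraction(p), len(p), p)
        cur = best_by_cov.get(key)
        if cur is None or rank < (-_pq_fraction(cur), len(cur), cur):
            best_by_cov[key] = p

    motifs = [
        Motif(p, pos_counts[p], neg_counts.get(p, 0)) for p in best_by_cov.values()
    ]
    motifs.sort(key=lambda m: (-m.positive_count, m.pattern))
    return motifs


def count_occurrences(
    patterns: Sequence[str], dataset: PeptideDataset
) -> dict[str, int]:
    """Per-sequence occurrence counts of each pattern in a dataset."""
    return {
        p: sum(1 for r in dataset if p in r.sequence) for p in patterns
    }


def scan_motifs(
    sequence: str, motifs: Sequence[Motif | str], sequence_id: str = "query"
) -> list[MotifHit]:
    """All occurrences of every motif, overlapping included.

    Starts are 1-based; hits are sorted by start, then pattern.
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    hits = []
    for m in motifs:
        pattern = m.pattern if isinstance(m, Motif) else m
        start = sequence.find(pattern)
        while start != -1:
            hits.append(MotifHit(pattern, sequence_id, start + 1))
            start = sequence.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.start, h.pattern))
    return hits


def first_match(sequence: str, patterns: Sequence[str]) -> Optional[str]:
    """The first pattern, in listed order, contained in the sequence."""
    for p in patterns:
        if p in sequence:
            return p
    return None


def coverage_table(
    motifs: Sequence[Motif | str], positives: PeptideDataset
) -> CoverageTable:
    """First-match attribution of positive sequences to an ordered motif list.

    Each sequence counts toward exactly one row — the first listed motif it
    contains — so the cumulative percentage is non-decreasing and, with the
    residual (sequences matching no motif, left for the ML tier), sums
    to 100.
    """
    if len(positives) == 0:
        raise ValueError("positive set must be non-empty")
    patterns = [m.pattern if isinstance(m, Motif) else m for m in motifs]
    counts = {p: 0 for p in patterns}
    residual = 0
    for r in positives:
        hit = first_match(r.sequence, patterns)
        if hit is None:
            residual += 1
        else:
            counts[hit] += 1
    n = len(positives)
    rows = []
    cum = 0.0
    for p in patterns:
        pct = 100.0 * counts[p] / n
        cum += pct
        rows.append(CoverageRow(p, counts[p], round(pct, 2), round(cum, 2)))
    return CoverageTable(tuple(rows), residual, round(100.0 * residual / n, 2))


def read_motif_list(path) -> list[Motif]:
    """Read a motif list file: one pattern per line, optional tab-separated
    positive/negative counts after it.  Blank lines and ``#`` comments are
    ignored.
    """
    motifs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        pattern = parts[0].strip().upper()
        pos = int(parts[1]) if len(parts) > 1 else 1
        neg = int(parts[2]) if len(parts) > 2 else 0
        motifs.append(Motif(pattern, pos, neg))
    return motifs


def write_motif_list(motifs: Sequence[Motif], path) -> None:
    with Path(path).open("w") as fh:
        for m in motifs:
            fh.write(f"{m.pattern}\t{m.positive_count}\t{m.negative_count}\n")
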