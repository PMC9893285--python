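"""Peptide records, FASTA/TSV I/O, validation and composition features.

Sequences are strings over the 20 standard one-letter amino-acid codes,
always stored uppercase.  Datasets are ordered collections of records with
optional binary class labels (``"positive"`` / ``"negative"``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = "positive"
NEGATIVE = "negative"


class SequenceError(ValueError):
    """Raised for malformed input sequences or dataset files."""


def validate_sequence(sequence: str, record_id: str = "<unnamed>") -> str:
    """Uppercase and validate a peptide sequence.

    Raises :class:`SequenceError` naming the record and the offending
    character if the sequence is empty or contains a non-standard residue
    (B, J, O, U, X, Z or anything else outside the 20-letter alphabet).
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    for ch in seq:
        if ch not in _AA_SET:
            raise SequenceError(
                f"record {record_id!r}: invalid residue character {ch!r} "
                f"(allowed: {AMINO_ACIDS})"
            )
    return seq


@dataclass(frozen=True)
class PeptideRecord:
    """One identified amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, self.id))
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise SequenceError(
                f"record {self.id!r}: label must be {POSITIVE!r} or {NEGATIVE!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """An ordered collection of :class:`PeptideRecord`."""

    records: list[PeptideRecord] = field(default_factory=list)
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def y(self) -> list[int]:
        """Labels as 0/1 integers; raises if any record is unlabeled."""
        out = []
        for r in self.records:
            if r.label is None:
                raise SequenceError(f"record {r.id!r} has no label")
            out.append(1 if r.label == POSITIVE else 0)
        return out

    def subset(self, ids: Iterable[str], name: Optional[str] = None) -> "PeptideDataset":
        wanted = set(ids)
        return PeptideDataset(
            [r for r in self.records if r.id in wanted], name or self.name
        )

    def relabel(self, label: Optional[str]) -> "PeptideDataset":
        return PeptideDataset([replace(r, label=label) for r in self.records], self.name)


def concat(datasets: Iterable[PeptideDataset], name: str = "dataset") -> PeptideDataset:
    records: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    for ds in datasets:
        for r in ds:
            # duplicate ids across merged datasets get a numeric suffix
            if r.id in seen:
                seen[r.id] += 1
                records.append(replace(r, id=f"{r.id}_{seen[r.id]}"))
            else:
                seen[r.id] = 0
                records.append(r)
    return PeptideDataset(records, name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path, label: Optional[str] = None, name: Optional[str] = None) -> PeptideDataset:
    """Read a FASTA file into a :class:`PeptideDataset`.

    The record id is the header up to the first whitespace.  Sequences are
    uppercased and validated; an invalid residue raises
    :class:`SequenceError` naming the record and the character.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        first = fh.read(1)
        if first and first != ">":
            raise SequenceError(
                f"{path}: malformed FASTA, line 1: sequence data before header"
            )
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(PeptideRecord(rec.id, str(rec.seq), label))
    return PeptideDataset(records, name or path.stem)


def write_fasta(dataset: PeptideDataset, path) -> None:
    """Write single-line-per-sequence FASTA; duplicate ids get a numeric suffix."""
    path = Path(path)
    seen: dict[str, int] = {}
    with path.open("w") as fh:
        for r in dataset:
            rid = r.id
            if rid in seen:
                seen[rid] += 1
                rid = f"{rid}_{seen[rid]}"
            else:
                seen[r.id] = 0
            fh.write(f">{rid}\n{r.sequence}\n")


def read_tsv(path, name: Optional[str] = None) -> PeptideDataset:
    """Read a two-column (sequence, label in {1,0}) tab-separated file.

    A header row is auto-detected: if the second field of the first row is
    not ``0``/``1`` the row is treated as a header.  Records are assigned
    ids ``seq1``, ``seq2``, ... in file order.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    if not rows:
        return PeptideDataset([], name or path.stem)
    start = 0
    if len(rows[0]) < 2 or rows[0][1].strip() not in ("0", "1"):
        start = 1  # header
    for i, row in enumerate(rows[start:], start=1):
        if len(row) < 2:
            raise SequenceError(f"{path}: row {i + start}: expected 2 columns")
        lab = row[1].strip()
        if lab not in ("0", "1"):
            raise SequenceError(f"{path}: row {i + start}: label must be 0 or 1")
        records.append(
            PeptideRecord(f"seq{i}", row[0].strip(), POSITIVE if lab == "1" else NEGATIVE)
        )
    return PeptideDataset(records, name or path.stem)


def write_tsv(dataset: PeptideDataset, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sequence\tlabel\n")
        for r in dataset:
            fh.write(f"{r.sequence}\t{1 if r.label == POSITIVE else 0}\n")


# ---------------------------------------------------------------------------
# Dataset filtering
# ---------------------------------------------------------------------------

def filter_by_length(
    dataset: PeptideDataset, min_len: int = 9, max_len: int = 20
) -> PeptideDataset:
    """Keep records with ``min_len <= L <= max_len`` (both inclusive) and
    drop duplicate sequences within each label class, keeping the first
    occurrence.  Returns a new dataset.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    seen: set[tuple[Optional[str], str]] = set()
    out = []
    for r in dataset:
        if not (min_len <= len(r) <= max_len):
            continue
        key = (r.label, r.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return PeptideDataset(out, dataset.name)


# ---------------------------------------------------------------------------
# Feature primitives
# ---------------------------------------------------------------------------

def termini_vector(sequence: str) -> str:
    """Fixed-length 18-mer: the first 9 residues concatenated with the last 9.

    For peptides of length 9-17 the two halves overlap; for an 18-mer the
    result is the sequence itself.  Raises for sequences shorter than 9.
    """
    if len(sequence) < 9:
        raise SequenceError(
            f"termini vector needs length >= 9, got {len(sequence)}"
        )
    return sequence[:9] + sequence[-9:]


def amino_acid_composition(sequence: str) -> dict[str, float]:
    """Per-residue composition percentages, AAC_i = 100 * R_i / L.

    Returns a mapping with exactly 20 entries in alphabetical residue
    order; residues absent from the sequence map to 0.0.  The values sum
    to 100 by construction.
    """
    seq = validate_sequence(sequence)
    L = len(seq)
    return {aa: 100.0 * seq.count(aa) / L for aa in AMINO_ACIDS}
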