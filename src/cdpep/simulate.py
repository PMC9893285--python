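"""Seeded generator of celiac-like positive and background negative peptides.

The generator emulates the statistical structure the prediction method
relies on: positives are proline/glutamine-enriched 9-20-mers, a fixed
fraction of which carry one planted motif from a pool of published
celiac-associated patterns; negatives are drawn from a Swiss-Prot-like
background composition and rejection-resampled until they contain no pool
motif.  Sequences are unique within each class and the whole dataset is a
deterministic function of the seed, so every pipeline stage is testable
without external downloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequences import AMINO_ACIDS, PeptideDataset, PeptideRecord, concat

_MAX_ATTEMPTS = 1000


def _positive_composition() -> dict[str, float]:
    # stylized disease-peptide composition: P/Q dominate, F/L/Y elevated
    comp = {"P": 0.28, "Q": 0.28, "F": 0.08, "L": 0.08, "Y": 0.06}
    rest = (1.0 - sum(comp.values())) / (20 - len(comp))
    for aa in AMINO_ACIDS:
        comp.setdefault(aa, rest)
    return comp


def _negative_composition() -> dict[str, float]:
    # Swiss-Prot-like background: roughly uniform, L/A/S mildly elevated
    comp = {"L": 0.090, "A": 0.080, "S": 0.070}
    rest = (1.0 - sum(comp.values())) / (20 - len(comp))
    for aa in AMINO_ACIDS:
        comp.setdefault(aa, rest)
    return comp


#: Motif pool planted into positives: published patterns near-exclusive to
#: celiac-associated peptides.
DEFAULT_MOTIF_POOL: tuple[str, ...] = (
    "QPF",
    "QQPF",
    "PYP",
    "PEQ",
    "QPQ",
    "PQPQ",
    "QQPQ",
    "PQL",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic datasets."""

    n_positive: int = 500
    n_negative: int = 500
    seed: int = 42
    length_range: tuple[int, int] = (9, 20)
    positive_composition: dict[str, float] = field(default_factory=_positive_composition)
    negative_composition: dict[str, float] = field(default_factory=_negative_composition)
    motif_pool: tuple[str, ...] = DEFAULT_MOTIF_POOL
    #: fraction of positives receiving exactly one planted pool motif; the
    #: remaining positives are resampled until motif-free, so the fraction
    #: of motif-bearing positives is exact.
    motif_plant_fraction: float = 0.8
    #: fraction of negatives allowed to carry a planted pool motif
    #: (emulates slight motif contamination of real negative sets)
    negative_motif_leak: float = 0.0

    def __post_init__(self) -> None:
        for comp in (self.positive_composition, self.negative_composition):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError("composition probabilities must sum to 1")
        if not 0.0 <= self.motif_plant_fraction <= 1.0:
            raise ValueError("motif_plant_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "seed": self.seed,
            "length_range": list(self.length_range),
            "positive_composition": self.positive_composition,
            "negative_composition": self.negative_composition,
            "motif_pool": list(self.motif_pool),
            "motif_plant_fraction": self.motif_plant_fraction,
            "negative_motif_leak": self.negative_motif_leak,
        }
        return d


def _contains_any(seq: str, patterns) -> bool:
    return any(p in seq for p in patterns)


def _sample_class(
    rng: np.random.Generator,
    n: int,
    composition: dict[str, float],
    length_range: tuple[int, int],
    motif_pool,
    plant_fraction: float,
    prefix: str,
    label: str,
) -> list[PeptideRecord]:
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array([composition[aa] for aa in AMINO_ACIDS])
    lo, hi = length_range
    n_plant = int(round(plant_fraction * n))
    planted = np.zeros(n, dtype=bool)
    planted[:n_plant] = True
    rng.shuffle(planted)

    seen: set[str] = set()
    records = []
    for i in range(n):
        for _ in range(_MAX_ATTEMPTS):
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=L, p=probs))
            if planted[i]:
                motif = motif_pool[int(rng.integers(len(motif_pool)))]
                start = int(rng.integers(0, L - len(motif) + 1))
                seq = seq[:start] + motif + seq[start + len(motif) :]
            elif _contains_any(seq, motif_pool):
                continue
            if seq not in seen:
                seen.add(seq)
                records.append(PeptideRecord(f"{prefix}{i + 1}", seq, label))
                break
        else:
            raise RuntimeError(
                "rejection sampling failed; increase alphabet mass outside "
                "P/Q or relax the motif-exclusion constraint"
            )
    return records


def generate_dataset(config: GeneratorConfig | None = None) -> PeptideDataset:
    """Generate the labeled synthetic dataset (positives then negatives).

    Deterministic given the config seed; sequences unique within each
    class; exactly ``round(motif_plant_fraction * n_positive)`` positives
    contain at least one pool motif and (with zero leak) no negative
    contains any.
    """
    config = config or GeneratorConfig()
    if config.n_positive < 1 or config.n_negative < 1:
        raise ValueError("need at least one record per class")
    rng = np.random.default_rng(config.seed)
    positives = _sample_class(
        rng,
        config.n_positive,
        config.positive_composition,
        config.length_range,
        config.motif_pool,
        config.motif_plant_fraction,
        "pos",
        "positive",
    )
    negatives = _sample_class(
        rng,
        config.n_negative,
        config.negative_composition,
        config.length_range,
        config.motif_pool,
        config.negative_motif_leak,
        "neg",
        "negative",
    )
    return PeptideDataset(positives + negatives, name=f"synthetic-seed{config.seed}")


def default_dataset(seed: int = 42, n_positive: int = 500, n_negative: int = 500) -> PeptideDataset:
    """The default synthetic study dataset (500+500, seed 42)."""
    return generate_dataset(
        GeneratorConfig(n_positive=n_positive, n_negative=n_negative, seed=seed)
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(config: GeneratorConfig, out_dir) -> tuple[Path, Path, Path]:
    """Write positive/negative FASTA files plus a JSON manifest recording
    the config, seed and file checksums.  Returns the three paths.
    """
    from .sequences import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(config)
    pos = PeptideDataset([r for r in ds if r.label == "positive"], "positives")
    neg = PeptideDataset([r for r in ds if r.label == "negative"], "negatives")
    pos_path = out_dir / "positives.fasta"
    neg_path = out_dir / "negatives.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    manifest = {
        "config": config.to_dict(),
        "files": {
            "positives.fasta": _sha256(pos_path),
            "negatives.fasta": _sha256(neg_path),
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return pos_path, neg_path, manifest_path
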