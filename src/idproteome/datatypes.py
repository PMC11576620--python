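"""Core domain types shared across the pipeline.

A proteome group is a named set of protein records; per-residue disorder
predictions attach to proteins as tracks (one per predictor); expression
tables map proteins to abundances within a sample pool.  All containers are
plain dataclasses with validation in ``__post_init__`` so that malformed
data fails at construction, not deep inside an analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residues ranked most order-promoting to most disorder-promoting.
#: First ten promote order (C..M), last ten promote disorder (R..P).
ORDER_PROMOTING: tuple[str, ...] = tuple("CWIYFLHVNM")
DISORDER_PROMOTING: tuple[str, ...] = tuple("RTDGAKQSEP")
RESIDUE_RANKING: tuple[str, ...] = ORDER_PROMOTING + DISORDER_PROMOTING


class ValidationError(ValueError):
    """Raised when an input object violates a domain invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a unique identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.id}: sequence must have length >= 1")
        bad = set(self.sequence) - set(CANONICAL_RESIDUES)
        if bad:
            raise ValidationError(
                f"{self.id}: non-canonical residues {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeGroup:
    """A named proteome: e.g. younger_lens, older_lens, zonules."""

    name: str
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"group {self.name!r}: at least one record required")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"group {self.name!r}: duplicate ids {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == protein_id:
                return r
        raise KeyError(protein_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)


@dataclass
class DisorderTrack:
    """Per-residue disorder scores in [0, 1] for one protein, one predictor."""

    protein_id: str
    predictor: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise ValidationError(
                f"{self.protein_id}/{self.predictor}: track must be 1-D, length >= 1"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError(
                f"{self.protein_id}/{self.predictor}: non-finite score in track"
            )
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise ValidationError(
                f"{self.protein_id}/{self.predictor}: scores must lie in [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class ExpressionTable:
    """Protein abundances for one sample pool, with the pool's mean donor age."""

    pool_id: str
    mean_age: float
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        if self.mean_age < 0:
            raise ValidationError(f"pool {self.pool_id}: mean_age must be >= 0")
        if not self.abundance:
            raise ValidationError(f"pool {self.pool_id}: no proteins in pool")
        for pid, a in self.abundance.items():
            if a < 0:
                raise ValidationError(
                    f"pool {self.pool_id}: negative abundance for {pid}"
                )
        if not any(a > 0 for a in self.abundance.values()):
            raise ValidationError(
                f"pool {self.pool_id}: at least one abundance must be > 0"
            )

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))


def tracks_by_protein(
    tracks: Sequence[DisorderTrack],
) -> dict[str, list[DisorderTrack]]:
    """Group a flat list of tracks by protein id, preserving order."""
    out: dict[str, list[DisorderTrack]] = {}
    for t in tracks:
        out.setdefault(t.protein_id, []).append(t)
    return out
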