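"""Per-protein disorder summaries and the cutoff-grid classification.

Two per-protein scalars summarize a per-residue track:

* ADS — average disorder score, the arithmetic mean of the track;
* PPDR — fraction of residues whose score is strictly above 0.5
  (reported as a fraction in [0, 1]; multiply by 100 for percent).

The mean disorder profile (MDP) is the per-residue mean across several
predictors' tracks for the same protein, itself a track named ``"MDP"``.

Classification uses the conventional three-tier grid:

=================== ================= ==================
tier                ADS               PPDR
=================== ================= ==================
highly_ordered      < 0.15            < 10%
moderately_disordered [0.15, 0.5)     [10%, 30%)
highly_disordered   ≥ 0.5             ≥ 30%
=================== ================= ==================

The two axes can disagree; the combined label is formed either by
``strict_and`` (highly disordered only when both axes say so, otherwise
the less-disordered of the two) or ``lenient_or`` (the more-disordered of
the two axes).  ``lenient_or`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .datatypes import DisorderTrack, ValidationError

PPDR_SCORE_THRESHOLD = 0.5
ADS_CUTOFFS = (0.15, 0.5)
PPDR_CUTOFFS = (0.10, 0.30)

CombineMode = Literal["strict_and", "lenient_or"]


class DisorderTier(IntEnum):
    """Ordered disorder tiers; larger = more disordered."""

    highly_ordered = 0
    moderately_disordered = 1
    highly_disordered = 2

    def __str__(self) -> str:  # TSV-friendly
        return self.name


@dataclass(frozen=True)
class DisorderSummary:
    protein_id: str
    predictor: str
    ads: float
    ppdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ads <= 1.0 and 0.0 <= self.ppdr <= 1.0):
            raise ValidationError(
                f"{self.protein_id}/{self.predictor}: ADS and PPDR must lie in [0, 1]"
            )


@dataclass(frozen=True)
class DisorderClass:
    ads_class: DisorderTier
    ppdr_class: DisorderTier
    combined: DisorderTier
    agreement: bool


def ads(track: DisorderTrack) -> float:
    """Average disorder score: mean of the per-residue scores."""
    return float(np.mean(track.scores))


def ppdr(track: DisorderTrack, threshold: float = PPDR_SCORE_THRESHOLD) -> float:
    """Fraction of residues with score strictly above ``threshold``."""
    return float(np.count_nonzero(track.scores > threshold) / len(track))


def summarize(track: DisorderTrack) -> DisorderSummary:
    return DisorderSummary(
        protein_id=track.protein_id,
        predictor=track.predictor,
        ads=ads(track),
        ppdr=ppdr(track),
    )


def mean_disorder_profile(tracks: Sequence[DisorderTrack]) -> DisorderTrack:
    """Per-residue mean across predictors for one protein, named ``MDP``."""
    if not tracks:
        raise ValidationError("mean_disorder_profile requires at least one track")
    pids = {t.protein_id for t in tracks}
    if len(pids) != 1:
        raise ValidationError(f"mixed protein ids in MDP input: {sorted(pids)}")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValidationError(
            f"{tracks[0].protein_id}: track length mismatch {sorted(lengths)}"
        )
    mean = np.mean([t.scores for t in tracks], axis=0)
    return DisorderTrack(protein_id=tracks[0].protein_id, predictor="MDP", scores=mean)


def _tier(value: float, cutoffs: tuple[float, float]) -> DisorderTier:
    lo, hi = cutoffs
    if value < lo:
        return DisorderTier.highly_ordered
    if value < hi:
        return DisorderTier.moderately_disordered
    return DisorderTier.highly_disordered


def classify(
    summary: DisorderSummary, mode: CombineMode = "lenient_or"
) -> DisorderClass:
    """Place a protein on the ADS/PPDR cutoff grid.

    Lower bins are half-open, the top bin closed below (ADS ≥ 0.5,
    PPDR ≥ 30% are highly disordered).
    """
    a = _tier(summary.ads, ADS_CUTOFFS)
    p = _tier(summary.ppdr, PPDR_CUTOFFS)
    if mode == "lenient_or":
        combined = max(a, p)
    elif mode == "strict_and":
        combined = min(a, p)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return DisorderClass(ads_class=a, ppdr_class=p, combined=combined, agreement=a == p)


def summary_table(
    summaries: Iterable[DisorderSummary], mode: CombineMode = "lenient_or"
) -> pd.DataFrame:
    """Per-protein table of ADS/PPDR and grid classes, one row per summary."""
    rows = []
    for s in summaries:
        c = classify(s, mode)
        rows.append(
            {
                "protein_id": s.protein_id,
                "predictor": s.predictor,
                "ads": s.ads,
                "ppdr": s.ppdr,
                "ads_class": str(c.ads_class),
                "ppdr_class": str(c.ppdr_class),
                "combined": str(c.combined),
                "agreement": c.agreement,
            }
        )
    return pd.DataFrame(rows)


def classification_counts(
    summaries_by_group: dict[str, Sequence[DisorderSummary]],
    mode: CombineMode = "lenient_or",
) -> pd.DataFrame:
    """Group × tier count table of combined classifications.

    Rows are groups, columns the three tiers ordered least→most disordered;
    every protein with a summary lands in exactly one cell.
    """
    tiers = [str(t) for t in DisorderTier]
    data = {}
    for gname, summaries in summaries_by_group.items():
        counts = dict.fromkeys(tiers, 0)
        for s in summaries:
            counts[str(classify(s, mode).combined)] += 1
        data[gname] = counts
    return pd.DataFrame(data).T[tiers]
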