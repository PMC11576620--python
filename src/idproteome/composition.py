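"""Amino-acid composition profiling with bootstrap significance.

For each residue type the enrichment of a query proteome relative to a
background proteome is the fractional difference

    (C_x - C_bg) / C_bg,

where ``C_x`` is the residue's relative frequency in the query and ``C_bg``
its frequency in the background.  Positive values mean enrichment, negative
depletion; −1 is complete absence from the query.  Uncertainty comes from a
protein-level bootstrap: proteins (the independent sampling units) are
resampled with replacement within each set, the fractional difference is
recomputed per iteration, and the per-residue SD over iterations is the
error bar.  Significance is a two-sided sign-crossing test with an add-one
correction: p = min(1, 2(k+1)/(B+1)) where k counts iterations whose value
falls on the opposite side of zero from the observed one.

Residues are reported on the fixed order→disorder ranking axis
(C,W,I,Y,F,L,H,V,N,M then R,T,D,G,A,K,Q,S,E,P).

A background whose frequency is zero for a residue the query contains makes
the ratio undefined; such residues are flagged ``undefined`` (value +inf)
and excluded from significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    CANONICAL_RESIDUES,
    ProteomeGroup,
    RESIDUE_RANKING,
    ValidationError,
)

_RES_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


@dataclass(frozen=True)
class CompositionVector:
    """Relative frequencies of the 20 canonical residues (sum to 1)."""

    frequency: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.frequency) != set(CANONICAL_RESIDUES):
            raise ValidationError("frequency must cover exactly the 20 canonical residues")
        vals = np.array([self.frequency[r] for r in CANONICAL_RESIDUES])
        if (vals < 0).any():
            raise ValidationError("frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"frequencies sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        """Frequencies as a length-20 array in canonical-alphabet order."""
        return np.array([self.frequency[r] for r in CANONICAL_RESIDUES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CompositionVector":
        return cls({r: float(arr[i]) for i, r in enumerate(CANONICAL_RESIDUES)})


@dataclass
class CompositionProfile:
    """Per-residue enrichment profile of a query set versus a background.

    One row per residue on the order→disorder ranking axis, carrying the
    observed fractional difference, the bootstrap mean and SD, the
    two-sided p-value and the significance flag at the configured alpha.
    """

    table: pd.DataFrame  # index: residue; columns as documented in to_tsv
    alpha: float
    iterations: int

    def significant_residues(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="residue", float_format="%.6g")


def residue_counts(group: ProteomeGroup) -> np.ndarray:
    """Per-protein residue count matrix, shape (n_proteins, 20)."""
    counts = np.zeros((len(group), 20), dtype=np.int64)
    for i, rec in enumerate(group):
        seq_idx = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        # map ASCII codes to alphabet slots
        for r, j in _RES_INDEX.items():
            counts[i, j] = np.count_nonzero(seq_idx == ord(r))
    return counts


def residue_composition(group: ProteomeGroup) -> CompositionVector:
    """Pooled residue frequencies over all sequences of a group."""
    counts = residue_counts(group).sum(axis=0)
    total = counts.sum()
    if total == 0:
        raise ValidationError(f"group {group.name!r} has no residues")
    return CompositionVector.from_array(counts / total)


def fractional_difference(
    query: CompositionVector, background: CompositionVector
) -> dict[str, float]:
    """(C_x − C_bg)/C_bg per residue.

    Residues with zero background frequency map to +inf (query present) or
    nan (both absent); callers treat either as undefined.
    """
    q = query.as_array()
    b = background.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        fd = (q - b) / b
    fd = np.where((b == 0) & (q > 0), np.inf, fd)
    fd = np.where((b == 0) & (q == 0), np.nan, fd)
    return {r: float(fd[i]) for i, r in enumerate(CANONICAL_RESIDUES)}


def _bootstrap_freqs(
    counts: np.ndarray, iterations: int, rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Bootstrap pooled frequencies: resample proteins with replacement.

    Returns shape (iterations, 20).  Chunked to bound the memory of the
    fancy-indexing intermediate.
    """
    n = counts.shape[0]
    out = np.empty((iterations, 20))
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        idx = rng.integers(0, n, size=(b, n))
        sums = counts[idx].sum(axis=1).astype(float)
        out[done:done + b] = sums / sums.sum(axis=1, keepdims=True)
        done += b
    return out


def bootstrap_composition_test(
    query: ProteomeGroup,
    background: ProteomeGroup,
    iterations: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CompositionProfile:
    """Fractional-difference profile with protein-bootstrap SDs and p-values.

    Query and background are resampled independently, each at its original
    size.  See the module docstring for the statistic and the p-value rule.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if seed is None:
        raise ValidationError("a seed is mandatory for reproducibility")
    rng = np.random.default_rng(seed)

    cq = residue_counts(query)
    cb = residue_counts(background)
    obs_q = cq.sum(0) / cq.sum()
    obs_b = cb.sum(0) / cb.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        observed = (obs_q - obs_b) / obs_b

    fq = _bootstrap_freqs(cq, iterations, rng)
    fb = _bootstrap_freqs(cb, iterations, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = (fq - fb) / fb  # (iterations, 20)

    undefined = (obs_b == 0) | ~np.isfinite(observed)
    observed = np.where((obs_b == 0) & (obs_q > 0), np.inf, observed)

    boot_masked = np.where(np.isfinite(boot), boot, np.nan)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # all-NaN columns (undefined residues) are expected; keep them NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        boot_mean = np.nanmean(boot_masked, axis=0)
        boot_sd = (
            np.nanstd(boot_masked, axis=0, ddof=1) if iterations > 1 else np.zeros(20)
        )

    # two-sided sign-crossing test with add-one correction
    sign = np.sign(np.where(np.isfinite(observed), observed, 0.0))
    crossings = np.nansum(boot_masked * sign[None, :] < 0, axis=0)
    pvals = np.minimum(1.0, 2.0 * (crossings + 1) / (iterations + 1))
    pvals = np.where(sign == 0, 1.0, pvals)

    significant = (pvals < alpha) & ~undefined

    order = [_RES_INDEX[r] for r in RESIDUE_RANKING]
    table = pd.DataFrame(
        {
            "fractional_difference": observed[order],
            "bootstrap_mean": boot_mean[order],
            "bootstrap_sd": np.where(undefined, np.nan, boot_sd)[order],
            "p_value": np.where(undefined, np.nan, pvals)[order],
            "significant": significant[order],
            "undefined": undefined[order],
        },
        index=pd.Index(list(RESIDUE_RANKING), name="residue"),
    )
    return CompositionProfile(table=table, alpha=alpha, iterations=iterations)
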