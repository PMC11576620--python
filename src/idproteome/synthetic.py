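"""Synthetic proteomes, disorder tracks and expression pools.

The generator emulates the statistical structure the pipeline consumes —
not any real biology.  Three knobs matter:

* **composition** — sequences are drawn i.i.d. per residue from a baseline
  composition (uniform 1/20 by default) reweighted by per-residue
  multiplicative biases, so composition-enrichment recovery can be tested
  against a known ground truth;
* **disorder structure** — per protein, a pseudo-predictor draws a
  protein-level mean disorder from a Beta distribution centered on the
  group's target ADS, then adds autocorrelated residue-level noise
  (moving-average of white noise over a configurable correlation length),
  clipped to [0, 1];
* **expression pools** — abundances are log-normal; a pool may carry a
  target disorder score, in which case abundances are exponentially tilted
  (weight ∝ exp(λ·ads), λ solved numerically) so the expression-weighted
  mean ADS hits the target exactly.

The whole corpus is a pure function of (spec, seed): every sub-stream is
derived from the master seed plus a stable CRC of the task name, so
regenerating any piece in isolation gives identical output.

The shipped defaults mirror the study conditions: groups of 926/261/279
proteins (younger lens / older lens / zonules), six pseudo-predictors with
the groups' published mean ADS targets, and four pools with mean donor
ages 38.5/50.5/60.0/38.5 years and target scores 0.323/0.310/0.353/0.310.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datatypes import (
    CANONICAL_RESIDUES,
    DisorderTrack,
    ExpressionTable,
    ProteinRecord,
    ProteomeGroup,
    ValidationError,
)

DEFAULT_GROUP_SIZES = {"younger_lens": 926, "older_lens": 261, "zonules": 279}

#: Published per-predictor group mean ADS targets (younger lens, older lens,
#: zonules) used as the default generating means.
DEFAULT_PREDICTOR_ADS = {
    "VLXT": (0.33, 0.30, 0.35),
    "VSL2B": (0.42, 0.39, 0.47),
    "VL3": (0.34, 0.31, 0.40),
    "IUP-Short": (0.25, 0.24, 0.28),
    "IUP-Long": (0.27, 0.26, 0.32),
    "PFIT": (0.30, 0.27, 0.33),
}


def _rng(seed: int, task: str) -> np.random.Generator:
    """Deterministic sub-stream: master seed + CRC32 of the task name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(task.encode())])


def concentration_from_sd(mean: float, sd: float) -> float:
    """Beta concentration κ with the given mean and SD: var = m(1−m)/(κ+1)."""
    v = sd * sd
    if v >= mean * (1 - mean):
        raise ValidationError(f"sd {sd} too large for a Beta with mean {mean}")
    return mean * (1 - mean) / v - 1


@dataclass
class PredictorModel:
    """One pseudo-predictor: group ADS targets plus residue-level noise."""

    name: str
    target_ads: dict[str, float]      # group name -> mean ADS
    ads_sd: float = 0.15              # protein-level spread of ADS
    noise_sd: float = 0.15            # residue-level noise SD
    corr_length: int = 10             # autocorrelation length, residues

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.ads_sd <= 0:
            raise ValidationError("noise/ads SDs must be non-negative")
        if self.corr_length < 1:
            raise ValidationError("corr_length must be >= 1")


@dataclass
class PoolSpec:
    """One expression pool: id, mean donor age, abundance model."""

    pool_id: str
    mean_age: float
    lognormal_sigma: float = 1.0
    target_score: float | None = None


@dataclass
class SyntheticSpec:
    """Full description of a synthetic corpus; the generator's only input."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    length_range: tuple[int, int] = (50, 500)
    composition_bias: dict[str, float] = field(default_factory=dict)
    baseline_composition: dict[str, float] | None = None
    predictor_models: list[PredictorModel] = field(
        default_factory=lambda: [
            PredictorModel(
                name=name,
                target_ads=dict(zip(DEFAULT_GROUP_SIZES, targets)),
            )
            for name, targets in DEFAULT_PREDICTOR_ADS.items()
        ]
    )
    pools: list[PoolSpec] = field(
        default_factory=lambda: [
            PoolSpec("A", 38.5, target_score=0.323),
            PoolSpec("B", 50.5, target_score=0.310),
            PoolSpec("C", 60.0, target_score=0.353),
            PoolSpec("D", 38.5, target_score=0.310),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be >= 1")
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValidationError("lengths must satisfy 30 <= min <= max")
        if any(w <= 0 for w in self.composition_bias.values()):
            raise ValidationError("composition bias weights must be > 0")

    def composition(self) -> np.ndarray:
        """Bias-reweighted baseline composition, canonical-alphabet order."""
        if self.baseline_composition is None:
            base = np.full(20, 1 / 20)
        else:
            base = np.array(
                [self.baseline_composition[r] for r in CANONICAL_RESIDUES]
            )
        w = np.array(
            [self.composition_bias.get(r, 1.0) for r in CANONICAL_RESIDUES]
        )
        p = base * w
        return p / p.sum()


def generate_proteome(spec: SyntheticSpec, group: str) -> ProteomeGroup:
    """Sequences drawn i.i.d. per residue; lengths uniform in range."""
    if group not in spec.group_sizes:
        raise ValidationError(f"unknown group {group!r}")
    rng = _rng(spec.seed, f"proteome:{group}")
    n = spec.group_sizes[group]
    lo, hi = spec.length_range
    probs = spec.composition()
    alphabet = np.array(list(CANONICAL_RESIDUES))
    records = []
    lengths = rng.integers(lo, hi + 1, size=n)
    for i in range(n):
        seq = "".join(rng.choice(alphabet, size=lengths[i], p=probs))
        records.append(ProteinRecord(id=f"{group}_{i:05d}", sequence=seq))
    return ProteomeGroup(name=group, records=records)


def _autocorrelated_noise(
    L: int, sd: float, corr_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Moving-average Gaussian noise with per-residue SD ``sd``."""
    if sd == 0.0:
        return np.zeros(L)
    ell = corr_length
    white = rng.normal(size=L + ell - 1)
    ma = np.convolve(white, np.ones(ell) / ell, mode="valid")
    return ma * sd * np.sqrt(ell)


def generate_tracks(
    group: ProteomeGroup, spec: SyntheticSpec, predictor: str
) -> list[DisorderTrack]:
    """Per-residue tracks for one pseudo-predictor over one group."""
    model = next((m for m in spec.predictor_models if m.name == predictor), None)
    if model is None:
        raise ValidationError(f"unknown predictor {predictor!r}")
    if group.name not in model.target_ads:
        raise ValidationError(
            f"predictor {predictor!r} has no ADS target for group {group.name!r}"
        )
    rng = _rng(spec.seed, f"tracks:{group.name}:{predictor}")
    m = model.target_ads[group.name]
    kappa = concentration_from_sd(m, model.ads_sd)
    tracks = []
    for rec in group:
        mean = rng.beta(m * kappa, (1 - m) * kappa)
        noise = _autocorrelated_noise(len(rec), model.noise_sd, model.corr_length, rng)
        scores = np.clip(mean + noise, 0.0, 1.0)
        tracks.append(
            DisorderTrack(protein_id=rec.id, predictor=predictor, scores=scores)
        )
    return tracks


def _tilted_weights(
    base: np.ndarray, ads: np.ndarray, target: float
) -> np.ndarray:
    """Exponential tilt base weights so the weighted mean ADS hits target."""
    if not ads.min() < target < ads.max():
        raise ValidationError(
            f"target {target} outside achievable ADS range "
            f"({ads.min():.3f}, {ads.max():.3f})"
        )

    def gap(lam: float) -> float:
        # subtract max for numerical stability
        w = base * np.exp(lam * (ads - ads.max()))
        return float(np.average(ads, weights=w)) - target

    lo, hi = -1.0, 1.0
    while gap(lo) > 0:
        lo *= 2
        if lo < -1e6:
            raise ValidationError("tilt solve failed (lower bracket)")
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValidationError("tilt solve failed (upper bracket)")
    lam = brentq(gap, lo, hi, xtol=1e-12)
    w = base * np.exp(lam * (ads - ads.max()))
    return w / w.max()


def generate_pools(
    spec: SyntheticSpec, mdp_ads: dict[str, float]
) -> list[ExpressionTable]:
    """Expression tables, optionally tilted to hit target pool scores."""
    if not spec.pools:
        raise ValidationError("no pools in spec")
    if not mdp_ads:
        raise ValidationError("mdp_ads is empty")
    pids = list(mdp_ads)
    ads = np.array([mdp_ads[p] for p in pids])
    tables = []
    for pool in spec.pools:
        rng = _rng(spec.seed, f"pool:{pool.pool_id}")
        base = rng.lognormal(mean=0.0, sigma=pool.lognormal_sigma, size=len(pids))
        if pool.target_score is not None:
            w = _tilted_weights(base, ads, pool.target_score)
        else:
            w = base
        tables.append(
            ExpressionTable(
                pool_id=pool.pool_id,
                mean_age=pool.mean_age,
                abundance={p: float(a) for p, a in zip(pids, w)},
            )
        )
    return tables
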