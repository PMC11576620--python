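"""Whole-protein binary disorder classifiers: CH, CDF and their quadrants.

The charge–hydropathy (CH) classifier places a protein by its mean absolute
net charge ⟨R⟩ against its mean scaled hydropathy ⟨H⟩ relative to a linear
boundary ⟨R⟩ = slope·⟨H⟩ + intercept; disordered proteins sit above the
line (high charge, low hydropathy).  The signed distance is

    ΔCH = ⟨R⟩ − (slope·⟨H⟩ + intercept),        ΔCH > 0 ⇒ disordered.

The CDF classifier compares a protein's cumulative distribution of
per-residue disorder scores against a fixed boundary curve sampled at a
handful of score thresholds; ordered proteins accumulate low scores, so
their curves run above the boundary:

    ΔCDF = mean over boundary points of (curve_y − boundary_y),
    ΔCDF > 0 ⇒ ordered.

Crossing the two gives the CH-CDF quadrants:

* Q1 (ΔCH<0, ΔCDF>0) — ordered by both;
* Q2 (ΔCH<0, ΔCDF<0) — disordered by CDF only (molten-globule-like);
* Q3 (ΔCH>0, ΔCDF<0) — disordered by both;
* Q4 (ΔCH>0, ΔCDF>0) — disordered by CH only.

Exact zeros are resolved by treating ΔCH ≥ 0 as the disordered side and
ΔCDF ≥ 0 as the ordered side (and logging the tie).

The module also provides a self-contained sliding-window baseline
predictor built from the same charge/hydropathy geometry, so the pipeline
can run end-to-end without any external per-residue predictor output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .datatypes import DisorderTrack, ValidationError

logger = logging.getLogger(__name__)

QUADRANT_MEANING = {
    "Q1": "ordered by CH and CDF",
    "Q2": "disordered by CDF only (molten-globule-like)",
    "Q3": "disordered by CH and CDF",
    "Q4": "disordered by CH only",
}


@dataclass(frozen=True)
class BoundaryConfig:
    """Boundary constants for the CH and CDF classifiers.

    All constants are user-overridable; the bundled defaults carry the
    standard CH line and a synthetic CDF boundary (see
    ``data/boundary_default.yaml``).
    """

    ch_slope: float
    ch_intercept: float
    cdf_boundary_points: tuple[tuple[float, float], ...]
    hydropathy_scale: dict[str, float]
    hydropathy_window: int = 5

    def __post_init__(self) -> None:
        pts = self.cdf_boundary_points
        if len(pts) < 2:
            raise ValidationError("cdf_boundary_points needs >= 2 points")
        xs = [x for x, _ in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValidationError("cdf_boundary_points must be strictly increasing in x")
        if not all(0 <= x <= 1 and 0 <= y <= 1 for x, y in pts):
            raise ValidationError("cdf boundary coordinates must lie in [0, 1]")
        if self.hydropathy_window < 1 or self.hydropathy_window % 2 == 0:
            raise ValidationError("hydropathy_window must be odd and positive")

    @property
    def cdf_x(self) -> np.ndarray:
        return np.array([x for x, _ in self.cdf_boundary_points])

    @property
    def cdf_y(self) -> np.ndarray:
        return np.array([y for _, y in self.cdf_boundary_points])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BoundaryConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            ch_slope=float(raw["ch_slope"]),
            ch_intercept=float(raw["ch_intercept"]),
            cdf_boundary_points=tuple((float(x), float(y)) for x, y in raw["cdf_boundary"]),
            hydropathy_scale={k: float(v) for k, v in raw["hydropathy_scale"].items()},
            hydropathy_window=int(raw.get("hydropathy_window", 5)),
        )

    @classmethod
    def default(cls) -> "BoundaryConfig":
        ref = resources.files("idproteome") / "data" / "boundary_default.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def _scaled_hydropathy_values(sequence: str, config: BoundaryConfig) -> np.ndarray:
    scale = config.hydropathy_scale
    lo = min(scale.values())
    hi = max(scale.values())
    try:
        return np.array([(scale[c] - lo) / (hi - lo) for c in sequence])
    except KeyError as exc:
        raise ValidationError(f"residue {exc.args[0]!r} missing from hydropathy scale")


def mean_scaled_hydropathy(sequence: str, config: BoundaryConfig) -> float:
    """⟨H⟩: min–max-scaled hydropathy averaged over sliding windows.

    Per-residue values are averaged within each full window of the
    configured width, then across windows.
    """
    w = config.hydropathy_window
    if len(sequence) < w:
        raise ValidationError(f"sequence length {len(sequence)} < window {w}")
    h = _scaled_hydropathy_values(sequence, config)
    window_means = np.convolve(h, np.ones(w) / w, mode="valid")
    return float(window_means.mean())


def mean_net_charge(sequence: str) -> float:
    """⟨R⟩: |#(K,R) − #(D,E)| / length; histidine neutral, no pH model."""
    if len(sequence) < 1:
        raise ValidationError("empty sequence")
    pos = sequence.count("K") + sequence.count("R")
    neg = sequence.count("D") + sequence.count("E")
    return abs(pos - neg) / len(sequence)


def delta_ch(sequence: str, config: BoundaryConfig) -> float:
    """Signed distance above the CH boundary; positive ⇒ disordered."""
    h = mean_scaled_hydropathy(sequence, config)
    r = mean_net_charge(sequence)
    return r - (config.ch_slope * h + config.ch_intercept)


def cdf_curve(track: DisorderTrack, thresholds: np.ndarray) -> np.ndarray:
    """At each threshold x, the fraction of residues with score ≤ x."""
    thresholds = np.asarray(thresholds, dtype=float)
    return np.array(
        [np.count_nonzero(track.scores <= x) / len(track) for x in thresholds]
    )


def delta_cdf(track: DisorderTrack, config: BoundaryConfig) -> float:
    """Mean signed elevation of the track's CDF above the boundary curve.

    Positive ⇒ the curve runs above the boundary ⇒ ordered.
    """
    curve = cdf_curve(track, config.cdf_x)
    return float(np.mean(curve - config.cdf_y))


def assign_quadrant(dch: float, dcdf: float) -> str:
    """Quadrant from the signs of (ΔCH, ΔCDF) under the documented tie rule."""
    if not (np.isfinite(dch) and np.isfinite(dcdf)):
        raise ValidationError("ΔCH and ΔCDF must be finite")
    if dch == 0.0 or dcdf == 0.0:
        logger.info("boundary tie at (ΔCH=%g, ΔCDF=%g)", dch, dcdf)
    ch_disordered = dch >= 0.0
    cdf_ordered = dcdf >= 0.0
    if ch_disordered:
        return "Q4" if cdf_ordered else "Q3"
    return "Q1" if cdf_ordered else "Q2"


@dataclass(frozen=True)
class ChCdfPoint:
    protein_id: str
    delta_ch: float
    delta_cdf: float
    quadrant: str


def ch_cdf_point(
    protein_id: str,
    sequence: str,
    track: DisorderTrack,
    config: BoundaryConfig,
) -> ChCdfPoint:
    dch = delta_ch(sequence, config)
    dcdf = delta_cdf(track, config)
    return ChCdfPoint(protein_id, dch, dcdf, assign_quadrant(dch, dcdf))


def baseline_disorder_track(
    sequence: str,
    config: BoundaryConfig,
    gain: float = 3.0,
    protein_id: str = "",
) -> DisorderTrack:
    """Sliding-window baseline disorder predictor from CH geometry.

    For each residue, windowed mean scaled hydropathy h and windowed mean
    absolute net charge q are computed over a centered window (shrunk at
    the termini); the CH-line margin (slope·h + intercept) − q is negated
    and squashed through a logistic so scores lie in (0, 1), higher = more
    disordered.  This is a deliberately simple stand-in with the right
    qualitative geometry (charged/hydrophilic → disordered), not a trained
    predictor.
    """
    L = len(sequence)
    if L < 1:
        raise ValidationError("empty sequence")
    half = config.hydropathy_window // 2
    h = _scaled_hydropathy_values(sequence, config)
    charge = np.zeros(L)
    for i, c in enumerate(sequence):
        charge[i] = 1.0 if c in "KR" else (-1.0 if c in "DE" else 0.0)
    scores = np.empty(L)
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        hw = h[lo:hi].mean()
        qw = abs(charge[lo:hi].sum()) / (hi - lo)
        raw = (config.ch_slope * hw + config.ch_intercept) - qw
        scores[i] = 1.0 / (1.0 + np.exp(gain * raw))
    return DisorderTrack(protein_id=protein_id, predictor="baseline", scores=scores)
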