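"""Group comparison statistics and the expression-weighted pool score.

One-way ANOVA (classical F = MS_between / MS_within) and Tukey HSD compare
per-protein ADS/PPDR distributions across proteome groups; Pearson
chi-squared tests independence of classification or quadrant count tables;
the normalized pool disorder score is the expression-weighted mean of
per-protein MDP average-disorder scores within a sample pool,

    score = Σᵢ abundanceᵢ · adsᵢ / Σᵢ abundanceᵢ ∈ [0, 1].

Tukey intervals use the studentized-range procedure with the Tukey–Kramer
unequal-n adjustment (via statsmodels), appropriate when group sizes differ
widely.  Chi-squared applies no continuity correction.  P-values are
returned at full precision; any "<0.01"-style bucketing is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import ExpressionTable, ValidationError


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int

    def summary(self) -> str:
        return (
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.4g}, p = {self.p_value:.4g}"
        )


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float
    ci_low: float
    ci_high: float
    reject_null: bool


@dataclass
class ChiSquaredResult:
    statistic: float
    dof: int
    p_value: float
    expected: np.ndarray

    def summary(self) -> str:
        return (
            f"chi-squared = {self.statistic:.4g}, dof = {self.dof}, "
            f"p = {self.p_value:.4g}"
        )


@dataclass(frozen=True)
class PoolDisorderScore:
    pool_id: str
    mean_age: float
    score: float


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("at least 2 groups required")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} needs >= 2 values")
        out[name] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across named groups."""
    gs = _validate_groups(groups)
    arrs = list(gs.values())
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValidationError("F undefined: zero variance within and between groups")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f_statistic=float(f), p_value=p, df_between=df_b, df_within=df_w)


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[TukeyPair]:
    """Tukey HSD simultaneous pairwise comparisons (Tukey–Kramer for unequal n)."""
    gs = _validate_groups(groups)
    endog = np.concatenate(list(gs.values()))
    labels = np.concatenate([[name] * arr.size for name, arr in gs.items()])
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    pairs = []
    ci = res.confint
    for i, (a, b) in enumerate(combinations(res.groupsunique, 2)):
        pairs.append(
            TukeyPair(
                group_a=str(a),
                group_b=str(b),
                mean_difference=float(res.meandiffs[i]),
                ci_low=float(ci[i, 0]),
                ci_high=float(ci[i, 1]),
                reject_null=bool(res.reject[i]),
            )
        )
    return pairs


def chi_squared_independence(table) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on an r×c count table.

    Expected counts come from the product of margins over the grand total;
    no continuity correction is applied.
    """
    obs = np.asarray(table)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("table must be at least 2x2")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)):
            raise ValidationError("counts must be integers")
        obs = np.round(obs).astype(np.int64)
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("every row and column sum must be > 0")
    res = sps.chi2_contingency(obs, correction=False)
    return ChiSquaredResult(
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        expected=np.asarray(res.expected_freq),
    )


def normalized_pool_disorder(
    expression: ExpressionTable, mdp_ads: Mapping[str, float]
) -> PoolDisorderScore:
    """Expression-weighted mean MDP ADS of a pool, normalized by total expression."""
    num = 0.0
    den = 0.0
    for pid, a in expression.abundance.items():
        if a == 0.0:
            continue
        if pid not in mdp_ads:
            raise ValidationError(
                f"pool {expression.pool_id}: protein {pid!r} has positive abundance "
                "but no MDP ADS"
            )
        num += a * mdp_ads[pid]
        den += a
    if den == 0.0:
        raise ValidationError(f"pool {expression.pool_id}: zero total abundance")
    return PoolDisorderScore(
        pool_id=expression.pool_id, mean_age=expression.mean_age, score=num / den
    )


def quadrant_share_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-wise percentage shares of a group × category count table."""
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
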