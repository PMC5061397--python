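"""Formal diel-activity categorization: ANOVA, Steel--Dwass ranking, labels.

A species' activity type over a scope (a season, or the whole year) is
decided from its daily photographic frequencies in the three diel periods:

1. One-way ANOVA across the three periods.  No significant difference at
   level ``alpha`` means the animal is active throughout the cycle:
   **cathemeral (Ca)**.
2. Otherwise the Steel--Dwass all-pairs nonparametric comparison ranks the
   periods.  If the period with the largest mean frequency beats both others
   pairwise, the label is the corresponding simple category -- **D**
   (day-time), **N** (night-time) or **Cr** (twilight / crepuscular).  If the
   top two periods are mutually indistinguishable but both beat the third,
   the label is their composite (e.g. **D/N**, **Cr/N**).  Any other pattern
   (ANOVA significant but no pair separated) is reported as
   **undetermined** rather than silently mislabelled.

The Steel--Dwass statistic for a pair of groups is the tie-corrected
standardized Wilcoxon rank-sum computed on those two groups alone, referred
to the studentized-range distribution with k groups and infinite degrees of
freedom via t* = sqrt(2) |z|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .solar import PERIODS

__all__ = [
    "ClassificationResult",
    "oneway_anova",
    "steel_dwass",
    "assign_category",
    "classify_species",
    "classify_all",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: simple category per winning diel period
_PERIOD_LABEL = {"day": "D", "night": "N", "twilight": "Cr"}

#: composite ordering: D before N, Cr before D and N
_COMPOSITE_ORDER = {"Cr": 0, "D": 1, "N": 2}


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the ANOVA + Steel--Dwass categorization for one species x scope."""

    species: str
    scope: str
    period_means: dict[str, float]
    period_ses: dict[str, float]
    n_days: int
    f_statistic: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]
    category: str


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA F and p.

    Degenerate all-constant input (zero variance everywhere, equal means)
    carries no evidence of a difference and returns (0, 1) by convention.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("one-way ANOVA needs >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    if all(np.ptp(a) == 0.0 for a in arrs):
        # equal-variance zero within-group scatter but different means:
        # infinite evidence of separation
        return math.inf, 0.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def _pairwise_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic on two groups alone."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))  # mid-ranks for ties
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # every observation tied
        return 0.0
    return (w - mean_w) / math.sqrt(var_w)


def steel_dwass(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Steel--Dwass all-pairs comparison p values.

    For each pair of groups the statistic is the standardized rank sum on
    the pair alone (mid-ranks, tie-corrected variance), referred to the
    studentized-range distribution with ``k = len(groups)`` and infinite
    degrees of freedom through ``t* = sqrt(2) |z|``.  Returns
    ``{(i, j): p}`` for i < j.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("steel_dwass needs >= 2 groups")
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(k), 2):
        z = _pairwise_z(arrs[i], arrs[j])
        t_star = math.sqrt(2.0) * abs(z)
        out[(i, j)] = float(stats.studentized_range.sf(t_star, k, np.inf))
    return out


def assign_category(
    period_means: dict[str, float],
    anova_p: float,
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Map the test results to a diel-activity label.

    Ca if the ANOVA finds no difference; else D / N / Cr when the most
    active period beats both others pairwise; a composite (e.g. D/N) when
    the top two are mutually indistinguishable but both beat the third;
    undetermined otherwise.  Scale-invariant in the means.
    """
    if not np.isfinite(anova_p):
        raise ValueError("anova_p must be finite")
    if anova_p >= alpha:
        return "Ca"

    def pair_p(a: str, b: str) -> float:
        return pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))

    ranked = sorted(period_means, key=lambda p: period_means[p], reverse=True)
    top, second, third = ranked
    if pair_p(top, second) < alpha and pair_p(top, third) < alpha:
        return _PERIOD_LABEL[top]
    if (
        pair_p(top, second) >= alpha
        and pair_p(top, third) < alpha
        and pair_p(second, third) < alpha
    ):
        pair = sorted((_PERIOD_LABEL[top], _PERIOD_LABEL[second]),
                      key=_COMPOSITE_ORDER.__getitem__)
        return f"{pair[0]}/{pair[1]}"
    return "undetermined"


def classify_species(
    freq_table: pd.DataFrame,
    species: str,
    scope: str = "annual",
    alpha: float = DEFAULT_ALPHA,
) -> ClassificationResult:
    """Classify one species over a scope from its daily-frequency table.

    ``freq_table`` is the output of
    :func:`dielclass.activity.daily_frequencies`; ``scope`` is ``'annual'``
    or a season name.  With fewer than 4 days of data the result is
    ``undetermined`` with NaN statistics.
    """
    sub = freq_table[freq_table["species"] == species]
    if scope != "annual":
        sub = sub[sub["season"] == scope]
    groups = {p: sub.loc[sub["period"] == p, "frequency"].to_numpy(float) for p in PERIODS}
    n_days = sub["date"].nunique()
    means = {p: (float(np.mean(g)) if g.size else math.nan) for p, g in groups.items()}
    ses = {
        p: (float(np.std(g, ddof=1) / math.sqrt(g.size)) if g.size > 1 else math.nan)
        for p, g in groups.items()
    }
    if n_days < 4 or any(g.size < 4 for g in groups.values()):
        logger.warning("%s/%s: %d days of data, too few to classify", species, scope, n_days)
        return ClassificationResult(species, scope, means, ses, n_days,
                                    math.nan, math.nan, {}, "undetermined")
    f, p = oneway_anova([groups[q] for q in PERIODS])
    pw_idx = steel_dwass([groups[q] for q in PERIODS])
    pairwise = {(PERIODS[i], PERIODS[j]): v for (i, j), v in pw_idx.items()}
    category = assign_category(means, p, pairwise, alpha)
    return ClassificationResult(species, scope, means, ses, n_days, f, p,
                                pairwise, category)


def classify_all(
    freq_table: pd.DataFrame,
    scopes: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Classify every species over every scope; tidy frame mirroring the
    per-period mean +/- SE, category and ANOVA p layout."""
    from .solar import SEASONS

    if scopes is None:
        scopes = ["annual", *SEASONS]
    rows = []
    for sp in sorted(freq_table["species"].unique()):
        for scope in scopes:
            r = classify_species(freq_table, sp, scope, alpha)
            row = {"species": sp, "scope": scope, "category": r.category,
                   "F": r.f_statistic, "anova_p": r.anova_p, "n_days": r.n_days}
            for p in PERIODS:
                row[f"{p}_mean"] = r.period_means.get(p, math.nan)
                row[f"{p}_se"] = r.period_ses.get(p, math.nan)
            rows.append(row)
    return pd.DataFrame(rows)
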