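"""Four-point "positive attributes" country index and its group comparison.

Each country scores one point per attribute associated with higher dietary
LCn-3: per-capita GDP above the median, ranked fish price below the median
(price runs opposite to LCn-3, so this attribute is inverted), total fish
supply above the median, and percent marine fish above the median. All four
comparisons are strict, so a country sitting exactly at a median earns no
point for that attribute. Only countries with all four variables observed
are scored; medians are taken over that complete-case set by default.

The score distribution is compared across the four guideline groups with a
standard fixed-effects one-way ANOVA, treating the integer score as a
continuous response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError
from .records import CountryRecord

_INDEX_VARIABLES = ("gdp_percap", "price_rank", "total_fish", "pct_marine")


@dataclass(frozen=True)
class IndexScore:
    """One country's four-attribute score and its component booleans."""

    country_id: str
    score: int
    gdp_above: bool
    price_below: bool
    total_fish_above: bool
    pct_marine_above: bool
    fbdg_group: str

    def __post_init__(self):
        components = (self.gdp_above, self.price_below,
                      self.total_fish_above, self.pct_marine_above)
        if self.score != sum(components):
            raise ValueError(
                f"score {self.score} does not equal the number of true "
                f"components ({sum(components)}) for {self.country_id!r}")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary for scores grouped by guideline category."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: Mapping[str, float]
    group_ns: Mapping[str, int]


def compute_index(records: Sequence[CountryRecord],
                  medians: Literal["complete_case", "available_case"] = "complete_case",
                  ) -> tuple[list[IndexScore], list[str]]:
    """Score every complete-case country on the four-attribute index.

    Returns the scores plus the identifiers of countries excluded for a
    missing variable. Under ``complete_case`` (default) each attribute's
    median is computed over the scored countries only; ``available_case``
    computes each median over all countries where that single variable is
    observed.
    """
    complete = [r for r in records
                if all(r.get(v) is not None for v in _INDEX_VARIABLES)]
    complete_ids = {r.country_id for r in complete}
    excluded = [r.country_id for r in records if r.country_id not in complete_ids]
    if len(complete) < 2:
        raise InsufficientDataError(
            f"need at least 2 complete-case countries to compute index "
            f"medians, got {len(complete)}")
    if medians == "complete_case":
        pool = {v: [r.get(v) for r in complete] for v in _INDEX_VARIABLES}
    elif medians == "available_case":
        pool = {v: [r.get(v) for r in records if r.get(v) is not None]
                for v in _INDEX_VARIABLES}
    else:
        raise ValueError(f"unknown medians policy: {medians!r}")
    med = {v: float(np.median(pool[v])) for v in _INDEX_VARIABLES}

    scores = []
    for r in complete:
        comp = {
            "gdp_above": r.gdp_percap > med["gdp_percap"],
            "price_below": r.price_rank < med["price_rank"],
            "total_fish_above": r.total_fish > med["total_fish"],
            "pct_marine_above": r.pct_marine > med["pct_marine"],
        }
        scores.append(IndexScore(country_id=r.country_id,
                                 score=sum(comp.values()),
                                 fbdg_group=r.fbdg_status.group_label,
                                 **comp))
    return scores, excluded


def anova_by_group(scores: Sequence[IndexScore]) -> AnovaResult:
    """One-way ANOVA of index scores across guideline groups.

    Groups with zero members are dropped with a warning. Raises
    :class:`DegenerateDesignError` when fewer than two non-empty groups
    remain or no group has two members (no within-group variance estimate).
    """
    groups: dict[str, list[int]] = {}
    for s in scores:
        groups.setdefault(s.fbdg_group, []).append(s.score)
    empty = [g for g, vals in groups.items() if not vals]
    if empty:
        warnings.warn(f"dropping empty guideline groups: {empty}", stacklevel=2)
        groups = {g: v for g, v in groups.items() if v}
    if len(groups) < 2:
        raise DegenerateDesignError(
            f"one-way ANOVA needs at least 2 groups, got {len(groups)}")
    if all(len(v) < 2 for v in groups.values()):
        raise DegenerateDesignError(
            "one-way ANOVA needs at least one group with 2 or more members")
    names = sorted(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    n_total = sum(len(s) for s in samples)
    df_between = len(samples) - 1
    df_within = n_total - len(samples)
    with warnings.catch_warnings():
        # scipy warns when every observation is identical; F=0, p=1 is the
        # documented convention for a contrast-free design.
        warnings.simplefilter("ignore")
        f_stat, p_value = stats.f_oneway(*samples)
    if np.isnan(f_stat):
        # every observation identical: no contrast at all
        f_stat, p_value = 0.0, 1.0
    elif np.isinf(f_stat):
        p_value = 0.0  # between-group contrast with zero within-group variance
    return AnovaResult(
        f_stat=float(f_stat), p_value=float(p_value),
        df_between=df_between, df_within=df_within,
        group_means={g: float(np.mean(groups[g])) for g in names},
        group_ns={g: len(groups[g]) for g in names})
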