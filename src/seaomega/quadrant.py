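"""Median-quadrant ("quadrate") association analysis.

The procedure classifies each country as below or above the median on two
variables, tabulates the four quadrant counts into a 2x2 table, tests
independence with the uncorrected Pearson chi-square on 1 degree of freedom,
and reads the association's direction off the quadrant concordance: a
majority of countries in the below-below plus above-above cells is a
positive association, a majority in the discordant cells a negative one.
Because only each country's position relative to a median enters, the method
depends on the two variables only through their ranks and is invariant under
any strictly increasing transform of either one.

Significance across a family of such comparisons is protected Bonferroni
style: each pair is judged against ``family_alpha / m`` for ``m`` pairs
(0.05 / 6 ≈ 0.008 for the canonical six-comparison family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateTableWarning, InsufficientDataError
from .records import CountryRecord, FbdgStatus

BELOW = "below"
ABOVE = "above"

TiePolicy = Literal["strict_above", "exclude_ties"]
Direction = Literal["positive", "negative", "none"]


class Dichotomized(NamedTuple):
    """Labels from a median split plus the indices of any dropped ties."""

    labels: list  # per input position: BELOW, ABOVE, or None
    median: float
    ties_dropped: list  # indices whose value equalled the median (exclude_ties)


@dataclass(frozen=True)
class QuadrantTable:
    """2x2 quadrant counts from median dichotomization of two variables.

    Cell names read x then y: ``bb`` = x below, y below; ``ba`` = x below,
    y above; ``ab`` = x above, y below; ``aa`` = x above, y above.
    """

    bb: int
    ba: int
    ab: int
    aa: int
    x_name: str = "x"
    y_name: str = "y"

    def __post_init__(self):
        for cell in ("bb", "ba", "ab", "aa"):
            v = getattr(self, cell)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {cell} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.bb + self.ba + self.ab + self.aa

    def as_array(self) -> np.ndarray:
        """Counts as a 2x2 array with rows = x (below, above), cols = y."""
        return np.array([[self.bb, self.ba], [self.ab, self.aa]], dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square verdict for one variable pair in a protected family."""

    table: QuadrantTable
    chi2: float
    p_value: float
    direction: Direction
    alpha_protected: float
    significant: bool

    @property
    def n(self) -> int:
        return self.table.n


def dichotomize(values: Sequence, policy: TiePolicy = "strict_above") -> Dichotomized:
    """Label each value ``below``/``above`` the median of the non-missing values.

    Under ``strict_above`` (default) a value is ``above`` iff it is strictly
    greater than the median, so values equal to the median count as below.
    Under ``exclude_ties`` values equal to the median are dropped (labelled
    ``None``) and their indices reported. Missing values (``None``/NaN) are
    never labelled.

    Raises
    ------
    InsufficientDataError
        if fewer than two non-missing values are supplied.
    ConfigurationError
        for an unknown tie policy.
    """
    if policy not in ("strict_above", "exclude_ties"):
        raise ConfigurationError(f"unknown tie policy: {policy!r}")
    arr = np.array([np.nan if v is None else float(v) for v in values], dtype=float)
    present = ~np.isnan(arr)
    if present.sum() < 2:
        raise InsufficientDataError(
            f"need at least 2 non-missing values to dichotomize, got {int(present.sum())}")
    med = float(np.median(arr[present]))
    labels: list = [None] * len(arr)
    ties: list = []
    for i, (ok, v) in enumerate(zip(present, arr)):
        if not ok:
            continue
        if v > med:
            labels[i] = ABOVE
        elif v < med:
            labels[i] = BELOW
        else:
            if policy == "exclude_ties":
                ties.append(i)
            else:
                labels[i] = BELOW
    return Dichotomized(labels=labels, median=med, ties_dropped=ties)


def build_quadrant_table(x_labels: Sequence, y_labels: Sequence,
                         x_name: str = "x", y_name: str = "y") -> QuadrantTable:
    """Tabulate aligned below/above labels into quadrant counts.

    Positions where either label is missing (``None``) are dropped, so the
    table is built on the pairwise-complete subset.

    Raises
    ------
    InsufficientDataError
        if no complete pairs remain.
    """
    if len(x_labels) != len(y_labels):
        raise ValueError(f"label collections must align: {len(x_labels)} != {len(y_labels)}")
    counts = {"bb": 0, "ba": 0, "ab": 0, "aa": 0}
    for x, y in zip(x_labels, y_labels):
        if x is None or y is None:
            continue
        key = ("b" if x == BELOW else "a") + ("b" if y == BELOW else "a")
        counts[key] += 1
    if sum(counts.values()) == 0:
        raise InsufficientDataError("no complete (x, y) pairs to tabulate")
    return QuadrantTable(x_name=x_name, y_name=y_name, **counts)


def pearson_chi2(table: QuadrantTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square and its chi-square(1) upper-tail p.

    Closed form for a 2x2 table::

        chi2 = n (bb*aa - ba*ab)^2 / [(bb+ba)(ab+aa)(bb+ab)(ba+aa)]

    No continuity correction is applied. A table with a zero row or column
    margin has no contrast; its statistic is defined as 0 with p = 1 and a
    :class:`DegenerateTableWarning` is emitted.
    """
    bb, ba, ab, aa = table.bb, table.ba, table.ab, table.aa
    n = table.n
    if n < 1:
        raise InsufficientDataError("empty quadrant table")
    r0, r1 = bb + ba, ab + aa
    c0, c1 = bb + ab, ba + aa
    if min(r0, r1, c0, c1) == 0:
        warnings.warn(
            f"degenerate 2x2 table for ({table.x_name}, {table.y_name}): "
            "a zero margin leaves no contrast; chi2 := 0",
            DegenerateTableWarning, stacklevel=2)
        return 0.0, 1.0
    chi2 = n * (bb * aa - ba * ab) ** 2 / (r0 * r1 * c0 * c1)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def association_direction(table: QuadrantTable) -> Direction:
    """Direction by quadrant concordance.

    ``positive`` when the concordant cells (bb + aa) hold the majority,
    ``negative`` when the discordant cells (ba + ab) do, ``none`` on a tie.
    """
    if table.n < 1:
        raise InsufficientDataError("empty quadrant table")
    concordant = table.bb + table.aa
    discordant = table.ba + table.ab
    if concordant > discordant:
        return "positive"
    if concordant < discordant:
        return "negative"
    return "none"


def _variable_values(records: Sequence[CountryRecord], name: str,
                     fbdg_positive: frozenset) -> list:
    """Extract a named analysis variable as floats with None for missing.

    ``fbdg_status`` is mapped to a presence/absence indicator: 1 when the
    country's guideline carries any seafood recommendation, 0 otherwise
    (which statuses count as "present" is configurable).
    """
    if name == "fbdg_status":
        return [1.0 if r.fbdg_status.value in fbdg_positive else 0.0 for r in records]
    if name not in CountryRecord.__dataclass_fields__ or name == "country_id":
        raise ConfigurationError(f"unknown analysis variable: {name!r}")
    return [r.get(name) for r in records]


DEFAULT_FBDG_POSITIVE = frozenset({
    FbdgStatus.REC_WITH_SERVING.value,
    FbdgStatus.REC_WITHOUT_SERVING.value,
})

#: The canonical six-comparison family: each covariate against dietary LCn-3.
DEFAULT_PAIRS = (
    ("recommended_g_day", "lcn3_mg_day"),
    ("fbdg_status", "lcn3_mg_day"),
    ("gdp_percap", "lcn3_mg_day"),
    ("price_rank", "lcn3_mg_day"),
    ("total_fish", "lcn3_mg_day"),
    ("pct_marine", "lcn3_mg_day"),
)


def analyze_pair(records: Sequence[CountryRecord], x_name: str, y_name: str,
                 alpha_protected: float, tie_policy: TiePolicy = "strict_above",
                 fbdg_positive: frozenset = DEFAULT_FBDG_POSITIVE) -> AssociationResult:
    """Run the median-quadrant test for one (x, y) variable pair.

    The medians are computed on the pair's own pairwise-complete subset, so
    different pairs may use different country subsets when columns have
    missing entries. ``fbdg_status`` is dichotomized by the presence of a
    seafood recommendation rather than by a median.
    """
    xs = _variable_values(records, x_name, fbdg_positive)
    ys = _variable_values(records, y_name, fbdg_positive)
    complete = [i for i, (x, y) in enumerate(zip(xs, ys)) if x is not None and y is not None]
    if len(complete) < 2:
        raise InsufficientDataError(
            f"fewer than 2 complete pairs for ({x_name}, {y_name})")
    xs_c = [xs[i] for i in complete]
    ys_c = [ys[i] for i in complete]
    if x_name == "fbdg_status":
        x_labels = [ABOVE if v > 0 else BELOW for v in xs_c]
    else:
        x_labels = dichotomize(xs_c, tie_policy).labels
    y_labels = dichotomize(ys_c, tie_policy).labels
    table = build_quadrant_table(x_labels, y_labels, x_name, y_name)
    chi2, p = pearson_chi2(table)
    direction = association_direction(table)
    significant = bool(p < alpha_protected) and chi2 > 0
    return AssociationResult(table=table, chi2=chi2, p_value=p,
                             direction=direction,
                             alpha_protected=alpha_protected,
                             significant=significant)


def run_family(records: Sequence[CountryRecord],
               pairs: Iterable[tuple[str, str]] = DEFAULT_PAIRS,
               family_alpha: float = 0.05,
               tie_policy: TiePolicy = "strict_above",
               fbdg_positive: frozenset = DEFAULT_FBDG_POSITIVE,
               ) -> list[AssociationResult]:
    """Run a protected family of median-quadrant comparisons.

    Each pair is tested as in :func:`analyze_pair`; every result carries
    ``alpha_protected = family_alpha / m`` where ``m`` is the number of
    pairs (the Bonferroni-protected per-comparison threshold).
    """
    pairs = list(pairs)
    if not pairs:
        raise ConfigurationError("pairs must be a nonempty list of (x, y) names")
    if not (0.0 < family_alpha < 1.0):
        raise ConfigurationError(f"family_alpha must lie in (0, 1), got {family_alpha!r}")
    alpha_protected = family_alpha / len(pairs)
    return [analyze_pair(records, x, y, alpha_protected, tie_policy, fbdg_positive)
            for x, y in pairs]
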