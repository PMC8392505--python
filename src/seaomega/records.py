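"""Core record types for country-level covariates and species consumption.

A :class:`CountryRecord` carries one country's dietary long-chain omega-3
(LCn-3, the sum of EPA and DHA, mg per capita per day), its food-based
dietary guideline (FBDG) status, and the covariates the association analysis
uses: recommended seafood serving (g/day, where the guideline states one),
per-capita GDP, the ordinal rank of national fish price, total per-capita
fish supply, and the percentage of that supply of marine origin. Missing
values are represented as ``None``.

A :class:`SpeciesConsumption` carries one seafood item's per-capita
consumption (g/week) and its EPA+DHA density (mg per 100 g edible portion).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass


class FbdgStatus(str, enum.Enum):
    """National food-based dietary guideline status with respect to seafood.

    ``NONE``
        the country has no FBDG at all;
    ``NO_RECOMMENDATION``
        an FBDG exists but does not mention seafood;
    ``REC_WITH_SERVING``
        the FBDG recommends seafood and states a serving size (g/day);
    ``REC_WITHOUT_SERVING``
        the FBDG recommends seafood but states no serving size.
    """

    NONE = "none"
    NO_RECOMMENDATION = "no_recommendation"
    REC_WITH_SERVING = "rec_with_serving"
    REC_WITHOUT_SERVING = "rec_without_serving"

    @property
    def has_seafood_recommendation(self) -> bool:
        return self in (FbdgStatus.REC_WITH_SERVING, FbdgStatus.REC_WITHOUT_SERVING)

    @property
    def group_label(self) -> str:
        """Short display label for the four guideline groups."""
        return _GROUP_LABELS[self]


_GROUP_LABELS = {
    FbdgStatus.NONE: "None",
    FbdgStatus.NO_RECOMMENDATION: "NR",
    FbdgStatus.REC_WITH_SERVING: "FBDG-s",
    FbdgStatus.REC_WITHOUT_SERVING: "no g/d",
}

#: Numeric covariate column names of a country table, in canonical order.
COVARIATE_COLUMNS = (
    "recommended_g_day",
    "gdp_percap",
    "price_rank",
    "total_fish",
    "pct_marine",
)

#: Full canonical column order of a country table.
COUNTRY_COLUMNS = ("country_id", "lcn3_mg_day", "fbdg_status") + COVARIATE_COLUMNS


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class CountryRecord:
    """One country's covariates, FBDG status, and dietary LCn-3 level."""

    country_id: str
    lcn3_mg_day: float | None
    fbdg_status: FbdgStatus
    recommended_g_day: float | None = None
    gdp_percap: float | None = None
    price_rank: int | None = None
    total_fish: float | None = None
    pct_marine: float | None = None

    def __post_init__(self):
        if not self.country_id:
            raise ValueError("country_id must be a non-empty string")
        object.__setattr__(self, "fbdg_status", FbdgStatus(self.fbdg_status))
        for name in ("lcn3_mg_day", "recommended_g_day", "gdp_percap",
                     "total_fish"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v!r} "
                                 f"for country {self.country_id!r}")
        if not _is_missing(self.gdp_percap) and self.gdp_percap == 0:
            raise ValueError(f"gdp_percap must be positive for country "
                             f"{self.country_id!r}")
        if not _is_missing(self.price_rank) and self.price_rank < 1:
            raise ValueError(f"price_rank must be a positive integer, got "
                             f"{self.price_rank!r} for country {self.country_id!r}")
        pm = self.pct_marine
        if not _is_missing(pm) and not (0.0 <= pm <= 100.0):
            raise ValueError(f"pct_marine must lie in [0, 100], got {pm!r} "
                             f"for country {self.country_id!r}")

    def get(self, name: str):
        """Return a field by column name (``None`` when missing)."""
        value = getattr(self, name)
        return None if _is_missing(value) else value


@dataclass(frozen=True)
class SpeciesConsumption:
    """One seafood item's consumption and EPA+DHA density.

    ``grams_per_week`` is per-capita edible weight; ``epa_dha_mg_per_100g``
    is the combined EPA+DHA content per 100 g edible portion.
    """

    species: str
    grams_per_week: float
    epa_dha_mg_per_100g: float

    def __post_init__(self):
        if not self.species:
            raise ValueError("species must be a non-empty string")
        if self.grams_per_week < 0:
            raise ValueError(f"grams_per_week must be nonnegative for "
                             f"{self.species!r}, got {self.grams_per_week!r}")
        if self.epa_dha_mg_per_100g < 0:
            raise ValueError(f"epa_dha_mg_per_100g must be nonnegative for "
                             f"{self.species!r}, got {self.epa_dha_mg_per_100g!r}")

    @property
    def lcn3_mg_per_day(self) -> float:
        """Daily EPA+DHA intake this item supplies: (g/wk / 7) * (mg/100 g)."""
        return (self.grams_per_week / 7.0) * (self.epa_dha_mg_per_100g / 100.0)


def check_unique(names, what: str) -> None:
    """Raise ``ValueError`` if ``names`` contains duplicates."""
    seen = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {what}: {n!r}")
        seen.add(n)
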