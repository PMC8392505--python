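"""Species-weighted dietary LCn-3 allocation and recommendation scaling.

Given a national consumption profile of listed seafood species (g/week per
capita) with EPA+DHA densities (mg per 100 g), the model

1. converts each species' consumption into a daily EPA+DHA intake,
   ``(g/week / 7) * (mg/100 g / 100)``;
2. imputes the unlisted residual — the fraction ``1 - coverage`` of total
   consumption the listed species do not cover — at the consumption-weighted
   mean density of the listed species;
3. optionally rescales the whole profile proportionally so total seafood
   equals a recommended weekly amount (e.g. 8 oz/week), holding the species
   mix and densities fixed, which multiplies every intake by the same factor
   and leaves all percentage shares unchanged.

The qualitative consequence the model exposes: when the most-consumed
species has the lowest density in the profile, its share of dietary LCn-3
is strictly smaller than its share of consumption — a low-omega-3 staple
(shrimp-like) contributes little even while dominating the plate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import ConfigurationError, InsufficientDataError
from .records import SpeciesConsumption, check_unique

#: Grams per avoirdupois ounce.
GRAMS_PER_OZ = 28.3495
#: Gram equivalent of the 8 oz/week guideline as printed in US dietary
#: guidance (226.7 g rather than the exact 8 * 28.3495 = 226.796 g).
GUIDELINE_8OZ_GRAMS = 226.7

RESIDUAL_LABEL = "other_species"


@dataclass(frozen=True)
class SpeciesContribution:
    """One profile entry's consumption and LCn-3 contribution with shares."""

    grams_per_week: float
    lcn3_mg_per_day: float
    share_of_consumption: float
    share_of_lcn3: float


@dataclass(frozen=True)
class DietSummary:
    """Per-species LCn-3 contributions plus the imputed residual and totals.

    ``scaled``, when present, holds the same profile proportionally extended
    to a recommended weekly total.
    """

    per_species: Mapping[str, SpeciesContribution]
    residual: SpeciesContribution
    total_grams_per_week: float
    total_lcn3_mg_per_day: float
    scaled: "DietSummary | None" = None

    def contribution(self, name: str) -> SpeciesContribution:
        if name == RESIDUAL_LABEL:
            return self.residual
        return self.per_species[name]


def weighted_mean_density(items: Sequence[SpeciesConsumption]) -> float:
    """Consumption-weighted mean EPA+DHA density (mg/100 g) of a profile."""
    total = sum(it.grams_per_week for it in items)
    if total <= 0:
        raise InsufficientDataError(
            "weighted mean density requires positive total consumption")
    return sum(it.grams_per_week * it.epa_dha_mg_per_100g for it in items) / total


def allocate(items: Sequence[SpeciesConsumption], coverage: float = 1.0) -> DietSummary:
    """Allocate dietary LCn-3 across listed species plus an imputed residual.

    ``coverage`` is the fraction of total consumption the listed species
    cover; the implied total is ``listed / coverage`` and the residual mass
    ``total * (1 - coverage)`` is assigned the weighted mean density of the
    listed species. Shares are computed over species plus residual and sum
    to 1.
    """
    if not 0.0 < coverage <= 1.0:
        raise ConfigurationError(f"coverage must lie in (0, 1], got {coverage!r}")
    check_unique([it.species for it in items], "species")
    listed_grams = sum(it.grams_per_week for it in items)
    if listed_grams <= 0:
        raise InsufficientDataError("allocation requires positive listed consumption")

    total_grams = listed_grams / coverage
    residual_grams = total_grams * (1.0 - coverage)
    mean_density = weighted_mean_density(items)
    residual_lcn3 = (residual_grams / 7.0) * (mean_density / 100.0)
    species_lcn3 = {it.species: it.lcn3_mg_per_day for it in items}
    total_lcn3 = sum(species_lcn3.values()) + residual_lcn3

    def contrib(grams, lcn3):
        return SpeciesContribution(
            grams_per_week=grams, lcn3_mg_per_day=lcn3,
            share_of_consumption=grams / total_grams,
            share_of_lcn3=(lcn3 / total_lcn3) if total_lcn3 > 0 else 0.0)

    return DietSummary(
        per_species={it.species: contrib(it.grams_per_week, species_lcn3[it.species])
                     for it in items},
        residual=contrib(residual_grams, residual_lcn3),
        total_grams_per_week=total_grams,
        total_lcn3_mg_per_day=total_lcn3)


def scale_to_recommendation(summary: DietSummary,
                            target_grams_per_week: float) -> DietSummary:
    """Proportionally extend a profile to a recommended weekly total.

    Every entry's grams (listed species and residual alike) are multiplied
    by ``target / total`` with densities unchanged, so total LCn-3 scales by
    exactly the same factor and every percentage share is preserved.
    """
    if target_grams_per_week <= 0:
        raise ConfigurationError(
            f"target_grams_per_week must be positive, got {target_grams_per_week!r}")
    if summary.total_grams_per_week <= 0:
        raise InsufficientDataError("cannot scale a profile with zero total consumption")
    k = target_grams_per_week / summary.total_grams_per_week

    def scale(c: SpeciesContribution) -> SpeciesContribution:
        return replace(c, grams_per_week=c.grams_per_week * k,
                       lcn3_mg_per_day=c.lcn3_mg_per_day * k)

    return DietSummary(
        per_species={name: scale(c) for name, c in summary.per_species.items()},
        residual=scale(summary.residual),
        total_grams_per_week=summary.total_grams_per_week * k,
        total_lcn3_mg_per_day=summary.total_lcn3_mg_per_day * k)


def diet_report(items: Sequence[SpeciesConsumption], coverage: float = 1.0,
                target_grams_per_week: float | None = None) -> DietSummary:
    """Allocate a profile and attach the scaled-to-recommendation scenario."""
    summary = allocate(items, coverage)
    if target_grams_per_week is None:
        return summary
    return replace(summary,
                   scaled=scale_to_recommendation(summary, target_grams_per_week))


_UNIT_TO_G_PER_WEEK = {
    "g/week": 1.0,
    "g/day": 7.0,
    # oz factor depends on the constants mode; handled in convert_units.
}
UNITS = ("oz/week", "g/week", "g/day")


def convert_units(quantity: float, from_unit: str, to_unit: str,
                  guideline_constants: bool = False) -> float:
    """Convert a seafood amount between oz/week, g/week and g/day.

    With ``guideline_constants=True`` the ounce bridge uses the rounded
    gram equivalent printed in US dietary guidance (8 oz = 226.7 g) instead
    of the exact 28.3495 g/oz, so 8 oz/week converts to 226.7 g/week and
    32.385... g/day (32.4 at one-decimal presentation). Results are never
    rounded here; round only at presentation.
    """
    for unit in (from_unit, to_unit):
        if unit not in UNITS:
            raise ConfigurationError(
                f"unknown unit {unit!r}; expected one of {UNITS}")
    oz_to_g = GUIDELINE_8OZ_GRAMS / 8.0 if guideline_constants else GRAMS_PER_OZ

    def to_g_per_week(q, unit):
        if unit == "oz/week":
            return q * oz_to_g
        return q * _UNIT_TO_G_PER_WEEK[unit]

    g_per_week = to_g_per_week(quantity, from_unit)
    if to_unit == "oz/week":
        return g_per_week / oz_to_g
    return g_per_week / _UNIT_TO_G_PER_WEEK[to_unit]
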