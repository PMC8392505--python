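"""Synthetic country tables and species-consumption profiles.

The country generator emulates the statistical structure the association
analysis assumes: a dietary LCn-3 level per country plus covariates whose
rank correlation with LCn-3 is configurable per covariate (0 = null).
Dependence is induced through a Gaussian copula on ranks and the marginals
are then transformed — per-capita GDP log-normal, fish price as a rank
permutation (an ordinal 1..n ranking), total fish supply gamma, percent
marine beta, and dietary LCn-3 normal truncated at zero. Only the rank
structure matters to the median-quadrant method, so the marginal families
are free modelling choices. Missing values are injected independently per
cell (MCAR) at configurable per-column rates; the default rates emulate a
compiled real-world table in which the serving-size column is observed for
roughly 65 of 166 countries, GDP for 160 and price for 146.

The consumption generator emulates a skewed national consumption profile in
which the single most-consumed species carries a low EPA+DHA density while
a minority species carries a high one (the shrimp/salmon pattern), and in
which the listed species cover only a configurable fraction of total
consumption (0.748 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .records import COVARIATE_COLUMNS, CountryRecord, FbdgStatus, SpeciesConsumption

#: Columns that may receive rank-correlation effects and MCAR missingness.
EFFECT_COLUMNS = COVARIATE_COLUMNS + ("fbdg_status",)
MISSINGNESS_COLUMNS = COVARIATE_COLUMNS + ("lcn3_mg_day",)

#: Default effects: sign pattern of the associations the analysis targets
#: (price runs opposite to dietary LCn-3; everything else with it).
DEFAULT_EFFECTS: Mapping[str, float] = {
    "recommended_g_day": 0.45,
    "fbdg_status": 0.30,
    "gdp_percap": 0.35,
    "price_rank": -0.30,
    "total_fish": 0.60,
    "pct_marine": 0.35,
}

#: Default per-column MCAR rates, emulating complete-pair counts of roughly
#: 65 (serving size), 160 (GDP) and 146 (price) out of 166 countries.
DEFAULT_MISSINGNESS: Mapping[str, float] = {
    "recommended_g_day": 101 / 166,
    "gdp_percap": 6 / 166,
    "price_rank": 20 / 166,
    "total_fish": 0.0,
    "pct_marine": 0.0,
    "lcn3_mg_day": 0.0,
}

#: Default guideline-category frequencies (none, no seafood recommendation,
#: recommendation with serving size, recommendation without serving size),
#: emulating a survey in which 92 of 166 countries recommend seafood and 65
#: state a serving size.
DEFAULT_FBDG_PROBS = (37 / 166, 37 / 166, 65 / 166, 27 / 166)

_FBDG_ORDER = (FbdgStatus.NONE, FbdgStatus.NO_RECOMMENDATION,
               FbdgStatus.REC_WITH_SERVING, FbdgStatus.REC_WITHOUT_SERVING)
# Latent-variable ordering from weakest to strongest seafood guidance; used
# to map copula quantiles to categories so the fbdg effect is directional.
_FBDG_LATENT_ORDER = (FbdgStatus.NONE, FbdgStatus.NO_RECOMMENDATION,
                      FbdgStatus.REC_WITHOUT_SERVING, FbdgStatus.REC_WITH_SERVING)


def _spearman_to_pearson(effect: float) -> float:
    """Gaussian-copula correlation whose Spearman rank correlation is `effect`."""
    return 2.0 * math.sin(math.pi * effect / 6.0)


@dataclass(frozen=True)
class CountryScenarioConfig:
    """Scenario definition for a synthetic country table.

    ``effect`` entries are target Spearman rank correlations in [-1, 1]
    between each covariate (or the latent guideline propensity for
    ``fbdg_status``) and dietary LCn-3; 0 gives the null scenario.
    ``missingness`` entries are per-column MCAR cell probabilities in [0, 1);
    a scalar applies one rate to every maskable column. ``fbdg_probs`` are
    the category frequencies (none, no_recommendation, rec_with_serving,
    rec_without_serving) and must sum to 1.
    """

    n_countries: int = 166
    seed: int = 0
    effect: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    fbdg_probs: Sequence[float] = DEFAULT_FBDG_PROBS
    missingness: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    gdp_log_mean: float = 9.0
    gdp_log_sd: float = 1.2
    lcn3_mean_mgday: float = 150.0
    lcn3_sd: float = 120.0

    def __post_init__(self):
        if self.n_countries < 8:
            raise ConfigurationError(
                f"n_countries must be at least 8, got {self.n_countries}")
        for name, value in self.effect.items():
            if name not in EFFECT_COLUMNS:
                raise ConfigurationError(f"effect: unknown column {name!r}")
            if not -1.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"effect[{name!r}] must lie in [-1, 1], got {value!r}")
        probs = tuple(self.fbdg_probs)
        if len(probs) != 4:
            raise ConfigurationError(
                f"fbdg_probs needs 4 category probabilities, got {len(probs)}")
        if any(p < 0 for p in probs):
            raise ConfigurationError("fbdg_probs entries must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"fbdg_probs must sum to 1 within 1e-9, got {sum(probs)!r}")
        for name, rate in self._missingness_map().items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(
                    f"missingness[{name!r}] must lie in [0, 1), got {rate!r}")
        if self.gdp_log_sd <= 0:
            raise ConfigurationError(f"gdp_log_sd must be > 0, got {self.gdp_log_sd!r}")
        if self.lcn3_sd <= 0:
            raise ConfigurationError(f"lcn3_sd must be > 0, got {self.lcn3_sd!r}")
        if self.lcn3_mean_mgday <= 0:
            raise ConfigurationError(
                f"lcn3_mean_mgday must be > 0, got {self.lcn3_mean_mgday!r}")

    def _missingness_map(self) -> dict[str, float]:
        if isinstance(self.missingness, Mapping):
            for name in self.missingness:
                if name not in MISSINGNESS_COLUMNS:
                    raise ConfigurationError(f"missingness: unknown column {name!r}")
            return {c: float(self.missingness.get(c, 0.0)) for c in MISSINGNESS_COLUMNS}
        rate = float(self.missingness)
        return {c: rate for c in COVARIATE_COLUMNS} | {"lcn3_mg_day": 0.0}

    def effect_for(self, column: str) -> float:
        return float(self.effect.get(column, 0.0))


def null_config(n_countries: int = 166, seed: int = 0,
                missingness: Mapping[str, float] | float = 0.0) -> CountryScenarioConfig:
    """Convenience constructor for the all-effects-zero null scenario."""
    return CountryScenarioConfig(
        n_countries=n_countries, seed=seed,
        effect={c: 0.0 for c in EFFECT_COLUMNS},
        missingness=missingness)


def generate_countries(config: CountryScenarioConfig) -> list[CountryRecord]:
    """Draw a synthetic country table under a scenario configuration.

    Deterministic under a fixed ``(config, seed)``. Each covariate's
    empirical Spearman correlation with dietary LCn-3 converges to its
    configured effect as ``n_countries`` grows. Missing values are injected
    per the MCAR rates; the country identifier is never missing.
    """
    n = config.n_countries
    rng = np.random.default_rng(config.seed)

    # Latent Gaussian copula: one LCn-3 factor, covariates conditionally
    # independent given it (correlation matrix is PSD by construction).
    z_lcn3 = rng.standard_normal(n)
    latent: dict[str, np.ndarray] = {}
    for col in EFFECT_COLUMNS:
        rho = _spearman_to_pearson(config.effect_for(col))
        latent[col] = rho * z_lcn3 + math.sqrt(max(0.0, 1.0 - rho * rho)) \
            * rng.standard_normal(n)

    lo = (0.0 - config.lcn3_mean_mgday) / config.lcn3_sd
    lcn3 = stats.truncnorm.ppf(stats.norm.cdf(z_lcn3), lo, np.inf,
                               loc=config.lcn3_mean_mgday, scale=config.lcn3_sd)
    gdp = np.exp(config.gdp_log_mean + config.gdp_log_sd * latent["gdp_percap"])
    price_rank = stats.rankdata(latent["price_rank"], method="ordinal").astype(int)
    total_fish = stats.gamma.ppf(stats.norm.cdf(latent["total_fish"]), a=2.0, scale=10.0)
    pct_marine = 100.0 * stats.beta.ppf(stats.norm.cdf(latent["pct_marine"]), a=5.0, b=2.0)
    # Serving sizes roughly log-normal around ~33 g/d with sd ~17 g/d.
    rec = np.exp(3.3703 + 0.4966 * latent["recommended_g_day"])

    # Guideline category from latent propensity quantiles, ordered weakest
    # to strongest seafood guidance.
    prob_by_status = dict(zip(_FBDG_ORDER, config.fbdg_probs))
    edges = np.cumsum([prob_by_status[s] for s in _FBDG_LATENT_ORDER])[:-1]
    thresholds = stats.norm.ppf(edges)
    cat_idx = np.searchsorted(thresholds, latent["fbdg_status"], side="right")
    fbdg = [_FBDG_LATENT_ORDER[i] for i in cat_idx]

    values = {
        "lcn3_mg_day": lcn3,
        "recommended_g_day": rec,
        "gdp_percap": gdp,
        "total_fish": total_fish,
        "pct_marine": pct_marine,
    }
    masks = {}
    for col in MISSINGNESS_COLUMNS:  # fixed order keeps the stream reproducible
        rate = config._missingness_map()[col]
        masks[col] = rng.random(n) < rate if rate > 0 else np.zeros(n, dtype=bool)

    width = max(3, len(str(n)))
    records = []
    for i in range(n):
        def cell(col, raw):
            return None if masks[col][i] else raw
        records.append(CountryRecord(
            country_id=f"C{i + 1:0{width}d}",
            lcn3_mg_day=cell("lcn3_mg_day", float(lcn3[i])),
            fbdg_status=fbdg[i],
            recommended_g_day=cell("recommended_g_day", float(values["recommended_g_day"][i])),
            gdp_percap=cell("gdp_percap", float(gdp[i])),
            price_rank=cell("price_rank", int(price_rank[i])),
            total_fish=cell("total_fish", float(total_fish[i])),
            pct_marine=cell("pct_marine", float(pct_marine[i])),
        ))
    return records


@dataclass(frozen=True)
class ConsumptionScenarioConfig:
    """Scenario definition for a synthetic species-consumption profile.

    ``top_coverage`` is the share of total national consumption the listed
    species jointly cover (0.748 by default); the remainder is the unlisted
    residual the diet model imputes. ``dominance`` > 0 skews the
    consumption-share distribution (shares fall off as rank^-dominance).
    ``total_grams_per_week`` sets the implied national per-capita total.
    """

    n_species: int = 10
    seed: int = 0
    top_coverage: float = 0.748
    dominance: float = 1.0
    density_range_mg_per_100g: tuple[float, float] = (20.0, 2000.0)
    total_grams_per_week: float = 138.9

    def __post_init__(self):
        if self.n_species < 2:
            raise ConfigurationError(
                f"n_species must be at least 2, got {self.n_species}")
        if not 0.0 < self.top_coverage <= 1.0:
            raise ConfigurationError(
                f"top_coverage must lie in (0, 1], got {self.top_coverage!r}")
        if self.dominance <= 0:
            raise ConfigurationError(
                f"dominance must be > 0, got {self.dominance!r}")
        lo, hi = self.density_range_mg_per_100g
        if not 0 < lo < hi:
            raise ConfigurationError(
                "density_range_mg_per_100g must satisfy 0 < low < high, "
                f"got {(lo, hi)!r}")
        if self.total_grams_per_week <= 0:
            raise ConfigurationError(
                f"total_grams_per_week must be > 0, got {self.total_grams_per_week!r}")


def generate_consumption(config: ConsumptionScenarioConfig) -> list[SpeciesConsumption]:
    """Draw a skewed species-consumption profile.

    The listed species' consumptions sum to ``top_coverage`` of the implied
    total. Species are emitted in descending consumption order; the dominant
    species receives an EPA+DHA density from the lower third of the density
    range and the runner-up one from the upper third, so the profile always
    exhibits the low-density-staple / high-density-minority structure.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_species
    ranks = np.arange(1, k + 1, dtype=float)
    weights = ranks ** (-config.dominance) * np.exp(0.15 * rng.standard_normal(k))
    weights = np.sort(weights)[::-1]
    shares = weights / weights.sum()
    grams = config.total_grams_per_week * config.top_coverage * shares

    lo, hi = config.density_range_mg_per_100g
    third = (hi - lo) / 3.0
    density = rng.uniform(lo, hi, size=k)
    density[0] = rng.uniform(lo, lo + third)          # low-density staple
    density[1] = rng.uniform(hi - third, hi)          # high-density minority

    width = max(2, len(str(k)))
    return [SpeciesConsumption(species=f"species_{i + 1:0{width}d}",
                               grams_per_week=float(grams[i]),
                               epa_dha_mg_per_100g=float(density[i]))
            for i in range(k)]
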