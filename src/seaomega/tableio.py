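"""CSV readers and writers for country and species tables.

Country tables carry the documented header
``country_id, lcn3_mg_day, fbdg_status, recommended_g_day, gdp_percap,
price_rank, total_fish, pct_marine``; species tables carry
``species, grams_per_week, epa_dha_mg_per_100g``. Empty cells are missing
values. All files are UTF-8, comma-separated, header row mandatory.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .records import (COUNTRY_COLUMNS, CountryRecord, FbdgStatus,
                      SpeciesConsumption, check_unique)

SPECIES_COLUMNS = ("species", "grams_per_week", "epa_dha_mg_per_100g")


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(expected)}")


def _cell(row, name, row_number, path, kind=float):
    """Parse one numeric cell; None when empty, SchemaError when malformed."""
    raw = row[name]
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or \
            (isinstance(raw, str) and raw.strip() == ""):
        return None
    try:
        return kind(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}: row {row_number}: malformed {name} value {raw!r}") from None


def read_country_table(path) -> list[CountryRecord]:
    """Read a country table CSV into typed records.

    Malformed numeric cells, invalid guideline statuses and out-of-range
    values are reported with their (1-based data) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, COUNTRY_COLUMNS, path)
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        status = row["fbdg_status"].strip()
        try:
            fbdg = FbdgStatus(status)
        except ValueError:
            raise SchemaError(
                f"{path}: row {i}: invalid fbdg_status {status!r}; expected "
                f"one of {[s.value for s in FbdgStatus]}") from None
        try:
            records.append(CountryRecord(
                country_id=row["country_id"].strip(),
                lcn3_mg_day=_cell(row, "lcn3_mg_day", i, path),
                fbdg_status=fbdg,
                recommended_g_day=_cell(row, "recommended_g_day", i, path),
                gdp_percap=_cell(row, "gdp_percap", i, path),
                price_rank=_cell(row, "price_rank", i, path,
                                 kind=lambda v: int(float(v))),
                total_fish=_cell(row, "total_fish", i, path),
                pct_marine=_cell(row, "pct_marine", i, path),
            ))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    check_unique([r.country_id for r in records], "country_id")
    return records


def write_country_table(records: Sequence[CountryRecord], path) -> None:
    """Write country records as CSV with the documented header."""
    rows = []
    for r in records:
        row = {c: r.get(c) for c in COUNTRY_COLUMNS}
        row["country_id"] = r.country_id
        row["fbdg_status"] = r.fbdg_status.value
        rows.append(row)
    pd.DataFrame(rows, columns=list(COUNTRY_COLUMNS)).to_csv(path, index=False)


def read_species_table(path) -> list[SpeciesConsumption]:
    """Read a species-consumption table CSV into typed records."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SPECIES_COLUMNS, path)
    items = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        grams = _cell(row, "grams_per_week", i, path)
        density = _cell(row, "epa_dha_mg_per_100g", i, path)
        if grams is None or density is None:
            raise SchemaError(f"{path}: row {i}: species rows cannot have "
                              "empty numeric cells")
        try:
            items.append(SpeciesConsumption(species=row["species"].strip(),
                                            grams_per_week=grams,
                                            epa_dha_mg_per_100g=density))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    check_unique([it.species for it in items], "species")
    return items


def write_species_table(items: Sequence[SpeciesConsumption], path) -> None:
    pd.DataFrame(
        [{"species": it.species, "grams_per_week": it.grams_per_week,
          "epa_dha_mg_per_100g": it.epa_dha_mg_per_100g} for it in items],
        columns=list(SPECIES_COLUMNS)).to_csv(path, index=False)
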