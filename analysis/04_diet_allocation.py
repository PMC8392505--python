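#!/usr/bin/env python
"""Dietary LCn-3 allocation for the synthetic consumption profile.

Allocates daily EPA+DHA across the listed species plus the imputed
unlisted residual (weighted-mean density), then extends the whole profile
proportionally to the 8 oz/week (226.7 g) recommendation. Prints both
scenarios and highlights the low-density-staple effect: the share of
dietary LCn-3 the most-consumed species supplies versus its share of the
plate.
"""

from pathlib import Path

from seaomega import convert_units, diet_report
from seaomega.report import diet_to_dict, render_report, to_json
from seaomega.tableio import read_species_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
COVERAGE = 0.748


def main() -> None:
    species_path = RESULTS / "synthetic_species.csv"
    if not species_path.exists():
        raise SystemExit("run analysis/01_simulate_tables.py first")
    items = read_species_table(species_path)
    target = convert_units(8, "oz/week", "g/week", guideline_constants=True)
    summary = diet_report(items, coverage=COVERAGE, target_grams_per_week=target)
    text, _ = render_report(diet=summary)
    print(text)
    (RESULTS / "diet_summary.json").write_text(
        to_json({"diet": diet_to_dict(summary)}) + "\n")

    staple = summary.per_species[items[0].species]
    print(f"staple species: {100 * staple.share_of_consumption:.1f}% of "
          f"consumption but only {100 * staple.share_of_lcn3:.1f}% of dietary "
          f"LCn-3")
    k = summary.scaled.total_grams_per_week / summary.total_grams_per_week
    print(f"meeting the {target:.1f} g/week recommendation scales every "
          f"contribution by {k:.3f}: "
          f"{summary.total_lcn3_mg_per_day:.1f} -> "
          f"{summary.scaled.total_lcn3_mg_per_day:.1f} mg EPA+DHA/day")


if __name__ == "__main__":
    main()
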