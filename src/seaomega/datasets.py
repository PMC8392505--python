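"""Published reference quadrant counts for the six-comparison family.

These are the country counts from a published global survey of national
food-based dietary guidelines and dietary EPA+DHA: for each comparison,
countries were classified below/above the median of the covariate (for the
FBDG row, by presence/absence of a seafood recommendation) and below/above
the median dietary LCn-3. They serve as fixed inputs for reproducing the
survey's headline chi-square statistics; the package's synthetic generator,
not this table, supplies data for calibration studies.

Cell convention matches :class:`~seaomega.quadrant.QuadrantTable`:
first letter = covariate below/above, second = dietary LCn-3 below/above.
"""

from .quadrant import QuadrantTable

#: Quadrant counts per comparison, keyed by covariate column name.
#: Ns differ across rows because not every covariate is observed for
#: every country (65, 166, 160, 146, 166, 166 complete pairs).
REFERENCE_QUADRANT_COUNTS: dict[str, QuadrantTable] = {
    "recommended_g_day": QuadrantTable(bb=19, ba=15, ab=5, aa=26,
                                       x_name="recommended_g_day", y_name="lcn3_mg_day"),
    "fbdg_status": QuadrantTable(bb=47, ba=27, ab=36, aa=56,
                                 x_name="fbdg_status", y_name="lcn3_mg_day"),
    "gdp_percap": QuadrantTable(bb=49, ba=31, ab=29, aa=51,
                                x_name="gdp_percap", y_name="lcn3_mg_day"),
    "price_rank": QuadrantTable(bb=28, ba=45, ab=44, aa=29,
                                x_name="price_rank", y_name="lcn3_mg_day"),
    "total_fish": QuadrantTable(bb=67, ba=16, ab=16, aa=67,
                                x_name="total_fish", y_name="lcn3_mg_day"),
    "pct_marine": QuadrantTable(bb=52, ba=31, ab=31, aa=52,
                                x_name="pct_marine", y_name="lcn3_mg_day"),
}

#: Number of comparisons in the protected family.
FAMILY_SIZE = len(REFERENCE_QUADRANT_COUNTS)
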