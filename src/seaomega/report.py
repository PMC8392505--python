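"""Deterministic JSON and plain-text rendering of analysis results.

The text report mirrors the field's usual presentation: one quadrant count
matrix per comparison with chi-square, p, direction and the protected
threshold; a score histogram per guideline group with the ANOVA line; and
observed plus scaled-to-recommendation diet tables.
"""

from __future__ import annotations

import json
from typing import Sequence

from .attribute_index import AnovaResult, IndexScore
from .diet import RESIDUAL_LABEL, DietSummary
from .quadrant import AssociationResult


def association_to_dict(res: AssociationResult) -> dict:
    t = res.table
    return {
        "x": t.x_name, "y": t.y_name, "n": t.n,
        "counts": {"bb": t.bb, "ba": t.ba, "ab": t.ab, "aa": t.aa},
        "chi2": res.chi2, "p_value": res.p_value,
        "direction": res.direction,
        "alpha_protected": res.alpha_protected,
        "significant": res.significant,
    }


def anova_to_dict(res: AnovaResult) -> dict:
    return {
        "f_stat": res.f_stat, "df_between": res.df_between,
        "df_within": res.df_within, "p_value": res.p_value,
        "group_means": dict(res.group_means), "group_ns": dict(res.group_ns),
    }


def diet_to_dict(summary: DietSummary) -> dict:
    def entry(c):
        return {"grams_per_week": c.grams_per_week,
                "lcn3_mg_per_day": c.lcn3_mg_per_day,
                "share_of_consumption": c.share_of_consumption,
                "share_of_lcn3": c.share_of_lcn3}
    out = {
        "per_species": {name: entry(c) for name, c in summary.per_species.items()},
        "residual": entry(summary.residual),
        "total_grams_per_week": summary.total_grams_per_week,
        "total_lcn3_mg_per_day": summary.total_lcn3_mg_per_day,
    }
    if summary.scaled is not None:
        out["scaled"] = diet_to_dict(summary.scaled)
    return out


def render_report(associations: Sequence[AssociationResult] | None = None,
                  scores: Sequence[IndexScore] | None = None,
                  anova: AnovaResult | None = None,
                  diet: DietSummary | None = None) -> tuple[str, dict]:
    """Render results into (text, json-dict). Sections absent from the
    input are omitted; identical inputs give byte-identical output."""
    if associations is None and anova is None and diet is None and scores is None:
        raise ValueError("render_report needs at least one result section")
    doc: dict = {}
    lines: list[str] = []

    if associations:
        doc["associations"] = [association_to_dict(r) for r in associations]
        alpha = associations[0].alpha_protected
        lines.append(f"Median-quadrant associations "
                     f"(protected alpha = {alpha:.6g}, {len(associations)} comparisons)")
        lines.append("=" * 72)
        for r in associations:
            t = r.table
            lines.append(f"{t.x_name} vs {t.y_name}  (n = {t.n})")
            lines.append(f"                 {t.y_name}: below  above")
            lines.append(f"  {t.x_name} above   {t.ab:5d}  {t.aa:5d}")
            lines.append(f"  {t.x_name} below   {t.bb:5d}  {t.ba:5d}")
            verdict = "significant" if r.significant else "not significant"
            lines.append(f"  chi2 = {r.chi2:.4f}, p = {r.p_value:.4g}, "
                         f"direction = {r.direction}, {verdict}")
            lines.append("")

    if scores is not None:
        doc["index_scores"] = [
            {"country_id": s.country_id, "score": s.score,
             "fbdg_group": s.fbdg_group} for s in scores]
        lines.append("Four-attribute index score counts by guideline group")
        lines.append("=" * 72)
        groups = sorted({s.fbdg_group for s in scores})
        for g in groups:
            hist = [0] * 5
            for s in scores:
                if s.fbdg_group == g:
                    hist[s.score] += 1
            lines.append(f"  {g:>8}: " + "  ".join(
                f"{k}:{hist[k]}" for k in range(5)))
        lines.append("")

    if anova is not None:
        doc["anova"] = anova_to_dict(anova)
        lines.append(f"One-way ANOVA: F({anova.df_between}, {anova.df_within}) "
                     f"= {anova.f_stat:.3f}, p = {anova.p_value:.4g}")
        for g in sorted(anova.group_means):
            lines.append(f"  {g:>8}: mean score {anova.group_means[g]:.3f} "
                         f"(n = {anova.group_ns[g]})")
        lines.append("")

    if diet is not None:
        doc["diet"] = diet_to_dict(diet)
        scenarios = [("observed consumption", diet)]
        if diet.scaled is not None:
            scenarios.append(("scaled to recommendation", diet.scaled))
        for title, s in scenarios:
            lines.append(f"Dietary LCn-3 allocation ({title}): "
                         f"total {s.total_grams_per_week:.1f} g/week, "
                         f"{s.total_lcn3_mg_per_day:.1f} mg EPA+DHA/day")
            lines.append("=" * 72)
            lines.append(f"  {'item':>16}  {'g/week':>8}  {'mg/day':>8}  "
                         f"{'% intake':>8}  {'% LCn-3':>8}")
            entries = list(s.per_species.items()) + [(RESIDUAL_LABEL, s.residual)]
            for name, c in entries:
                lines.append(f"  {name:>16}  {c.grams_per_week:8.1f}  "
                             f"{c.lcn3_mg_per_day:8.1f}  "
                             f"{100 * c.share_of_consumption:8.1f}  "
                             f"{100 * c.share_of_lcn3:8.1f}")
            lines.append("")

    return "\n".join(lines), doc


def to_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=False)
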