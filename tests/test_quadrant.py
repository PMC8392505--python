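"""Median-quadrant association machinery: dichotomization, tabulation,
chi-square, direction, and the protected comparison family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seaomega import (QuadrantTable, association_direction,
                      build_quadrant_table, dichotomize, pearson_chi2,
                      run_family)
from seaomega.errors import (ConfigurationError, DegenerateTableWarning,
                             InsufficientDataError)
from seaomega.quadrant import ABOVE, BELOW


def chi2_expected_counts_oracle(table):
    """Independent brute-force Pearson statistic: sum (O-E)^2 / E."""
    obs = table.as_array()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


class TestDichotomize:
    @pytest.mark.parametrize("values, expected", [
        ([1, 2, 3, 4, 5], [BELOW, BELOW, BELOW, ABOVE, ABOVE]),   # median 3
        ([1, 1, 1, 1], [BELOW] * 4),                              # all at median
        ([2, 4, 6, 8], [BELOW, BELOW, ABOVE, ABOVE]),             # median 5
    ])
    def test_strict_above_labels(self, values, expected):
        assert dichotomize(values).labels == expected

    def test_exclude_ties_drops_and_reports_median_values(self):
        out = dichotomize([1, 2, 2, 3], policy="exclude_ties")
        assert out.ties_dropped == [1, 2]
        assert out.labels == [BELOW, None, None, ABOVE]

    def test_missing_values_are_never_labelled(self):
        out = dichotomize([1.0, None, 3.0, float("nan"), 5.0])
        assert out.labels == [BELOW, None, BELOW, None, ABOVE]
        assert out.median == 3.0  # median over non-missing values only

    def test_too_few_values_raises(self):
        with pytest.raises(InsufficientDataError):
            dichotomize([1.0, None])

    def test_unknown_policy_raises(self):
        with pytest.raises(ConfigurationError):
            dichotomize([1, 2, 3], policy="midpoint")


class TestQuadrantTable:
    def test_reconstructs_reference_serving_size_counts(self, reference_tables):
        ref = reference_tables["recommended_g_day"]
        x = [BELOW] * (ref.bb + ref.ba) + [ABOVE] * (ref.ab + ref.aa)
        y = [BELOW] * ref.bb + [ABOVE] * ref.ba + [BELOW] * ref.ab + [ABOVE] * ref.aa
        t = build_quadrant_table(x, y, "recommended_g_day", "lcn3_mg_day")
        assert (t.bb, t.ba, t.ab, t.aa) == (19, 15, 5, 26)
        assert t.n == 65

    def test_all_pairs_in_one_quadrant(self):
        t = build_quadrant_table([BELOW] * 6, [BELOW] * 6)
        assert (t.bb, t.ba, t.ab, t.aa) == (6, 0, 0, 0)

    def test_one_pair_per_quadrant(self):
        t = build_quadrant_table([BELOW, BELOW, ABOVE, ABOVE],
                                 [BELOW, ABOVE, BELOW, ABOVE])
        assert (t.bb, t.ba, t.ab, t.aa) == (1, 1, 1, 1)

    def test_incomplete_pairs_are_dropped(self):
        t = build_quadrant_table([BELOW, None, ABOVE], [BELOW, BELOW, None])
        assert t.n == 1

    def test_no_complete_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            build_quadrant_table([None, BELOW], [ABOVE, None])


class TestPearsonChi2:
    # Frozen values recomputed by hand from the closed form
    # n*(bb*aa - ba*ab)^2 / [(bb+ba)(ab+aa)(bb+ab)(ba+aa)].
    @pytest.mark.parametrize("name, expected", [
        ("recommended_g_day", 11.0029),
        ("fbdg_status", 9.7532),
        ("gdp_percap", 10.0063),
        ("price_rank", 7.0150),
        ("total_fish", 62.6747),
        ("pct_marine", 10.6265),
    ])
    def test_reference_counts_reproduce_published_statistics(
            self, reference_tables, name, expected):
        chi2, p = pearson_chi2(reference_tables[name])
        assert chi2 == pytest.approx(expected, abs=5e-4)
        assert 0 < p < 0.01

    def test_perfect_independence_is_zero(self):
        chi2, p = pearson_chi2(QuadrantTable(10, 10, 10, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_defines_zero_with_warning(self):
        with pytest.warns(DegenerateTableWarning):
            chi2, p = pearson_chi2(QuadrantTable(5, 7, 0, 0))
        assert (chi2, p) == (0.0, 1.0)

    def test_agrees_with_expected_count_oracle_and_scipy(self, rng):
        """Closed form == brute-force sum (O-E)^2/E == scipy, 1000 tables."""
        for _ in range(1000):
            cells = rng.integers(1, 80, size=4)
            t = QuadrantTable(*map(int, cells))
            chi2, p = pearson_chi2(t)
            assert chi2 == pytest.approx(chi2_expected_counts_oracle(t), abs=1e-9)
            s_chi2, s_p, dof, _ = stats.chi2_contingency(t.as_array(),
                                                         correction=False)
            assert dof == 1
            assert chi2 == pytest.approx(s_chi2, abs=1e-9)
            assert p == pytest.approx(s_p, abs=1e-12)


class TestDirection:
    @pytest.mark.parametrize("cells, expected", [
        ((19, 15, 5, 26), "positive"),   # concordant majority 45 > 20
        ((28, 45, 44, 29), "negative"),  # discordant majority 57 < 89
        ((1, 1, 1, 1), "none"),
    ])
    def test_quadrant_concordance_rule(self, cells, expected):
        assert association_direction(QuadrantTable(*cells)) == expected


class TestRunFamily:
    def test_six_comparison_family_protects_at_one_sixth(self, default_records):
        results = run_family(default_records)
        assert len(results) == 6
        for r in results:
            assert r.alpha_protected == pytest.approx(0.05 / 6)
            assert round(r.alpha_protected, 3) == 0.008
            assert r.significant == (r.p_value < r.alpha_protected and r.chi2 > 0)

    def test_single_pair_uses_family_alpha_directly(self, default_records):
        (r,) = run_family(default_records, [("gdp_percap", "lcn3_mg_day")])
        assert r.alpha_protected == 0.05

    def test_fbdg_split_is_presence_absence(self, default_records):
        (r,) = run_family(default_records, [("fbdg_status", "lcn3_mg_day")])
        n_with_rec = sum(rec.fbdg_status.has_seafood_recommendation
                         for rec in default_records)
        assert r.table.ab + r.table.aa == n_with_rec
        assert r.table.n == len(default_records)  # fbdg_status never missing

    def test_medians_are_pairwise_complete_so_ns_differ(self, default_records):
        results = {r.table.x_name: r for r in run_family(default_records)}
        # serving size is sparsely observed; fully observed columns keep n=166
        assert results["recommended_g_day"].n < results["total_fish"].n == 166

    def test_unknown_variable_raises(self, default_records):
        with pytest.raises(ConfigurationError):
            run_family(default_records, [("selenium", "lcn3_mg_day")])

    def test_empty_family_raises(self, default_records):
        with pytest.raises(ConfigurationError):
            run_family(default_records, [])


def analyze_xy(xs, ys):
    """Run the full chain on raw paired values: dichotomize both, tabulate,
    test, read the direction. Unlike country records, raw values may be
    negative, which the antisymmetry property needs."""
    table = build_quadrant_table(dichotomize(xs).labels, dichotomize(ys).labels)
    chi2, p = pearson_chi2(table)
    return table, chi2, p, association_direction(table)


@settings(deadline=None, max_examples=60)
@given(st.integers(0, 2**31 - 1), st.sampled_from(["cube", "exp", "affine"]))
def test_monotone_invariance(seed, transform):
    """Strictly increasing transforms of either variable change nothing:
    the method depends only on ranks."""
    r = np.random.default_rng(seed)
    n = int(r.integers(8, 60))
    xs, ys = r.normal(size=n), r.normal(size=n)
    f = {"cube": lambda v: v**3, "exp": np.exp,
         "affine": lambda v: 2.5 * v + 7}[transform]
    t0, chi0, _, dir0 = analyze_xy(xs, ys)
    t1, chi1, _, dir1 = analyze_xy(f(xs), ys)
    assert (t0.bb, t0.ba, t0.ab, t0.aa) == (t1.bb, t1.ba, t1.ab, t1.aa)
    assert chi0 == pytest.approx(chi1, abs=1e-12)
    assert dir0 == dir1


@settings(deadline=None, max_examples=60)
@given(st.integers(0, 2**31 - 1))
def test_negation_antisymmetry(seed):
    """Negating one variable swaps its labels, keeps chi2, flips direction.

    Even n with continuous values: under strict_above with odd n the data
    point sitting exactly at the median is labelled below on both signs, so
    the exact swap holds only when no value equals its median."""
    r = np.random.default_rng(seed)
    n = 2 * int(r.integers(4, 30))
    xs, ys = r.normal(size=n), r.normal(size=n)
    t0, chi0, _, dir0 = analyze_xy(xs, ys)
    t1, chi1, _, dir1 = analyze_xy(-xs, ys)
    assert (t1.bb, t1.ba) == (t0.ab, t0.aa)
    assert (t1.ab, t1.aa) == (t0.bb, t0.ba)
    assert chi1 == pytest.approx(chi0, abs=1e-12)
    flip = {"positive": "negative", "negative": "positive", "none": "none"}
    assert dir1 == flip[dir0]
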