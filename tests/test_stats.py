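"""Fisher's exact test, Wilcoxon rank-sum, and percentage reporting."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st_h

from exrte.stats import (
    enrichment_report,
    fisher_exact_two_sided,
    percent,
    wilcoxon_rank_sum,
)


def brute_force_fisher(table):
    """Exact-rational oracle: enumerate all tables with the observed margins
    and sum the probabilities no larger than the observed table's."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    kept = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(kept, total)


@pytest.mark.parametrize(
    "table, expected",
    [
        (((1, 1), (1, 1)), 1.0),
        (((3, 0), (0, 3)), 0.1),  # 2 of the 20 equally-margined assignments
    ],
)
def test_fisher_small_examples(table, expected):
    assert fisher_exact_two_sided(table).p_two_sided == pytest.approx(expected)


def test_fisher_matches_r_convention_on_large_survey_tables():
    """On recency-style tables with N ~ 35,000 the log-factorial
    implementation agrees with R's fisher.test / scipy to full precision."""
    for table, expected in [
        (((21, 23), (5932, 29037)), 2.384238198849077e-06),
        (((21, 23), (5932, 34969)), 1.668685807234047e-07),
    ]:
        res = fisher_exact_two_sided(table)
        assert res.p_two_sided == pytest.approx(expected, rel=1e-9)
        assert res.p_two_sided == pytest.approx(
            scipy.stats.fisher_exact(table).pvalue, rel=1e-9
        )


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(((1, -1), (0, 2)))


def test_fisher_p_is_one_when_margins_force_the_table():
    assert fisher_exact_two_sided(((3, 0), (2, 0))).p_two_sided == 1.0


def test_fisher_odds_ratio():
    assert fisher_exact_two_sided(((2, 1), (1, 2))).odds_ratio == pytest.approx(4.0)
    assert math.isinf(fisher_exact_two_sided(((2, 0), (1, 2))).odds_ratio)


@settings(deadline=None, max_examples=150)
@given(st_h.tuples(*[st_h.integers(min_value=0, max_value=12)] * 4))
def test_fisher_equals_exact_enumeration(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    p = fisher_exact_two_sided(((a, b), (c, d))).p_two_sided
    assert p == pytest.approx(float(brute_force_fisher(((a, b), (c, d)))), rel=1e-9)


@settings(deadline=None, max_examples=80)
@given(st_h.tuples(*[st_h.integers(min_value=0, max_value=30)] * 4))
def test_fisher_invariant_under_transpose_and_double_swap(cells):
    a, b, c, d = cells
    if a + b + c + d == 0:
        return
    p = fisher_exact_two_sided(((a, b), (c, d))).p_two_sided
    assert fisher_exact_two_sided(((a, c), (b, d))).p_two_sided == pytest.approx(p)
    assert fisher_exact_two_sided(((d, c), (b, a))).p_two_sided == pytest.approx(p)


def test_wilcoxon_exact_extreme_assignment():
    p, mode = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert mode == "exact"
    assert p == pytest.approx(0.1)  # 2 of C(6,3) = 20 assignments as extreme


def test_wilcoxon_identical_multisets():
    p, _ = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)


def test_wilcoxon_degenerate_input_warns_and_returns_one():
    p, mode = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0 and mode == "degenerate"


def test_wilcoxon_switches_to_asymptotic_for_large_or_tied_samples():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    _, mode = wilcoxon_rank_sum(x, y)
    assert mode == "asymptotic"
    _, mode = wilcoxon_rank_sum([1, 1, 2], [3, 4, 5])  # tie in x
    assert mode == "asymptotic"


@pytest.mark.parametrize(
    "num, den, text",
    [(2670, 45393, "6%"), (1359, 3915, "35%"), (25, 44, "57%"), (1, 200, "1%")],
)
def test_percent_rounding(num, den, text):
    formatted, raw = percent(num, den)
    assert formatted == text
    assert raw == pytest.approx(100 * num / den)


def test_percent_rejects_zero_denominator():
    with pytest.raises(ValueError):
        percent(1, 0)


@settings(deadline=None, max_examples=100)
@given(st_h.integers(min_value=0, max_value=10**5), st_h.integers(min_value=1, max_value=10**5))
def test_percent_roundtrip_within_half_step(a, b):
    formatted, _ = percent(a, b)
    back = int(formatted.rstrip("%")) * b / 100
    assert abs(back - a) <= b / 200 + 1e-9


def test_enrichment_report_delegates_to_fisher_and_handles_zero_cells():
    features = pd.DataFrame(
        {
            "set": ["exRTE"] * 4 + ["n-exRTE"] * 6,
            "clade": ["Ale", "Ale", "Reina", "Reina", "Tekay", "Tekay", "Tekay", "Ale", "Reina", "Tekay"],
            "max_orf_nt": [900, 1200, 800, 1000, 300, 350, 310, 400, 320, 330],
        }
    )
    report = enrichment_report(
        features, categorical={"clade": "Tekay"}, continuous=["max_orf_nt"]
    )
    row = report[report.attribute == "clade=Tekay"].iloc[0]
    # the expressed side has a zero cell; p must still be defined
    assert row.ex_with == 0
    expected = fisher_exact_two_sided(((0, 4), (4, 2))).p_two_sided
    assert row.p_value == pytest.approx(expected)
    assert (report[report.attribute == "max_orf_nt"].iloc[0].p_value) < 0.2


def test_enrichment_report_skips_missing_attributes(caplog):
    features = pd.DataFrame({"set": ["exRTE", "n-exRTE"]})
    report = enrichment_report(features, categorical={"ghost": "x"}, continuous=["gone"])
    assert report.empty
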