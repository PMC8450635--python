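from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st
from scipy import stats

from paleoprev import (
    bootstrap_median_ci,
    era_summary_table,
    mann_whitney_u,
    occurrence_prevalence,
    per_myr_rate,
)
from paleoprev.prevalence import PrevalenceValue
from tests.test_io import _rec


@pytest.mark.parametrize(
    "k, n, expected",
    [(5, 50, Fraction(1, 10)), (0, 10, Fraction(0)), (10, 10, Fraction(1))],
)
def test_occurrence_prevalence_exact(k, n, expected):
    value = occurrence_prevalence(_rec(1, n, k))
    assert value.p == expected and value.n == n


def test_occurrence_prevalence_rejects_ineligible():
    with pytest.raises(ValueError, match="missing"):
        occurrence_prevalence(_rec(1, None, None))
    with pytest.raises(ValueError, match="below min_n"):
        occurrence_prevalence(_rec(1, 5, 1))


@pytest.mark.parametrize(
    "count, duration, expected",
    [(481, 289, 1.66), (492, 185, 2.66), (451, 66, 6.83), (117, 66, 1.77), (0, 66, 0.0)],
)
def test_per_myr_rate_matches_printed_values(count, duration, expected):
    assert round(per_myr_rate(count, duration), 2) == expected


def test_per_myr_rate_requires_positive_duration():
    with pytest.raises(ValueError):
        per_myr_rate(10, 0)


def test_bootstrap_degenerate_and_deterministic():
    values = [0.1] * 20
    assert bootstrap_median_ci(values, B=500, seed=1) == (0.1, 0.1)
    rng_values = np.random.default_rng(0).beta(2, 20, size=40)
    a = bootstrap_median_ci(rng_values, B=2000, seed=7)
    b = bootstrap_median_ci(rng_values, B=2000, seed=7)
    assert a == b
    with pytest.raises(ValueError):
        bootstrap_median_ci([], B=100)
    with pytest.raises(ValueError):
        bootstrap_median_ci([0.1], B=0)


def test_mann_whitney_exact_small_sample():
    _, p = mann_whitney_u([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)


@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12),
    st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12),
)
def test_mann_whitney_complementarity_and_symmetry(x, y):
    assume(len(set(x) | set(y)) > 1)  # a zero-variance pooled sample has no test
    ux, px = mann_whitney_u(x, y)
    uy, py = mann_whitney_u(y, x)
    assert ux + uy == pytest.approx(len(x) * len(y))
    assert px == pytest.approx(py)


def test_exact_and_normal_branches_agree_without_ties():
    rng = np.random.default_rng(3)
    for n1, n2 in [(9, 9), (10, 12), (12, 11), (9, 12)]:
        x, y = rng.normal(size=n1), rng.normal(0.3, 1, size=n2)
        # implementation takes the tie-corrected normal branch here
        _, p_impl = mann_whitney_u(x, y)
        p_exact = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact"
        ).pvalue
        assert abs(p_impl - p_exact) < 0.02


def _value(p, n, era, age, rid="V1"):
    return PrevalenceValue(
        record_id=rid, p=Fraction(p).limit_denominator(1000), n=n, era=era,
        period="", best_age_ma=age,
    )


def test_era_summary_medians_and_rates(ts):
    values = [
        _value(0.02, 50, "Paleozoic", 400, "a"),
        _value(0.05, 50, "Paleozoic", 390, "b"),
        _value(0.08, 50, "Paleozoic", 380, "c"),
        _value(0.04, 30, "Mesozoic", 150, "d"),
        _value(0.06, 30, "Mesozoic", 140, "e"),
    ]
    res = era_summary_table(values, ts, B=500, seed=0)
    row = res.summary.set_index("era").loc["Paleozoic"]
    assert row["median_p"] == pytest.approx(0.05, abs=1e-3)
    assert row["n_values"] == 3
    assert row["occurrences_per_myr"] == pytest.approx(3 / 289)
    assert row["ci_low"] <= row["median_p"] <= row["ci_high"]
    # empty Cenozoic subset is flagged, not dropped
    cen = res.summary.set_index("era").loc["Cenozoic"]
    assert cen["flags"] == "no_values" and np.isnan(cen["median_p"])
    # per-era counts reconcile with the input total
    assert res.summary["n_values"].sum() == len(values)
    # pairwise tests cover every era pair
    assert len(res.pairwise) == 3


def test_median_is_permutation_invariant(ts):
    rng = np.random.default_rng(1)
    ps = rng.beta(2, 20, size=21)
    values = [_value(float(p), 30, "Mesozoic", 150, str(i)) for i, p in enumerate(ps)]
    shuffled = [values[i] for i in rng.permutation(len(values))]
    m1 = era_summary_table(values, ts, B=10, seed=0).summary
    m2 = era_summary_table(shuffled, ts, B=10, seed=0).summary
    a = m1.set_index("era").loc["Mesozoic", "median_p"]
    b = m2.set_index("era").loc["Mesozoic", "median_p"]
    assert a == pytest.approx(b)
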