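import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paleoprev import (
    BinOccurrenceSet,
    GenusOccurrence,
    SQSConfig,
    diversity_table,
    goods_u,
    sqs_richness,
    three_timer_counts,
    turnover_rates,
)
from paleoprev.sqs import CoverageShortfallError, expected_richness_exact


def _bin(ts, counts, period="Devonian"):
    return BinOccurrenceSet(
        period=ts.period(period), counts=pd.Series(counts).sort_index()
    )


@pytest.mark.parametrize(
    "counts, expected",
    [({"A": 5, "B": 3, "C": 2}, 1.0), ({"A": 1, "B": 1}, 0.0), ({"A": 3, "B": 1}, 0.75)],
)
def test_goods_u(counts, expected):
    assert goods_u(list(counts.values())) == expected


def test_goods_u_empty_bin():
    with pytest.raises(ValueError):
        goods_u([])


def test_full_quorum_requires_every_genus(ts):
    b = _bin(ts, {"A": 5, "B": 3, "C": 2})
    mean, trials = sqs_richness(b, SQSConfig(quorum=1.0, trials=20, seed=0))
    assert mean == 3.0 and (trials == 3).all()


def test_quorum_above_coverage_is_flagged(ts):
    b = _bin(ts, {"A": 3, "B": 1})  # u = 0.75
    with pytest.raises(CoverageShortfallError):
        sqs_richness(b, SQSConfig(quorum=0.8, trials=10, seed=0))


def test_exact_expectation_hand_value():
    # counts 5/3/2, u=1, q=0.5: richness is 1 iff the first occurrence
    # drawn belongs to the dominant genus (P = 1/2), else 2
    assert expected_richness_exact([5, 3, 2], 0.5) == pytest.approx(1.5)


def test_subsampler_matches_exhaustive_expectation(ts):
    b = _bin(ts, {"A": 5, "B": 3, "C": 2})
    config = SQSConfig(quorum=0.5, trials=10_000, seed=11)
    mean, trials = sqs_richness(b, config)
    se = trials.std(ddof=1) / math.sqrt(config.trials)
    assert abs(mean - 1.5) < 2 * se + 1e-9


def test_low_quorum_limit_is_one_genus(ts):
    b = _bin(ts, {"A": 4, "B": 3, "C": 3})
    mean, trials = sqs_richness(b, SQSConfig(quorum=1e-9, trials=50, seed=0))
    assert mean == 1.0
    assert (trials <= b.n_genera).all()


def test_mean_richness_nondecreasing_in_quorum(ts):
    b = _bin(ts, {chr(65 + i): c for i, c in enumerate([8, 6, 5, 4, 3, 2, 2])})
    means = [
        sqs_richness(b, SQSConfig(quorum=q, trials=2000, seed=3))[0]
        for q in (0.3, 0.6, 0.9)
    ]
    assert means[0] <= means[1] + 0.05 <= means[2] + 0.1


def test_doubling_counts_leaves_richness_unchanged(ts):
    # no singletons, so coverage u = 1 for both and frequencies are equal
    counts = {"A": 6, "B": 4, "C": 3, "D": 2}
    doubled = {g: 2 * c for g, c in counts.items()}
    m1, t1 = sqs_richness(_bin(ts, counts), SQSConfig(0.6, 4000, seed=5))
    m2, t2 = sqs_richness(_bin(ts, doubled), SQSConfig(0.6, 4000, seed=6))
    se = math.hypot(t1.std(ddof=1), t2.std(ddof=1)) / math.sqrt(4000)
    assert abs(m1 - m2) < 3 * se + 1e-9


def _incidence(spec: dict[str, list[int]], n_bins: int) -> pd.DataFrame:
    inc = pd.DataFrame(False, index=sorted(spec), columns=range(n_bins))
    for genus, bins in spec.items():
        inc.loc[genus, bins] = True
    return inc


def test_three_timer_hand_count():
    inc = _incidence({"A": [0, 1, 2], "B": [0, 2], "C": [1]}, 3)
    tc = three_timer_counts(inc, 1)
    assert (tc.t3, tc.pt, tc.t2_bottom, tc.t2_top) == (1, 1, 1, 1)
    assert tc.P_s == 0.5


def test_three_timer_complete_incidence():
    inc = _incidence({g: [0, 1, 2, 3] for g in "ABCD"}, 4)
    tc = three_timer_counts(inc, 1)
    assert tc.pt == 0 and tc.P_s == 1.0
    lam, mu = turnover_rates(inc, 1)
    assert mu == 0.0  # ln(4/4) + ln(1)
    lam2, mu2 = turnover_rates(inc, 2)
    assert lam2 == 0.0 and math.isnan(mu2)  # youngest interior bin: no P_s above


def test_three_timer_empty_middle_bin():
    inc = _incidence({"A": [0, 2], "B": [0, 2]}, 3)
    tc = three_timer_counts(inc, 1)
    assert tc.t3 == 0 and math.isnan(turnover_rates(inc, 1)[1])


def test_three_timer_edge_bin_raises():
    inc = _incidence({"A": [0, 1]}, 2)
    with pytest.raises(ValueError):
        three_timer_counts(inc, 0)


def test_extinction_rate_direct_substitution():
    # bins 0..3: A-D are two-timers across (0,1); A,B survive into bin 2;
    # everything present in bins 1..3 is a three-timer at bin 2, so
    # P_s(2) = 1 and mu(1) = ln(2t_bottom/3t) = ln 2
    inc = _incidence(
        {"A": [0, 1, 2, 3], "B": [0, 1, 2, 3], "C": [0, 1], "D": [0, 1]}, 4
    )
    lam, mu = turnover_rates(inc, 1)
    assert mu == pytest.approx(math.log(2))
    assert math.isnan(lam)  # bin 0 has no older neighbour for P_s


@given(
    st.integers(min_value=0, max_value=2**15 - 1),
)
def test_three_timer_invariants_on_random_incidence(bits):
    rng = np.random.default_rng(bits)
    inc = pd.DataFrame(rng.random((6, 5)) < 0.5, index=list("ABCDEF"))
    for i in range(1, 4):
        tc = three_timer_counts(inc, i)
        assert tc.t3 <= tc.t2_bottom
        assert tc.t3 <= tc.t2_top
        assert 0 <= tc.pt
        if tc.t3 + tc.pt:
            assert 0.0 <= tc.P_s <= 1.0


def _occ(genus, age, host_class="Bivalvia"):
    p, _ = __import__("paleoprev").assign_interval(age)
    return GenusOccurrence(
        genus=genus, host_class=host_class, collection_id="1", max_ma=age,
        min_ma=age, reference_id="1", period=p.name, age_ambiguous=False,
    )


def test_single_period_dataset_has_richness_but_no_rates(ts):
    occurrences = [
        _occ(g, 380.0 + i * 0.01) for i, g in enumerate("AABBBCCDDE")
    ]
    table = diversity_table(occurrences, SQSConfig(quorum=0.5, trials=20, seed=0), ts)
    dev = table.frame.set_index("period").loc["Devonian"]
    assert not math.isnan(dev["S_mean"])
    assert table.frame["lambda_3t"].isna().all()
    assert table.frame["mu_3t"].isna().all()


def test_low_coverage_bin_is_flagged(ts):
    # all singletons in the Devonian: u = 0 < quorum
    occurrences = [_occ(g, 380.0 + i) for i, g in enumerate("ABCDEFGHIJ")]
    table = diversity_table(occurrences, SQSConfig(quorum=0.6, trials=10, seed=0), ts)
    assert table.dropped.get("Devonian") == "insufficient_coverage"
    assert math.isnan(table.frame.set_index("period").loc["Devonian", "S_mean"])


def test_trial_richness_never_exceeds_raw_richness(ts, paper_amp_bundle):
    from paleoprev.sqs import bin_occurrences

    bins = bin_occurrences(paper_amp_bundle.occurrences, ts)
    for b in list(bins.values())[:4]:
        mean, trials = sqs_richness(b, SQSConfig(quorum=0.6, trials=30, seed=1))
        assert (trials <= b.n_genera).all()
        assert mean <= b.n_genera
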