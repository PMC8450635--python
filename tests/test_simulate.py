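import math

import numpy as np
import pytest

from paleoprev import (
    GeoInterval,
    SimulationParams,
    assign_interval,
    filter_analytical,
    read_occurrence_table,
    read_parasitism_table,
    scenario_bundle,
    select_prevalence_eligible,
    simulate_sampling,
    simulate_taxon_history,
)
from paleoprev.simulate import ELIGIBLE_FRAC, CAT4_RATIO, replica_bundle

UNIFORM_BINS = tuple(
    GeoInterval(f"bin{i}", "period", 300.0 - 50.0 * i, 250.0 - 50.0 * i, "Paleozoic")
    for i in range(6)
)


def test_zero_extinction_ranges_to_youngest_bin():
    params = SimulationParams(bins=UNIFORM_BINS, n0=30, ext_rate=0.0, mass_extinctions=())
    hist = simulate_taxon_history(params, 0)
    original = hist.ranges.iloc[:30]
    assert (original["last_bin"] == len(UNIFORM_BINS) - 1).all()


def test_no_turnover_keeps_richness_constant():
    params = SimulationParams(
        bins=UNIFORM_BINS, n0=25, orig_rate=0.0, ext_rate=0.0, mass_extinctions=()
    )
    hist = simulate_taxon_history(params, 1)
    assert (hist.richness == 25).all()


def test_empty_pool_warns():
    with pytest.warns(UserWarning):
        hist = simulate_taxon_history(
            SimulationParams(bins=UNIFORM_BINS, n0=0), 0
        )
    assert hist.ranges.empty


def test_final_richness_matches_branching_mean():
    params = SimulationParams(
        bins=UNIFORM_BINS, n0=40, orig_rate=0.006, ext_rate=0.005,
        mass_extinctions=(),
    )
    finals = np.array(
        [simulate_taxon_history(params, seed).richness[-1] for seed in range(200)]
    )
    # E[N_{i+1}] = N_i * (exp(-mu d) + lambda d) per transition
    expected = 40.0
    for b in UNIFORM_BINS[:-1]:
        d = b.duration_myr
        expected *= math.exp(-params.ext_rate * d) + params.orig_rate * d
    se = finals.std(ddof=1) / math.sqrt(len(finals))
    assert abs(finals.mean() - expected) < 3 * se


def test_sampling_intensity_zero_gives_empty_table():
    params = SimulationParams(bins=UNIFORM_BINS, n0=10, sampling_mean=0.0)
    hist = simulate_taxon_history(params, 0)
    assert simulate_sampling(hist, params, 1) == []


def test_sampled_ages_stay_inside_bins():
    params = SimulationParams(bins=UNIFORM_BINS, n0=15, sampling_mean=2.0)
    hist = simulate_taxon_history(params, 2)
    occ = simulate_sampling(hist, params, 3)
    for o in occ[:200]:
        b = next(bb for bb in UNIFORM_BINS if bb.name == o.period)
        assert b.min_ma < o.max_ma < b.max_ma
        assert o.max_ma == o.min_ma  # point ages never cross bin bounds


def test_bundle_row_counts_match_preset_exactly():
    for preset, total in (("paper", 1424), ("tiny", 180)):
        bundle = scenario_bundle("amplification", preset=preset, seed=4)
        analytical = filter_analytical(bundle.parasitism)
        eligible = select_prevalence_eligible(analytical, 10)
        assert len(analytical) == total
        assert len(bundle.parasitism) == total + round(total * CAT4_RATIO)
        assert len(eligible) == round(total * ELIGIBLE_FRAC)


def test_replica_bundle_pins_printed_marginals():
    bundle = replica_bundle(seed=9)
    analytical = filter_analytical(bundle.parasitism)
    eligible = select_prevalence_eligible(analytical, 10)
    by_era = lambda recs: {
        e: sum(r.era == e for r in recs)
        for e in ("Paleozoic", "Mesozoic", "Cenozoic")
    }
    assert len(bundle.parasitism) == 2118
    assert by_era(analytical) == {"Paleozoic": 481, "Mesozoic": 492, "Cenozoic": 451}
    assert by_era(eligible) == {"Paleozoic": 112, "Mesozoic": 144, "Cenozoic": 117}


def test_unknown_scenario_and_preset_raise():
    with pytest.raises(ValueError, match="scenario"):
        scenario_bundle("decoy", seed=0)
    with pytest.raises(ValueError, match="preset"):
        scenario_bundle("neutral", preset="huge", seed=0)


def test_bundle_outputs_are_deterministic(tmp_path):
    p1 = scenario_bundle("neutral", "tiny", seed=5, outdir=tmp_path / "a").write(
        tmp_path / "a"
    )
    p2 = scenario_bundle("neutral", "tiny", seed=5, outdir=tmp_path / "b").write(
        tmp_path / "b"
    )
    for key in ("parasitism", "occurrences", "truth"):
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_neutral_pooled_prevalence_matches_intercept(tiny_neutral_bundle):
    bundle = scenario_bundle("neutral", "paper", seed=8)
    eligible = select_prevalence_eligible(filter_analytical(bundle.parasitism), 10)
    k = sum(r.n_infested for r in eligible)
    n = sum(r.n_specimens for r in eligible)
    pi = 1.0 / (1.0 + math.exp(2.75))  # logistic(intercept), b = 0
    se = math.sqrt(pi * (1 - pi) / n)
    assert abs(k / n - pi) < 4 * se


def test_amplification_prevalence_tracks_richness(paper_amp_bundle):
    eligible = select_prevalence_eligible(
        filter_analytical(paper_amp_bundle.parasitism), 10
    )
    periods = list(paper_amp_bundle.truth.periods)
    pooled = []
    richness = []
    for i, period in enumerate(periods):
        rows = [r for r in eligible if r.period == period]
        n = sum(r.n_specimens for r in rows)
        if n >= 200:
            pooled.append(sum(r.n_infested for r in rows) / n)
            richness.append(paper_amp_bundle.truth.richness[i])
    r = np.corrcoef(richness, pooled)[0, 1]
    assert len(pooled) >= 5 and r > 0.5


def test_emitted_tables_pass_validation(tmp_path, tiny_amp_bundle):
    paths = tiny_amp_bundle.write(tmp_path)
    records, rep = read_parasitism_table(paths["parasitism"])
    assert rep.n_rejected == 0 and len(records) == len(tiny_amp_bundle.parasitism)
    occ, occ_rep = read_occurrence_table(paths["occurrences"])
    assert occ_rep.n_rejected == 0
    assert not any(o.age_ambiguous for o in occ)
    for r in records[:100]:
        p, e = assign_interval(r.best_age_ma)
        assert (p.name, e.name) == (r.period, r.era)
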