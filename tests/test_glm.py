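import math

import numpy as np
import pandas as pd
import pytest

from paleoprev import (
    ModelSpec,
    OccurrenceCountModel,
    PrevalenceModel,
    SQSConfig,
    classify_support,
    diversity_table,
    filter_analytical,
    fit_glm,
    select_prevalence_eligible,
)
from paleoprev.glm import GLMFit, sig_code, wald_summary


def test_intercept_only_poisson_closed_form():
    data = pd.DataFrame({"count": [1, 2, 3], "weight": [1.0, 1.0, 1.0]})
    fit = fit_glm(ModelSpec("count", ()), data)
    assert fit.params["Intercept"] == pytest.approx(math.log(2), abs=1e-8)


def test_intercept_only_weighted_poisson_closed_form():
    data = pd.DataFrame({"count": [0, 4], "weight": [1.0, 3.0]})
    fit = fit_glm(ModelSpec("count", ()), data)
    assert fit.params["Intercept"] == pytest.approx(math.log(3), abs=1e-8)


def test_intercept_only_binomial_closed_form():
    # 30 successes of 100 trials, split over two rows
    data = pd.DataFrame({"k": [20, 10], "n": [60, 40], "weight": [1.0, 1.0]})
    fit = fit_glm(ModelSpec("proportion", ()), data)
    assert fit.params["Intercept"] == pytest.approx(
        math.log(0.3 / 0.7), abs=1e-8
    )


def test_weight_scale_invariance_and_se_shrinkage():
    rng = np.random.default_rng(2)
    x = rng.normal(size=60)
    data = pd.DataFrame(
        {
            "count": rng.poisson(np.exp(0.4 + 0.5 * x)),
            "x": x,
            "weight": rng.uniform(0.5, 2.0, size=60),
        }
    )
    spec = ModelSpec("count", ("x",))
    fit1 = fit_glm(spec, data)
    fit2 = fit_glm(spec, data.assign(weight=data["weight"] * 2.0))
    assert np.abs(fit1.params - fit2.params).max() < 1e-8
    assert fit2.bse.to_numpy() == pytest.approx(
        fit1.bse.to_numpy() / math.sqrt(2.0), rel=1e-6
    )


def test_deviance_nonincreasing_in_nested_models():
    rng = np.random.default_rng(4)
    n = 50
    data = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
            "weight": np.ones(n),
        }
    )
    data["count"] = rng.poisson(np.exp(0.5 + 0.4 * data.x1 - 0.2 * data.x2))
    deviances = [
        fit_glm(ModelSpec("count", preds), data).deviance
        for preds in [(), ("x1",), ("x1", "x2"), ("x1", "x2", "x3")]
    ]
    assert all(a >= b - 1e-9 for a, b in zip(deviances, deviances[1:]))


def test_too_few_rows_refused():
    data = pd.DataFrame(
        {"count": [1, 2, 3], "x1": [1, 2, 3], "x2": [3, 1, 2], "weight": [1.0] * 3}
    )
    with pytest.raises(ValueError, match="rows"):
        fit_glm(ModelSpec("count", ("x1", "x2")), data)


def test_rank_deficient_design_is_flagged_not_silent():
    data = pd.DataFrame(
        {
            "count": [3, 4, 5, 6, 7],
            "x": [1.0, 1.0, 1.0, 1.0, 1.0],  # collinear with the intercept
            "weight": [1.0] * 5,
        }
    )
    fit = fit_glm(ModelSpec("count", ("x",)), data)
    assert not fit.converged and "rank_deficient" in fit.flags
    assert fit.params.isna().all()


@pytest.mark.parametrize(
    "z, code",
    [(0.0, ""), (1.7, "#"), (2.1, "*"), (2.7, "**"), (3.5, "***")],
)
def test_wald_codes(z, code):
    fit = GLMFit(
        spec=ModelSpec("count", ()),
        params=pd.Series({"Intercept": z}),
        bse=pd.Series({"Intercept": 1.0}),
        deviance=0.0, converged=True, n_rows=10,
    )
    table = wald_summary(fit)
    row = table.set_index("term").loc["Intercept"]
    assert row["code"] == code
    if z == 0:
        assert row["p"] == pytest.approx(1.0)
    if z == 1.7:
        assert row["p"] == pytest.approx(0.0891, abs=5e-4)


def test_sig_code_thresholds():
    assert [sig_code(p) for p in (0.0005, 0.005, 0.02, 0.07, 0.2)] == [
        "***", "**", "*", "#", "",
    ]


@pytest.fixture(scope="module")
def fitted_models(paper_amp_bundle):
    analytical = filter_analytical(paper_amp_bundle.parasitism)
    div = diversity_table(
        paper_amp_bundle.occurrences, SQSConfig(quorum=0.6, trials=50, seed=21)
    )
    eligible = select_prevalence_eligible(analytical, 10)
    occ_model = OccurrenceCountModel.from_records(analytical, div)
    prev_model = PrevalenceModel.from_records(eligible, div)
    return occ_model, prev_model


def test_occurrence_model_drops_incomplete_periods(fitted_models):
    occ_model, _ = fitted_models
    fit = occ_model.fit()
    assert fit.converged
    # edge periods have undefined turnover rates and are complete-case dropped
    assert "Cambrian" in fit.dropped_rows and "Quaternary" in fit.dropped_rows
    assert fit.n_rows == 12 - len(fit.dropped_rows)


def test_prevalence_intercept_only_reduction(fitted_models):
    _, prev_model = fitted_models
    data = prev_model.data
    reduced = PrevalenceModel(
        data, predictors=(), group="all"
    ).fit()
    w, k, n = data["weight"], data["k"], data["n"]
    pooled = float((w * k).sum() / (w * n).sum())
    assert reduced.params["Intercept"] == pytest.approx(
        math.log(pooled / (1 - pooled)), abs=1e-8
    )


def test_prevalence_single_period_is_rank_deficient(fitted_models):
    _, prev_model = fitted_models
    one_period = prev_model.data[prev_model.data["period"] == "Devonian"]
    if len(one_period) < 25:
        one_period = pd.concat([one_period] * 5, ignore_index=True)
    fit = PrevalenceModel(one_period).fit()
    assert "rank_deficient" in fit.flags and not fit.converged


def _table(rows):
    return pd.DataFrame(rows, columns=["term", "estimate", "p"]).assign(
        se=1.0, z=0.0, code=""
    )


def test_classification_rules():
    amp = _table([("S_mean", 0.003, 0.0005), ("mu_3t", -0.3, 0.2)])
    assert classify_support(amp).call == "amplification"
    dil = _table([("S_mean", -0.02, 0.0008)])
    assert classify_support(dil).call == "dilution"
    unclear = _table([("S_mean", 0.01, 0.5), ("mu_3t", 0.2, 0.4)])
    call = classify_support(unclear)
    assert call.call == "unclear"
    assert call.notes == ("no significant relationships",)
    rates_amp = _table(
        [("S_mean", 0.001, 0.4), ("lambda_3t", 0.9, 0.01), ("mu_3t", -0.4, 0.3)]
    )
    assert classify_support(rates_amp).call == "amplification"
    ext_dil = _table([("S_mean", 0.001, 0.4), ("mu_3t", 0.8, 0.02)])
    assert classify_support(ext_dil).call == "dilution"
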