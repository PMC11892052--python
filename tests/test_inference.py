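"""Regression layer: LPM, probit AME, cross-fitted DML and their oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from offlabel.errors import ConfigError, EstimationError
from offlabel.inference import (ModelSpec, _package, build_analysis_table,
                                fit_dml_plr, fit_lpm, fit_probit,
                                summarize_models)

BARE = dict(condition_dummies=False, age_dummies=False, sex=False,
            education=False, race=False, year_dummies=False,
            rx_count_dummies=False, mean_approval_year=False)


def _linear_frame(rng, n=800, beta=(0.5, -0.3)):
    x = rng.normal(size=(n, 2))
    d = x @ np.array([0.4, 0.2]) + rng.normal(size=n)
    y = beta[0] * d + x @ np.array([1.0, -0.5]) + rng.normal(size=n)
    return pd.DataFrame({"y": y, "d": d, "x0": x[:, 0], "x1": x[:, 1]})


def test_outcome_cannot_be_exposure():
    with pytest.raises(ConfigError):
        ModelSpec(outcome="frac_indicated")


def test_lpm_equals_frisch_waugh_lovell_partialling():
    """The exposure coefficient equals the residual-on-residual OLS slope."""
    rng = np.random.default_rng(5)
    data = _linear_frame(rng)
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    res = fit_lpm(spec, data)[0]
    X = sm.add_constant(data[["x0", "x1"]])
    ry = sm.OLS(data["y"], X).fit().resid
    rd = sm.OLS(data["d"], X).fit().resid
    fwl = sm.OLS(ry, rd).fit().params.iloc[0]
    assert res.estimate == pytest.approx(fwl, abs=1e-10)


def test_dml_with_insample_linear_learner_is_exact_fwl():
    """With a linear nuisance learner fit in-sample (one fold) the DML
    residual-on-residual estimate reduces to the partialled-out OLS
    coefficient."""
    rng = np.random.default_rng(6)
    data = _linear_frame(rng)
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    ols = fit_lpm(spec, data)[0]
    dml = fit_dml_plr(spec, data, learner="linear", n_folds=1)[0]
    assert dml.estimate == pytest.approx(ols.estimate, abs=1e-6)


def test_constant_exposure_is_estimation_error():
    rng = np.random.default_rng(7)
    data = _linear_frame(rng)
    data["d"] = 0.7
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    with pytest.raises(EstimationError, match="d"):
        fit_lpm(spec, data)


def test_collinear_columns_are_named():
    rng = np.random.default_rng(8)
    data = _linear_frame(rng)
    data["x2"] = data["x0"] + data["x1"]
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1", "x2"), **BARE)
    with pytest.raises(EstimationError, match="collinear"):
        fit_lpm(spec, data)


def test_mean_percentage_normalisation():
    """An estimate of 0.0369 on an outcome with mean 0.3212 is 11.49% of
    the outcome level."""
    spec = ModelSpec(outcome="y", exposures=("d",), **BARE)
    r = _package(spec, "lpm", "d", 0.0369, 0.0070, 0.3212, 1000)
    assert round(r.mean_percentage, 2) == 11.49
    assert r.t_value == pytest.approx(0.0369 / 0.0070)


def test_mean_percentage_invariant_under_outcome_scaling():
    rng = np.random.default_rng(9)
    data = _linear_frame(rng)
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    base = fit_lpm(spec, data)[0]
    scaled = data.copy()
    scaled["y"] = 3.0 * scaled["y"]
    res = fit_lpm(spec, scaled)[0]
    assert res.estimate == pytest.approx(3.0 * base.estimate)
    assert res.mean_percentage == pytest.approx(base.mean_percentage, rel=1e-9)


def test_probit_rejects_degenerate_outcome():
    rng = np.random.default_rng(10)
    data = _linear_frame(rng)
    data["y"] = 0.0
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    with pytest.raises(EstimationError, match="binary"):
        fit_probit(spec, data)


def test_probit_ame_close_to_lpm_on_binary_outcome():
    rng = np.random.default_rng(11)
    n = 4000
    d = rng.uniform(0, 1, n)
    p = np.clip(0.2 + 0.15 * d, 0.01, 0.99)
    data = pd.DataFrame({"y": rng.binomial(1, p), "d": d})
    spec = ModelSpec(outcome="y", exposures=("d",), **BARE)
    lpm = fit_lpm(spec, data)[0]
    probit = fit_probit(spec, data)[0]
    assert probit.estimate == pytest.approx(lpm.estimate, abs=0.02)
    assert probit.std_error > 0


def test_probit_type_one_error_rate_under_null():
    """Zero-effect DGP: the 5% test on the AME rejects at close to its
    nominal rate (200 replicates, n = 1000)."""
    rng = np.random.default_rng(12)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        n = 1000
        d = rng.uniform(0, 1, n)
        x = rng.normal(size=n)
        y = rng.binomial(1, np.clip(0.3 + 0.1 * x, 0.01, 0.99))
        data = pd.DataFrame({"y": y, "d": d, "x0": x})
        spec = ModelSpec(outcome="y", exposures=("d",),
                         extra_controls=("x0",), **BARE)
        res = fit_probit(spec, data)[0]
        rejections += int(res.p_value < 0.05)
    assert 0.02 <= rejections / n_rep <= 0.08


def test_dml_is_reproducible_with_fixed_seed():
    rng = np.random.default_rng(13)
    data = _linear_frame(rng, n=600)
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    a = fit_dml_plr(spec, data, learner="regression_tree", seed=99)[0]
    b = fit_dml_plr(spec, data, learner="regression_tree", seed=99)[0]
    assert (a.estimate, a.std_error) == (b.estimate, b.std_error)


def test_dml_zero_signal_within_two_se():
    rng = np.random.default_rng(14)
    n = 1500
    x = rng.normal(size=(n, 2))
    d = np.sin(x[:, 0]) + rng.normal(size=n)
    y = np.cos(x[:, 1]) + rng.normal(size=n)   # theta = 0
    data = pd.DataFrame({"y": y, "d": d, "x0": x[:, 0], "x1": x[:, 1]})
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    res = fit_dml_plr(spec, data, learner="random_forest",
                      learner_params={"n_estimators": 100}, seed=3)[0]
    assert abs(res.estimate) < 2 * res.std_error


def test_dml_requires_enough_observations():
    rng = np.random.default_rng(15)
    data = _linear_frame(rng, n=30)
    spec = ModelSpec(outcome="y", exposures=("d",),
                     extra_controls=("x0", "x1"), **BARE)
    with pytest.raises(EstimationError, match="n_folds"):
        fit_dml_plr(spec, data, n_folds=5)


def test_lpm_recovers_planted_effects_on_generated_data():
    """Full pipeline single replicate: both exposure betas inside wide
    sampling bands around the truth."""
    from offlabel.classify import classify_all, person_exposures
    from offlabel.simulate import generate, preset_effect_recovery

    config = preset_effect_recovery(seed=424, n_persons=4000)
    sim = generate(config)
    cls, _ = classify_all(sim.kb, sim.dataset)
    expo = person_exposures(cls, sim.dataset, sim.kb)
    table = build_analysis_table(expo, sim.dataset)
    results = {r.exposure: r for r in fit_lpm(ModelSpec(outcome="UNABLE31"),
                                              table)}
    truth = {"frac_contraindicated": 0.04, "frac_indicated": -0.03}
    for expo_name, b in truth.items():
        r = results[expo_name]
        assert abs(r.estimate - b) < 4 * r.std_error
        assert r.ci_low <= r.estimate <= r.ci_high


def test_summarize_models_shapes_and_sign_agreement():
    spec = ModelSpec(outcome="y", exposures=("d",), **BARE)
    a = _package(spec, "lpm", "d", 0.5, 0.1, 1.0, 100)
    b = _package(spec, "dml", "d", 0.4, 0.2, 1.0, 100)
    out = summarize_models([a, b])
    assert len(out) == 2
    assert out["estimators_agree_on_sign"].all()
    c = _package(spec, "probit", "d", -0.1, 0.2, 1.0, 100)
    out2 = summarize_models([a, b, c])
    assert not out2["estimators_agree_on_sign"].any()
    with pytest.raises(EstimationError):
        summarize_models([])


def test_single_result_summary_row():
    spec = ModelSpec(outcome="y", exposures=("d",), **BARE)
    out = summarize_models([_package(spec, "lpm", "d", 0.5, 0.1, 2.0, 50)])
    row = out.iloc[0]
    assert (row["outcome"], row["exposure"], row["n"]) == ("y", "d", 50)
    assert row["mean_percentage"] == pytest.approx(25.0)
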