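"""Net survival, age standardization, EHR surfaces and the MEHR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from exhaz.model import EffectSpec, FittedModel, ModelSpec, ParameterVector
from exhaz.predict import (
    StandardWeights,
    asns,
    asns_ci,
    edi_quintiles,
    ehr_surface,
    emh_curve,
    icss,
    mehr,
    mehr_contrast,
    net_survival,
    percentile_profiles,
)
from exhaz.simulate import preset_scenarios


def stub_fit(spec, assign=None, vcov_scale=0.0):
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    for name, v in (assign or {}).items():
        vals[pv.layout[name]] = v
    pv = pv.with_values(vals)
    return FittedModel(
        spec=spec, params=pv, vcov=vcov_scale * np.eye(pv.n_params),
        loglik=0.0, n_events=1000, n_params=pv.n_params, converged=True,
    )


# -- standard weights -------------------------------------------------------


def test_icss_weight_sets():
    w1 = icss(1)
    assert np.isclose(sum(w1.weights), 1.0)
    merged = icss(1, merge_young=True)
    assert merged.n_groups == 4
    assert merged.weights[0] == pytest.approx(0.19)
    assert merged.labels()[0] == "[15,55)"


def test_bad_weights_rejected():
    with pytest.raises(ValueError):
        StandardWeights(weights=(0.5, 0.2, 0.1, 0.1, 0.2))  # sums to 1.1


def test_group_assignment():
    w = icss(1)
    np.testing.assert_array_equal(w.group_of([20, 45, 54.9, 70, 99]), [0, 1, 1, 3, 4])


# -- net survival -----------------------------------------------------------


def test_null_model_net_survival_is_exp_minus_t():
    fm = stub_fit(ModelSpec(random_effect=False))
    for t in (0.5, 1.0, 3.0):
        assert net_survival(fm, 70.0, 2000.0, 0.0, t) == pytest.approx(np.exp(-t), abs=1e-13)


def test_marginal_equals_conditional_when_sigma_zero():
    fm = stub_fit(ModelSpec(), {"log_sigma": -25.0})
    c = net_survival(fm, 70.0, 2000.0, 0.0, 2.0, mode="conditional_w0")
    m = net_survival(fm, 70.0, 2000.0, 0.0, 2.0, mode="marginal")
    assert m == pytest.approx(c, abs=1e-12)


def test_marginal_matches_trapezoid_oracle():
    # Lambda(5) = 0.8 via constant log-baseline, sigma = 0.5
    fm = stub_fit(ModelSpec(), {"baseline": np.log(0.16), "log_sigma": np.log(0.5)})
    got = net_survival(fm, 70.0, 2000.0, 0.0, 5.0, mode="marginal")
    w = np.linspace(-5.0, 5.0, 100_001)
    oracle = np.trapezoid(np.exp(-np.exp(w) * 0.8) * norm.pdf(w, 0, 0.5), w)
    assert got == pytest.approx(oracle, abs=1e-8)


# -- ASNS -------------------------------------------------------------------


def test_asns_reduces_to_common_survival_without_age_effect():
    fm = stub_fit(ModelSpec(random_effect=False), {"baseline": np.log(0.2)})
    s = net_survival(fm, 30.0, 2002.0, 0.0, 5.0)
    assert asns(fm, icss(1), 0.0, 2002.0, 5.0) == pytest.approx(s, abs=1e-14)


def test_asns_is_the_weighted_mean_of_group_survival():
    fm = stub_fit(ModelSpec(random_effect=False), {"baseline": np.log(0.2), "gamma_age": 0.03})
    w = StandardWeights(edges=(15.0, 55.0, np.inf), weights=(0.4, 0.6), rep_ages=(40.0, 75.0))
    expect = 0.4 * net_survival(fm, 40.0, 2000.0, 1.0, 5.0) + 0.6 * net_survival(
        fm, 75.0, 2000.0, 1.0, 5.0
    )
    assert asns(fm, w, 1.0, 2000.0, 5.0) == pytest.approx(expect, abs=1e-14)


def test_asns_invariant_to_proportional_group_split():
    fm = stub_fit(ModelSpec(random_effect=False), {"baseline": np.log(0.2), "gamma_age": 0.03})
    merged = StandardWeights(edges=(15.0, 65.0, np.inf), weights=(0.5, 0.5), rep_ages=(50.0, 80.0))
    split = StandardWeights(
        edges=(15.0, 40.0, 65.0, np.inf), weights=(0.2, 0.3, 0.5), rep_ages=(50.0, 50.0, 80.0)
    )
    assert asns(fm, split, 0.0, 2000.0, 5.0) == pytest.approx(
        asns(fm, merged, 0.0, 2000.0, 5.0), abs=1e-14
    )


def test_asns_ci_collapses_without_uncertainty():
    fm = stub_fit(ModelSpec(random_effect=False), {"baseline": np.log(0.2)}, vcov_scale=0.0)
    est, lo, hi = asns_ci(fm, icss(1), 0.0, 2000.0, 5.0)
    assert lo == pytest.approx(est, abs=1e-9) and hi == pytest.approx(est, abs=1e-9)


def test_asns_ci_ordered_and_in_unit_interval():
    rng = np.random.default_rng(0)
    spec = ModelSpec(random_effect=False)
    for _ in range(25):
        pv = ParameterVector.zeros(spec)
        vals = pv.values.copy()
        vals[pv.layout["baseline"]] = rng.normal(np.log(0.3), 0.5, 5)
        vals[pv.layout["gamma_age"]] = rng.normal(0, 0.02)
        A = rng.normal(0, 0.05, (pv.n_params, pv.n_params))
        fm = FittedModel(spec=spec, params=pv.with_values(vals), vcov=A @ A.T,
                         loglik=0.0, n_events=500, n_params=pv.n_params, converged=True)
        est, lo, hi = asns_ci(fm, icss(1), 0.0, 2000.0, 5.0)
        assert 0.0 <= lo <= est <= hi <= 1.0


# -- hazard curves and EHR --------------------------------------------------


def test_emh_curve_flat_for_null_model():
    fm = stub_fit(ModelSpec(random_effect=False))
    cur = emh_curve(fm, 70.0, 2000.0, 0.0, np.linspace(0.1, 9.9, 20))
    np.testing.assert_allclose(cur["hazard"], 1.0, atol=1e-13)


def test_proportional_edi_effect_on_curves():
    g = 0.07
    fm = stub_fit(ModelSpec(random_effect=False), {"baseline": np.log(0.3), "gamma_edi": g})
    ts = np.linspace(0.1, 9.9, 15)
    h0 = emh_curve(fm, 70.0, 2000.0, 2.0, ts)["hazard"].to_numpy()
    h1 = emh_curve(fm, 70.0, 2000.0, 3.0, ts)["hazard"].to_numpy()
    np.testing.assert_allclose(h1 / h0, np.exp(g), rtol=1e-12)


def test_percentile_profiles_match_quantiles():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {"age": rng.uniform(20, 95, 500), "year": rng.uniform(1997, 2010, 500),
         "edi": rng.normal(0, 3, 500)}
    )
    prof = percentile_profiles(df)
    assert list(prof["percentile"]) == [10, 50, 90]
    assert prof.loc[1, "age"] == pytest.approx(np.quantile(df["age"], 0.5))
    assert prof.loc[2, "edi"] == pytest.approx(np.quantile(df["edi"], 0.9))


def test_ehr_surface_constant_in_time_for_ph_spec():
    fm = stub_fit(ModelSpec(random_effect=False), {"gamma_edi": 0.05}, vcov_scale=1e-4)
    surf = ehr_surface(fm, np.linspace(-3, 8, 12), times=(0.5, 2.0, 8.0))
    for edi, g in surf.groupby("edi"):
        assert g["ehr"].max() - g["ehr"].min() < 1e-12
        assert g["ehr"].iloc[0] == pytest.approx(np.exp(0.05 * edi), rel=1e-12)


def test_ehr_reference_point_is_exactly_one():
    fm = stub_fit(ModelSpec(random_effect=False), {"gamma_edi": 0.05}, vcov_scale=1e-2)
    surf = ehr_surface(fm, np.array([0.0]), times=(1.0,), ref_edi=0.0)
    assert surf["ehr"].iloc[0] == 1.0
    assert surf["lower"].iloc[0] == 1.0 and surf["upper"].iloc[0] == 1.0


def test_reversing_td_spec_crosses_one():
    cfg = preset_scenarios()["reversing_td"]
    pv = cfg.parameter_vector
    fm = FittedModel(spec=cfg.spec, params=pv, vcov=np.zeros((pv.n_params,) * 2),
                     loglik=0.0, n_events=1000, n_params=pv.n_params, converged=True)
    surf = ehr_surface(fm, np.array([-3.0]), times=(0.5, 3.0))
    early = surf[surf["time"] == 0.5]["ehr"].iloc[0]
    late = surf[surf["time"] == 3.0]["ehr"].iloc[0]
    # for a below-reference (less deprived) area the harmful early effect
    # means EHR < 1, reversing after about a year
    assert early < 1.0 < late


# -- MEHR -------------------------------------------------------------------


def test_mehr_trivial_and_monotone():
    assert mehr(0.0) == 1.0
    grid = np.linspace(0.0, 2.0, 21)
    vals = [mehr(s) for s in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        mehr(-0.1)


def test_mehr_contrast_closed_form():
    fa = stub_fit(ModelSpec(), {"log_sigma": np.log(0.2)}, vcov_scale=1e-4)
    fu = stub_fit(ModelSpec(edi=EffectSpec(include=False)), {"log_sigma": np.log(0.3)},
                  vcov_scale=1e-4)
    tab = mehr_contrast(fa, fu)
    got = dict(zip(tab["model"], tab["mehr"]))
    assert got["adjusted"] == pytest.approx(np.exp(0.9539 * 0.2), abs=1e-4)
    assert got["unadjusted"] == pytest.approx(np.exp(0.9539 * 0.3), abs=1e-4)
    assert got["adjusted"] < got["unadjusted"]


# -- quintiles --------------------------------------------------------------


def test_edi_quintiles_with_explicit_cuts():
    q = edi_quintiles([-3.0, -2.0, -0.5, 1.0, 5.0], cuts=(-2.9, -1.4, 0.0, 2.1))
    np.testing.assert_array_equal(q, [1, 2, 3, 4, 5])
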