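"""Excess-hazard model: linear predictor, quadrature, frailty likelihood, fit."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import norm

from exhaz.lifetable import LifeTable
from exhaz.model import (
    EffectSpec,
    EventsPerParameterError,
    FittedModel,
    ModelSpec,
    ParameterVector,
    cluster_marginal_loglik,
    cumulative_excess_hazard,
    fit,
    linear_predictor,
    loglik,
    lrt,
    validate_cohort,
)
from exhaz.simulate import ScenarioConfig, make_lifetable, simulate_cohort
from exhaz.splines import BSplineBasis, TruncatedQuadraticBasis

from conftest import FULL_SPEC, sane_full_params


# -- linear predictor -------------------------------------------------------


def test_null_params_give_unit_hazard():
    spec = ModelSpec(random_effect=False)
    pv = ParameterVector.zeros(spec)
    for t in (0.0, 1.0, 7.3):
        assert linear_predictor(spec, pv, t, 75.0, 2005.0, 3.0) == 0.0


def test_linear_edi_shifts_predictor_proportionally():
    spec = ModelSpec(random_effect=False)
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    vals[pv.layout["gamma_edi"]] = np.log(1.05)
    pv = pv.with_values(vals)
    for t in (0.2, 2.0, 9.0):
        d = linear_predictor(spec, pv, t, 70.0, 2000.0, 4.0) - linear_predictor(
            spec, pv, t, 70.0, 2000.0, 3.0
        )
        assert d == pytest.approx(np.log(1.05), abs=1e-12)


def test_full_predictor_matches_term_by_term_sum():
    pv = sane_full_params(3)
    t, a, y, i = 2.0, 75.0, 2005.0, 3.0
    tb = BSplineBasis((1.0, 5.0), (0.0, 10.0))
    tp = TruncatedQuadraticBasis(0.0)
    expect = float((tb.eval(t) @ pv.get("baseline"))[0])
    for name, x, c in (("age", a, 70.0), ("year", y, 2000.0), ("edi", i, 0.0)):
        expect += float((tp.eval(x - c) @ pv.get(f"gamma_{name}"))[0])
        expect += float((x - c) * (tb.td(t) @ pv.get(f"eta_{name}"))[0])
    got = linear_predictor(FULL_SPEC, pv, t, a, y, i)
    assert got == pytest.approx(expect, abs=1e-12)


def test_time_outside_window_raises():
    spec = ModelSpec(random_effect=False)
    pv = ParameterVector.zeros(spec)
    with pytest.raises(ValueError):
        cumulative_excess_hazard(spec, pv, 70.0, 2000.0, 0.0, 11.0)


# -- cumulative excess hazard ----------------------------------------------


def test_unit_hazard_cumulative_is_t():
    spec = ModelSpec(random_effect=False)
    pv = ParameterVector.zeros(spec)
    assert cumulative_excess_hazard(spec, pv, 70.0, 2000.0, 0.0, 3.0) == pytest.approx(
        3.0, abs=1e-13
    )


def test_weibull_exponential_special_case():
    spec = ModelSpec(baseline="weibull", random_effect=False)
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    vals[0] = np.log(0.2)  # shape 1, constant rate 0.2
    pv = pv.with_values(vals)
    assert cumulative_excess_hazard(spec, pv, 70.0, 2000.0, 0.0, 5.0) == pytest.approx(1.0)
    assert pv.weibull_shape == pytest.approx(1.0)


def test_spline_cumulative_matches_riemann():
    pv = sane_full_params(7)
    t = 7.0
    grid = np.linspace(0.0, t, 100_001)
    lp = linear_predictor(FULL_SPEC, pv, grid, np.full_like(grid, 75.0), 2005.0, 3.0)
    riemann = np.trapezoid(np.exp(lp), grid)
    got = cumulative_excess_hazard(FULL_SPEC, pv, 75.0, 2005.0, 3.0, t)
    assert got == pytest.approx(riemann, rel=1e-6)


def test_cumulative_monotone_in_t():
    pv = sane_full_params(11)
    ts = np.linspace(0.0, 10.0, 60)
    vals = cumulative_excess_hazard(
        FULL_SPEC, pv, np.full_like(ts, 60.0), 2000.0, -2.0, ts
    )
    assert np.all(np.diff(vals) >= -1e-12)


def test_frailty_scales_cumulative():
    pv = sane_full_params(5)
    base = cumulative_excess_hazard(FULL_SPEC, pv, 70.0, 2001.0, 1.0, 4.0)
    shifted = cumulative_excess_hazard(FULL_SPEC, pv, 70.0, 2001.0, 1.0, 4.0, w=0.7)
    assert shifted == pytest.approx(np.exp(0.7) * base, rel=1e-12)


# -- cluster marginal likelihood -------------------------------------------


def test_sigma_to_zero_limit_equals_no_frailty(const_lt, toy_cohort):
    pv = sane_full_params(1, log_sigma=-20.0)
    ll = loglik(FULL_SPEC, pv, toy_cohort, const_lt)
    spec_nf = replace(FULL_SPEC, random_effect=False)
    ll_nf = loglik(spec_nf, ParameterVector(spec_nf, pv.values[:-1]), toy_cohort, const_lt)
    assert ll == pytest.approx(ll_nf, abs=1e-6)


def test_cluster_loglik_matches_trapezoid_oracle(const_lt, toy_cohort):
    cluster = toy_cohort[toy_cohort["cluster"] == "a"]
    sigma = 0.5
    pv = sane_full_params(1, log_sigma=np.log(sigma))
    got = cluster_marginal_loglik(FULL_SPEC, pv, cluster, const_lt)
    # brute force: trapezoid integration of the joint over the frailty
    spec_nf = replace(FULL_SPEC, random_effect=False)
    pv_nf = ParameterVector(spec_nf, pv.values[:-1])
    t = cluster["t"].to_numpy()
    lam = np.exp(
        linear_predictor(spec_nf, pv_nf, t, cluster["age"].to_numpy(), cluster["year"].to_numpy(), cluster["edi"].to_numpy())
    )
    Lam = cumulative_excess_hazard(
        spec_nf, pv_nf, cluster["age"].to_numpy(), cluster["year"].to_numpy(), cluster["edi"].to_numpy(), t
    )
    w = np.linspace(-5.0, 5.0, 100_001)
    integrand = norm.pdf(w, 0.0, sigma)
    for j in range(len(cluster)):
        d = cluster["status"].to_numpy()[j]
        integrand = integrand * (0.02 + np.exp(w) * lam[j]) ** d * np.exp(-np.exp(w) * Lam[j])
    oracle = np.log(np.trapezoid(integrand, w))
    assert got == pytest.approx(oracle, abs=1e-8)


def test_closed_form_single_event_unit_hazard(zero_lt):
    one = pd.DataFrame(
        {"t": [1.0], "status": [1], "age": [70.0], "year": [2000.0], "edi": [0.0],
         "cluster": ["a"], "sex": "male", "site": "x"}
    )
    spec = ModelSpec()
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    vals[-1] = -20.0  # sigma -> 0
    assert cluster_marginal_loglik(spec, pv.with_values(vals), one, zero_lt) == pytest.approx(
        -1.0, abs=1e-9
    )


def test_cluster_loglik_requires_single_cluster(const_lt, toy_cohort):
    with pytest.raises(ValueError):
        cluster_marginal_loglik(FULL_SPEC, sane_full_params(0), toy_cohort, const_lt)


# -- fitting ----------------------------------------------------------------


def _expo_config(n_clusters=100, mean_size=20.0):
    spec = ModelSpec(baseline="weibull", random_effect=False)
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    vals[0] = np.log(0.3)  # exponential excess hazard, rate 0.3
    return ScenarioConfig(
        name="expo", seed=101, n_clusters=n_clusters, mean_cluster_size=mean_size,
        spec=spec, params=tuple(vals),
    )


def test_fit_recovers_exponential_rate(const_lt):
    cfg = _expo_config()
    data = simulate_cohort(cfg, const_lt)
    fm = fit(cfg.spec, data, const_lt, seed=2)
    assert fm.converged
    b0 = fm.params.get("baseline")[0]
    se = np.sqrt(fm.vcov[0, 0])
    assert abs(b0 - np.log(0.3)) < 3 * se
    assert abs(fm.params.get("baseline")[1]) < 3 * np.sqrt(fm.vcov[1, 1])


def test_fit_recovers_linear_edi_effect():
    lt = make_lifetable("gompertz")
    spec = ModelSpec(gl_nodes=32)
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    L = pv.layout
    vals[L["baseline"]] = np.log(0.3)
    vals[L["gamma_edi"]] = 0.05
    vals[L["log_sigma"]] = np.log(0.3)
    cfg = ScenarioConfig(name="lin", seed=55, n_clusters=120, mean_cluster_size=18.0,
                         spec=spec, params=tuple(vals))
    data = simulate_cohort(cfg, lt)
    fm = fit(spec, data, lt, seed=3)
    assert fm.converged
    k = fm.params.layout["gamma_edi"].start
    est, se = fm.params.get("gamma_edi")[0], np.sqrt(fm.vcov[k, k])
    assert abs(est - 0.05) < 3 * se
    # vcov is symmetric PSD
    eig = np.linalg.eigvalsh(fm.vcov)
    assert eig.min() > -1e-10 * max(eig.max(), 1.0)


def test_events_per_parameter_rule(const_lt):
    cfg = _expo_config(n_clusters=20, mean_size=10.0)
    data = simulate_cohort(cfg, const_lt)
    data = data.iloc[:170]  # ~150 events at most, 27-parameter model refused
    with pytest.raises(EventsPerParameterError):
        fit(FULL_SPEC, data, const_lt)
    fm = fit(
        replace(FULL_SPEC, gl_nodes=16), data, const_lt,
        allow_few_events=True, maxiter=5, restarts=0, compute_vcov=False,
    )
    assert fm.n_params == 27


def test_loglik_invariant_to_edi_recentering(const_lt):
    cfg = _expo_config(n_clusters=60, mean_size=10.0)
    data = simulate_cohort(cfg, const_lt)
    spec = ModelSpec(random_effect=False, gl_nodes=32)
    fm = fit(spec, data, const_lt, seed=0, compute_vcov=False)
    shifted = data.assign(edi=data["edi"] + 5.0)
    spec2 = replace(spec, centers=(("age", 70.0), ("year", 2000.0), ("edi", 5.0)))
    fm2 = fit(spec2, shifted, const_lt, seed=0, compute_vcov=False)
    assert fm2.loglik == pytest.approx(fm.loglik, abs=1e-4)


# -- likelihood-ratio test --------------------------------------------------


def _dummy_fit(spec, ll, n_events=500):
    pv = ParameterVector.zeros(spec)
    return FittedModel(
        spec=spec, params=pv, vcov=np.eye(pv.n_params), loglik=ll,
        n_events=n_events, n_params=pv.n_params, converged=True,
    )


def test_lrt_identical_models():
    spec = ModelSpec()
    stat, df, p = lrt(_dummy_fit(spec, -100.0), _dummy_fit(spec, -100.0))
    assert stat == 0.0 and df == 0 and p == 1.0


def test_lrt_td_block_df_and_chi2_quantile():
    spec = ModelSpec()
    full = spec.with_effect("edi", EffectSpec(time_dependent=True))
    # chi-square upper tail: P(X2_4 > 9.488) = 0.05
    stat, df, p = lrt(_dummy_fit(spec, -100.0), _dummy_fit(full, -100.0 + 9.488 / 2.0))
    assert df == 4
    assert p == pytest.approx(0.05, abs=5e-4)


def test_lrt_rejects_non_nested():
    nested = ModelSpec().with_effect("age", EffectSpec(nonlinear=True))
    full = ModelSpec().with_effect("edi", EffectSpec(nonlinear=True))
    with pytest.raises(ValueError):
        lrt(_dummy_fit(nested, -10.0), _dummy_fit(full, -9.0))


# -- spec and data validation ----------------------------------------------


def test_weibull_forbids_time_dependence():
    with pytest.raises(ValueError):
        ModelSpec(baseline="weibull", edi=EffectSpec(time_dependent=True))


def test_excluded_covariate_cannot_be_flexible():
    with pytest.raises(ValueError):
        EffectSpec(nonlinear=True, include=False)


@pytest.mark.parametrize(
    "patch",
    [{"t": 0.0}, {"status": 2}, {"age": 12.0}],
    ids=["zero-time", "bad-status", "too-young"],
)
def test_cohort_validation(toy_cohort, patch):
    bad = toy_cohort.copy()
    for k, v in patch.items():
        bad.loc[0, k] = v
    with pytest.raises(ValueError):
        validate_cohort(bad)
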