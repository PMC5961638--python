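"""Registry-like synthetic cohorts for excess-hazard analyses.

The generator emulates the structure of a population-based cancer registry
covering a region of small-area census units ("clusters", ~2000 inhabitants
each): an ecological deprivation index drawn at cluster level from a skewed
location-scale distribution, diagnoses spread over 1997-2010 in adults
(> 15 years), administrative censoring mid-2013 with a 10-year analysis
horizon, and all-cause mortality that is the sum of a life-table background
hazard and a configurable excess hazard (the model family of
:mod:`exhaz.model`, including nonlinear, time-dependent and cluster-frailty
effects).

Latent quantities (cause of death, frailty values, uncensored times) are
available for validation only via ``return_latents`` and are never part of
the cohort handed to estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .lifetable import (
    LifeTable,
    invert_expected_cumulative_hazard,
)
from .model import (
    COVARIATES,
    EffectSpec,
    ModelSpec,
    ParameterVector,
    cumulative_excess_hazard,
)

__all__ = [
    "ScenarioConfig",
    "make_lifetable",
    "simulate_cohort",
    "preset_scenarios",
    "write_cohort",
    "spec_to_dict",
    "spec_from_dict",
]

HORIZON = 10.0
_BISECT_TOL = 1e-8  # in cumulative-hazard units


# ---------------------------------------------------------------------------
# model spec (de)serialization shared with the CLI config dialect
# ---------------------------------------------------------------------------


def spec_to_dict(spec: ModelSpec) -> dict:
    d = {
        v: {
            "nonlinear": spec.effect(v).nonlinear,
            "time_dependent": spec.effect(v).time_dependent,
            "include": spec.effect(v).include,
        }
        for v in COVARIATES
    }
    d.update(
        baseline=spec.baseline,
        random_effect=spec.random_effect,
        time_knots=list(spec.time_knots),
        time_boundary=list(spec.time_boundary),
        centers={k: v for k, v in spec.centers},
        gl_nodes=spec.gl_nodes,
        gh_nodes=spec.gh_nodes,
    )
    return d


def spec_from_dict(d: dict) -> ModelSpec:
    kwargs = {}
    for v in COVARIATES:
        e = d.get(v, {})
        kwargs[v] = EffectSpec(
            bool(e.get("nonlinear", False)),
            bool(e.get("time_dependent", False)),
            bool(e.get("include", True)),
        )
    return ModelSpec(
        baseline=d.get("baseline", "spline"),
        random_effect=bool(d.get("random_effect", True)),
        time_knots=tuple(d.get("time_knots", (1.0, 5.0))),
        time_boundary=tuple(d.get("time_boundary", (0.0, 10.0))),
        centers=tuple(sorted(d.get("centers", dict(age=70.0, year=2000.0, edi=0.0)).items())),
        gl_nodes=int(d.get("gl_nodes", 64)),
        gh_nodes=int(d.get("gh_nodes", 10)),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# synthetic life tables
# ---------------------------------------------------------------------------


def make_lifetable(
    kind: str = "gompertz",
    *,
    rate: float = 0.02,
    alpha: float | dict = 2e-5,
    beta: float = 0.10,
    drift: float = 0.0,
    years: tuple[int, int] = (1997, 2013),
    sexes: tuple[str, ...] = ("female", "male"),
    regions: tuple[str, ...] = ("all",),
) -> LifeTable:
    """Complete synthetic expected-mortality table (ages 0-99, all years).

    ``constant``: every cell equals ``rate``.  ``gompertz``: the classic
    adult-mortality law rate(age) = alpha * exp(beta * age) with optional
    proportional calendar ``drift`` per year (rate multiplied by
    (1 - drift)^(year - first_year)); ``alpha`` may be a per-sex dict.
    """
    yrs = np.arange(years[0], years[1] + 1)
    ages = np.arange(100)
    rates = np.empty((len(sexes), 100, len(yrs), len(regions)))
    for s, sex in enumerate(sexes):
        if kind == "constant":
            base = np.full(100, float(rate))
        elif kind == "gompertz":
            a0 = alpha[sex] if isinstance(alpha, dict) else alpha
            base = a0 * np.exp(beta * ages)
        else:
            raise ValueError(f"unknown life-table kind {kind!r}")
        trend = (1.0 - drift) ** (yrs - yrs[0])
        rates[s] = base[:, None, None] * trend[None, :, None]
    return LifeTable(rates, tuple(sexes), yrs, tuple(regions))


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to draw one synthetic cohort, reproducibly.

    Default magnitudes mirror a single-region registry: a few hundred
    clusters of ~2000 inhabitants contributing on the order of 10 cancer
    cases each over 1997-2010, a right-skewed cluster-level deprivation
    index roughly spanning [-17, 51], and follow-up administratively
    censored mid-2013 with a 10-year analysis horizon.
    """

    name: str = "custom"
    seed: int = 0  # mandatory: every draw is reproducible
    n_clusters: int = 300
    mean_cluster_size: float = 10.0
    sex: str = "male"
    site: str = "synthetic"
    # cluster-level deprivation: edi = loc + scale * exp(shape * Z), Z ~ N(0,1)
    edi_loc: float = -4.7
    edi_scale: float = 3.9
    edi_shape: float = 0.7
    edi_jitter_sd: float = 0.0  # optional within-cluster jitter, off by default
    age_mean: float = 68.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (15.01, 99.0)
    year_range: tuple[float, float] = (1997.0, 2010.5)
    censor_date: float = 2013.5
    horizon: float = HORIZON
    spec: ModelSpec = field(default_factory=lambda: ModelSpec(random_effect=True))
    params: tuple[float, ...] = ()  # full parameter vector incl. log_sigma slot

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.mean_cluster_size <= 0:
            raise ValueError("cluster counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not self.params:
            object.__setattr__(
                self, "params", tuple(ParameterVector.zeros(self.spec).values)
            )

    @property
    def parameter_vector(self) -> ParameterVector:
        return ParameterVector(self.spec, np.asarray(self.params))

    @property
    def sigma(self) -> float:
        return self.parameter_vector.sigma if self.spec.random_effect else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = spec_to_dict(self.spec)
        d["params"] = [float(v) for v in self.params]
        d["age_range"] = list(self.age_range)
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["spec"] = spec_from_dict(d["spec"])
        d["params"] = tuple(float(v) for v in d["params"])
        d["age_range"] = tuple(d["age_range"])
        d["year_range"] = tuple(d["year_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _invert_excess(spec, params, a, y, i, targets, horizon):
    """Solve Lambda(t) = target by bisection on the quadrature-evaluated
    cumulative excess hazard; +inf where unreachable within the horizon."""
    n = len(a)
    out = np.full(n, np.inf)
    lam_h = cumulative_excess_hazard(spec, params, a, y, i, np.full(n, horizon))
    todo = targets <= lam_h
    if not todo.any():
        return out
    a, y, i, tg = a[todo], y[todo], i[todo], targets[todo]
    lo = np.zeros(len(a))
    hi = np.full(len(a), horizon)
    # bisection: ~45 halvings bound the cumulative-hazard error far below tol
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        val = cumulative_excess_hazard(spec, params, a, y, i, mid)
        less = val < tg
        lo = np.where(less, mid, lo)
        hi = np.where(less, hi, mid)
        if np.max(hi - lo) * 1.0 < _BISECT_TOL * 1e-2:
            break
    out[todo] = 0.5 * (lo + hi)
    return out


def simulate_cohort(
    cfg: ScenarioConfig,
    lt: LifeTable,
    seed: int | None = None,
    return_latents: bool = False,
):
    """Draw one cohort as a patient DataFrame (t, status, age, year, edi,
    cluster, sex, site).

    Event times: the excess ("cancer") death time inverts
    exp(w) * Lambda(t) = -log U by bracketed root-finding; the background
    death time inverts the exact piecewise-constant expected cumulative
    hazard.  The observed time is the minimum of both with administrative
    censoring at the study cutoff date and the analysis horizon.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sizes = rng.poisson(cfg.mean_cluster_size, cfg.n_clusters)
    sizes = np.maximum(sizes, 1)  # clusters contribute at least one case
    n = int(sizes.sum())
    cl = np.repeat(np.arange(cfg.n_clusters), sizes)
    edi_cluster = cfg.edi_loc + cfg.edi_scale * np.exp(
        cfg.edi_shape * rng.standard_normal(cfg.n_clusters)
    )
    w_cluster = (
        rng.normal(0.0, cfg.sigma, cfg.n_clusters) if cfg.sigma > 0 else np.zeros(cfg.n_clusters)
    )
    edi = edi_cluster[cl]
    if cfg.edi_jitter_sd > 0:
        edi = edi + rng.normal(0.0, cfg.edi_jitter_sd, n)
    lo_a, hi_a = cfg.age_range
    az = (lo_a - cfg.age_mean) / cfg.age_sd, (hi_a - cfg.age_mean) / cfg.age_sd
    age = truncnorm.rvs(*az, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng)
    year = rng.uniform(*cfg.year_range, n)
    w = w_cluster[cl]

    u_e = rng.uniform(size=n)
    target_e = -np.log(u_e) * np.exp(-w)
    t_excess = _invert_excess(
        cfg.spec, cfg.parameter_vector, age, year, edi, target_e, cfg.horizon
    )
    u_p = rng.uniform(size=n)
    t_pop = invert_expected_cumulative_hazard(
        lt, cfg.sex, lt.regions[0], age, year, -np.log(u_p), cfg.horizon,
    )
    t_death = np.minimum(t_excess, t_pop)
    t_censor = np.minimum(cfg.censor_date - year, cfg.horizon)
    status = (t_death <= t_censor).astype(int)
    t_obs = np.maximum(np.minimum(t_death, t_censor), 1e-6)
    df = pd.DataFrame(
        {
            "t": t_obs,
            "status": status,
            "age": age,
            "year": year,
            "edi": edi,
            "cluster": np.char.add("iris_", np.char.zfill(cl.astype(str), 5)),
            "sex": cfg.sex,
            "site": cfg.site,
        }
    )
    if not return_latents:
        return df
    latents = pd.DataFrame(
        {
            "t_excess": t_excess,
            "t_pop": t_pop,
            "w": w,
            "cause": np.where(
                status == 0, "censored", np.where(t_excess <= t_pop, "excess", "population")
            ),
        }
    )
    return df, latents


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _lsq_coefs(basis_matrix: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(basis_matrix, target, rcond=None)[0]


def _baseline_coefs(spec: ModelSpec, log_rate_fn) -> np.ndarray:
    grid = np.linspace(*spec.time_boundary, 201)
    return _lsq_coefs(spec.time_basis.eval(grid), log_rate_fn(grid))


def _td_coefs(spec: ModelSpec, target_fn, gamma: float) -> np.ndarray:
    grid = np.linspace(*spec.time_boundary, 201)
    return _lsq_coefs(spec.time_basis.td(grid), target_fn(grid) - gamma)


def _declining_log_baseline(t):
    # excess hazard falling from ~0.5/yr at diagnosis towards ~0.05/yr
    return np.log(0.05 + 0.45 * np.exp(-0.9 * t))


def _scenario(name, spec, assign, *, sigma=0.24, **kw) -> ScenarioConfig:
    pv = ParameterVector.zeros(spec)
    vals = pv.values.copy()
    L = pv.layout
    vals[L["baseline"]] = _baseline_coefs(spec, _declining_log_baseline)
    for key, value in assign.items():
        vals[L[key]] = value
    if spec.random_effect:
        vals[L["log_sigma"]] = np.log(sigma) if sigma > 0 else -30.0
    return ScenarioConfig(name=name, spec=spec, params=tuple(vals), **kw)


def preset_scenarios() -> dict[str, ScenarioConfig]:
    """Named generating scenarios spanning the qualitative effect patterns
    reported for deprivation: none, linear proportional, nonlinear with a
    plateau in the most deprived, late-emerging time-dependent, and an
    effect that reverses sign around one year after diagnosis."""
    lin = ModelSpec()  # all linear, time-constant, with cluster frailty
    nl_edi = lin.with_effect("edi", EffectSpec(nonlinear=True))
    td_edi = lin.with_effect("edi", EffectSpec(time_dependent=True))

    out = {}
    out["null"] = _scenario("null", lin, {}, sigma=0.2, seed=20251)
    out["linear_ph"] = _scenario(
        "linear_ph",
        lin,
        {"gamma_age": 0.02, "gamma_year": -0.01, "gamma_edi": 0.05},
        sigma=0.3,
        n_clusters=200,
        mean_cluster_size=25.0,
        seed=20252,
    )
    # slope 0.06 per unit below the knot, flattening to ~0 around EDI ~ +7
    out["nonlinear_plateau"] = _scenario(
        "nonlinear_plateau",
        nl_edi,
        {"gamma_age": 0.02, "gamma_edi": [0.06, 0.0, -0.004]},
        sigma=0.24,
        n_clusters=400,
        mean_cluster_size=12.0,
        seed=20253,
    )
    spec_td = td_edi
    late = _td_coefs(spec_td, lambda t: 0.06 * (1.0 - np.exp(-t)), 0.0)
    out["late_td"] = _scenario(
        "late_td",
        spec_td,
        {"gamma_age": 0.02, "gamma_edi": 0.0, "eta_edi": late},
        sigma=0.24,
        n_clusters=400,
        mean_cluster_size=12.0,
        seed=20254,
    )
    # per-unit log-EHR +0.15 at diagnosis, crossing zero near 1 year,
    # settling at -0.08: deleterious early, protective late for high EDI
    rev_fn = lambda t: 0.15 * np.exp(-t) - 0.08 * (1.0 - np.exp(-t))
    rev = _td_coefs(spec_td, rev_fn, 0.15)
    out["reversing_td"] = _scenario(
        "reversing_td",
        spec_td,
        {"gamma_age": 0.02, "gamma_edi": 0.15, "eta_edi": rev},
        sigma=0.24,
        n_clusters=250,
        mean_cluster_size=20.0,
        seed=20255,
    )
    return out
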