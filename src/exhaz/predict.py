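"""Model-based net-survival indicators.

From a fitted excess-hazard model this module derives:

* net survival — exp(-cumulative excess hazard), either conditional on a
  median cluster (w = 0) or marginalized over the frailty distribution;
* age-standardized net survival (ASNS) with International Cancer Survival
  Standard (ICSS) weights and delta-method confidence intervals computed on
  the log cumulative-excess-hazard scale;
* excess-mortality-hazard curves for covariate profiles (e.g. the 10th,
  50th, 90th percentile profiles of the data);
* the excess hazard ratio (EHR) as a function of deprivation and,
  for time-dependent models, of time since diagnosis;
* the median excess hazard ratio (MEHR), the general contextual effect of
  the clustering: exp(sqrt(2) * sigma * Phi^-1(0.75)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.stats import norm

from .model import FittedModel, cumulative_excess_hazard, hazard_design

__all__ = [
    "StandardWeights",
    "NetSurvivalEstimate",
    "icss",
    "net_survival",
    "asns",
    "asns_ci",
    "asns_table",
    "emh_curve",
    "percentile_profiles",
    "ehr_surface",
    "mehr",
    "mehr_contrast",
    "FRENCH_EDI_QUINTILE_CUTS",
    "edi_quintiles",
]

# Deprivation quintile cut points of the index in the French general
# population (quintile 1 = least deprived).
FRENCH_EDI_QUINTILE_CUTS = (-2.9, -1.4, 0.0, 2.1)

# ICSS standard age-group weights (groups 15-44, 45-54, 55-64, 65-74, 75+).
_ICSS_WEIGHTS = {
    1: (0.07, 0.12, 0.23, 0.29, 0.29),
    2: (0.28, 0.17, 0.21, 0.20, 0.14),
    3: (0.60, 0.10, 0.10, 0.10, 0.10),
}
_ICSS_EDGES = (15.0, 45.0, 55.0, 65.0, 75.0, np.inf)
# representative age per group: midpoints, 85 for the open-ended group
_ICSS_REP_AGES = (30.0, 50.0, 60.0, 70.0, 85.0)


@dataclass(frozen=True)
class StandardWeights:
    """Age-group standardization weights partitioning [15, inf)."""

    edges: tuple[float, ...] = _ICSS_EDGES
    weights: tuple[float, ...] = _ICSS_WEIGHTS[1]
    rep_ages: tuple[float, ...] = _ICSS_REP_AGES

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.weights) + 1:
            raise ValueError("need one more edge than weights")
        if len(self.rep_ages) != len(self.weights):
            raise ValueError("need one representative age per group")
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if list(self.edges) != sorted(self.edges) or self.edges[0] != 15.0:
            raise ValueError("age-group edges must increase from 15")

    @property
    def n_groups(self) -> int:
        return len(self.weights)

    def group_of(self, age) -> np.ndarray:
        return np.clip(
            np.searchsorted(np.asarray(self.edges[1:-1]), np.asarray(age, float), side="right"),
            0,
            self.n_groups - 1,
        )

    def labels(self) -> list[str]:
        out = []
        for k in range(self.n_groups):
            hi = self.edges[k + 1]
            out.append(f"[{self.edges[k]:g},{hi:g})" if np.isfinite(hi) else f"{self.edges[k]:g}+")
        return out


def icss(standard: int = 1, merge_young: bool = False) -> StandardWeights:
    """ICSS weight sets 1-3; ``merge_young`` pools [15,45) and [45,55) into
    [15,55) (adding their weights), the sparse-data variant."""
    w = _ICSS_WEIGHTS[standard]
    if not merge_young:
        return StandardWeights(weights=w)
    return StandardWeights(
        edges=(15.0,) + _ICSS_EDGES[2:],
        weights=(w[0] + w[1],) + w[2:],
        rep_ages=(35.0,) + _ICSS_REP_AGES[2:],
    )


@dataclass
class NetSurvivalEstimate:
    """Net survival at a set of times with pointwise confidence bounds."""

    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str  # "model" | "pohar_perme"
    stratum: str = ""
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "time": self.times,
                "estimate": self.estimate,
                "lower": self.lower,
                "upper": self.upper,
                "method": self.method,
            }
        )


def edi_quintiles(edi, cuts=None) -> np.ndarray:
    """Quintile labels 1..5 from cut points (defaults: data quintiles)."""
    edi = np.asarray(edi, float)
    if cuts is None:
        cuts = np.quantile(edi, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(np.asarray(cuts, float), edi, side="right") + 1


# ---------------------------------------------------------------------------
# net survival and age standardization
# ---------------------------------------------------------------------------


def _net_survival_theta(fm: FittedModel, theta, a, y, i, t, mode: str, gh_nodes: int):
    params = fm.params.with_values(theta)
    Lam = cumulative_excess_hazard(fm.spec, params, a, y, i, t)
    if mode == "conditional_w0" or not fm.spec.random_effect:
        return np.exp(-Lam)
    if mode != "marginal":
        raise ValueError(f"unknown mode {mode!r}")
    sigma = params.sigma
    x, w = hermgauss(gh_nodes)
    Lam = np.atleast_1d(Lam)
    vals = np.exp(-np.exp(np.sqrt(2.0) * sigma * x)[None, :] * Lam[:, None])
    out = (vals @ w) / np.sqrt(np.pi)
    return out if np.ndim(t) > 0 else float(out[0])


def net_survival(fm: FittedModel, a, y, i, t, mode: str = "conditional_w0", gh_nodes: int = 64):
    """Net survival for one covariate profile.

    ``conditional_w0``: exp(-Lambda(t)) for a median (w = 0) cluster.
    ``marginal``: the frailty is integrated out by Gauss-Hermite quadrature.
    """
    return _net_survival_theta(fm, fm.params.values, a, y, i, t, mode, gh_nodes)


def _asns_theta(fm, theta, weights, edi_value, y_ref, t, mode, gh_nodes):
    w = np.asarray(weights.weights, float)
    s = np.array(
        [
            _net_survival_theta(fm, theta, ag, y_ref, edi_value, t, mode, gh_nodes)
            for ag in weights.rep_ages
        ]
    )
    return float(w @ s)


def asns(
    fm: FittedModel,
    weights: StandardWeights,
    edi_value: float,
    y_ref: float,
    t: float,
    mode: str = "conditional_w0",
    gh_nodes: int = 64,
) -> float:
    """Age-standardized net survival: ICSS-weighted mean of the net survival
    of representative-age profiles (one per age group)."""
    return _asns_theta(fm, fm.params.values, weights, edi_value, y_ref, t, mode, gh_nodes)


def asns_ci(
    fm: FittedModel,
    weights: StandardWeights,
    edi_value: float,
    y_ref: float,
    t: float,
    mode: str = "conditional_w0",
    level: float = 0.95,
    gh_nodes: int = 64,
    rel_step: float = 1e-5,
) -> tuple[float, float, float]:
    """(estimate, lower, upper) with a delta-method interval.

    Normality is assumed for log(-log S), i.e. the log cumulative excess
    hazard; the gradient with respect to the full parameter vector is
    computed by central finite differences and the interval back-transformed,
    so it always lies inside [0, 1].
    """
    theta = fm.params.values
    est = _asns_theta(fm, theta, weights, edi_value, y_ref, t, mode, gh_nodes)
    grad = np.zeros_like(theta)
    for k in range(len(theta)):
        h = rel_step * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        sp = _asns_theta(fm, tp, weights, edi_value, y_ref, t, mode, gh_nodes)
        sm = _asns_theta(fm, tm, weights, edi_value, y_ref, t, mode, gh_nodes)
        grad[k] = (sp - sm) / (2.0 * h)
    s = min(max(est, 1e-12), 1.0 - 1e-12)
    # d loglog / d theta = dS/dtheta / (S log S)
    gll = grad / (s * np.log(s))
    var = float(gll @ fm.vcov @ gll)
    if var < 0:
        if var < -1e-8:
            raise ValueError("covariance matrix is not positive semi-definite")
        var = 0.0
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    lower = s ** np.exp(half)
    upper = s ** np.exp(-half)
    return est, float(lower), float(upper)


def asns_table(
    fm: FittedModel,
    weights: StandardWeights,
    quintile_edis: dict,
    y_ref: float,
    times=(1.0, 5.0, 10.0),
    mode: str = "conditional_w0",
) -> pd.DataFrame:
    """ASNS with CIs per deprivation quintile and time since diagnosis."""
    rows = []
    for q, edival in quintile_edis.items():
        for t in times:
            est, lo, hi = asns_ci(fm, weights, edival, y_ref, t, mode=mode)
            rows.append(
                {"quintile": q, "edi": edival, "time": t, "estimate": est, "lower": lo, "upper": hi}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hazard curves and hazard-ratio surfaces
# ---------------------------------------------------------------------------


def emh_curve(fm: FittedModel, a: float, y: float, i: float, times) -> pd.DataFrame:
    """Excess mortality hazard (w = 0) over a time grid for one profile."""
    times = np.asarray(times, float)
    X = hazard_design(fm.spec, times, np.full_like(times, a), np.full_like(times, y), np.full_like(times, i))
    return pd.DataFrame({"time": times, "hazard": np.exp(X @ fm.params.hazard), "age": a, "year": y, "edi": i})


def percentile_profiles(data: pd.DataFrame, qs=(0.10, 0.50, 0.90)) -> pd.DataFrame:
    """Covariate percentile profiles of a cohort (age, year, EDI marginals)."""
    rows = [
        {
            "percentile": int(round(100 * q)),
            "age": float(np.quantile(data["age"], q)),
            "year": float(np.quantile(data["year"], q)),
            "edi": float(np.quantile(data["edi"], q)),
        }
        for q in qs
    ]
    return pd.DataFrame(rows)


def ehr_surface(
    fm: FittedModel,
    edi_grid,
    times,
    ref_edi: float = 0.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Excess hazard ratio vs deprivation at given times after diagnosis.

    EHR(i, t) = exp(m(i) - m(ref) + n(t) (i - ref)); time-constant for
    proportional-hazards specs.  The delta-method CI is computed on the log
    scale, with zero width at the reference value.
    """
    edi_grid = np.asarray(edi_grid, float)
    times = np.asarray(times, float)
    centers = fm.spec.center_map
    a0, y0 = centers["age"], centers["year"]
    z = norm.ppf(0.5 + level / 2.0)
    p_h = fm.params.n_hazard
    V = fm.vcov[:p_h, :p_h]
    rows = []
    for t in times:
        tt = np.full_like(edi_grid, t)
        Xi = hazard_design(fm.spec, tt, np.full_like(edi_grid, a0), np.full_like(edi_grid, y0), edi_grid)
        Xr = hazard_design(
            fm.spec, tt, np.full_like(edi_grid, a0), np.full_like(edi_grid, y0), np.full_like(edi_grid, ref_edi)
        )
        D = Xi - Xr
        log_ehr = D @ fm.params.hazard
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, V, D), 0.0))
        rows.append(
            pd.DataFrame(
                {
                    "edi": edi_grid,
                    "time": t,
                    "ehr": np.exp(log_ehr),
                    "lower": np.exp(log_ehr - z * se),
                    "upper": np.exp(log_ehr + z * se),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# median excess hazard ratio
# ---------------------------------------------------------------------------


def mehr(sigma: float) -> float:
    """Median excess hazard ratio for a cluster SD ``sigma``.

    Median of exp(|w1 - w2|) over independent cluster effects
    w ~ Normal(0, sigma^2): exp(sqrt(2) * sigma * Phi^-1(0.75)).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(np.exp(np.sqrt(2.0) * sigma * norm.ppf(0.75)))


def mehr_contrast(fm_with_edi: FittedModel, fm_without_edi: FittedModel) -> pd.DataFrame:
    """MEHR of the deprivation-adjusted and unadjusted fits, side by side.

    The drop from the unadjusted to the adjusted MEHR indicates how much of
    the general contextual (between-cluster) effect the deprivation index
    explains.
    """
    rows = []
    for label, fm in (("adjusted", fm_with_edi), ("unadjusted", fm_without_edi)):
        if not fm.spec.random_effect:
            raise ValueError("MEHR requires a cluster random effect in the model")
        s = fm.sigma
        lo, hi = fm.sigma_ci()
        rows.append(
            {"model": label, "sigma": s, "sigma_lower": lo, "sigma_upper": hi,
             "mehr": mehr(s), "mehr_lower": mehr(lo), "mehr_upper": mehr(hi)}
        )
    return pd.DataFrame(rows)
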