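"""Flexible parametric excess-mortality-hazard (EMH) regression.

The observed all-cause hazard of a cancer patient is decomposed as
``lambda_obs(u) = lambda_E(a+u, y+u) + lambda_plus(u)`` where ``lambda_E`` is
the known expected (general-population) mortality and ``lambda_plus`` the
excess hazard attributable to the cancer.  The full model for the excess
hazard of patient j in cluster c is

    lambda_plus(t, a, y, i | w_c)
        = lambda_0(t) * exp(g(a) + h(t) a + j(y) + k(t) y + m(i) + n(t) i + w_c)

with ``a`` age at diagnosis, ``y`` year of diagnosis, ``i`` the deprivation
index (EDI), and ``w_c ~ Normal(0, sigma^2)`` shared by all patients of the
same small-area cluster (IRIS).  log lambda_0 and the time-dependent
coefficient functions h, k, n are quadratic B-splines of time (knots at 1 and
5 years on [0, 10]); the nonlinear functional forms g, j, m are quadratic
truncated-power splines with one knot (age 70, year 2000, EDI 0).  A Weibull
baseline with linear proportional effects is available as the "simple model"
benchmark.

Estimation is by maximum marginal likelihood: the cluster-shared frailty is
integrated out with mode-centered, curvature-scaled (adaptive) Gauss-Hermite
quadrature; the cumulative excess hazard uses Gauss-Legendre quadrature (the
Weibull family has a closed form).  Individual likelihood factors drop the
parameter-free term exp(-Lambda_E).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from .lifetable import LifeTable, expected_hazard
from .splines import BSplineBasis, TruncatedQuadraticBasis

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "ModelSpec",
    "ParameterVector",
    "param_layout",
    "FittedModel",
    "EventsPerParameterError",
    "linear_predictor",
    "hazard_design",
    "cumulative_excess_hazard",
    "cluster_marginal_loglik",
    "loglik",
    "fit",
    "lrt",
    "read_cohort",
    "validate_cohort",
]

COVARIATES = ("age", "year", "edi")
DEFAULT_CENTERS = {"age": 70.0, "year": 2000.0, "edi": 0.0}

# linear-predictor clip guarding exp overflow far from any optimum
_LP_MAX = 60.0


class EventsPerParameterError(RuntimeError):
    """Model asks for more parameters than the events support (EPV rule)."""


@dataclass(frozen=True)
class EffectSpec:
    """Shape of one covariate's effect on the log excess hazard.

    ``include=False`` drops the covariate from the model altogether (used
    e.g. to fit the deprivation-unadjusted model for the MEHR contrast).
    """

    nonlinear: bool = False
    time_dependent: bool = False
    include: bool = True

    def __post_init__(self) -> None:
        if not self.include and (self.nonlinear or self.time_dependent):
            raise ValueError("an excluded covariate cannot have NL/TD effects")


@dataclass(frozen=True)
class ModelSpec:
    """Which effects the model contains and the knots that realize them.

    ``centers`` double as the single interior knot of each covariate's
    quadratic truncated-power basis; covariates are centered there before
    basis expansion for numerical conditioning (reported hazard ratios are
    invariant to the centering).
    """

    age: EffectSpec = EffectSpec()
    year: EffectSpec = EffectSpec()
    edi: EffectSpec = EffectSpec()
    baseline: str = "spline"  # "spline" | "weibull"
    random_effect: bool = True
    time_knots: tuple[float, ...] = (1.0, 5.0)
    time_boundary: tuple[float, float] = (0.0, 10.0)
    centers: tuple[tuple[str, float], ...] = tuple(DEFAULT_CENTERS.items())
    gl_nodes: int = 64
    gh_nodes: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centers", tuple(sorted((k, float(v)) for k, v in self.centers))
        )
        object.__setattr__(self, "time_knots", tuple(float(k) for k in self.time_knots))
        object.__setattr__(
            self, "time_boundary", tuple(float(b) for b in self.time_boundary)
        )
        if self.baseline not in ("spline", "weibull"):
            raise ValueError(f"unknown baseline family {self.baseline!r}")
        if self.baseline == "weibull":
            if any(self.effect(v).time_dependent for v in COVARIATES):
                raise ValueError(
                    "the Weibull baseline is a proportional-hazards family and "
                    "does not admit time-dependent effects"
                )

    def effect(self, name: str) -> EffectSpec:
        return getattr(self, name)

    @property
    def center_map(self) -> dict[str, float]:
        return dict(self.centers)

    @property
    def time_basis(self) -> BSplineBasis:
        return BSplineBasis(self.time_knots, self.time_boundary)

    def with_effect(self, name: str, effect: EffectSpec) -> "ModelSpec":
        return replace(self, **{name: effect})

    def is_restriction_of(self, other: "ModelSpec") -> bool:
        """True when this spec's parameter space is nested in ``other``'s."""
        if (
            self.baseline != other.baseline
            or self.random_effect != other.random_effect
            or self.time_knots != other.time_knots
            or self.time_boundary != other.time_boundary
            or self.centers != other.centers
        ):
            return False
        for v in COVARIATES:
            s, o = self.effect(v), other.effect(v)
            if s.include and not o.include:
                return False
            if (s.nonlinear and not o.nonlinear) or (s.time_dependent and not o.time_dependent):
                return False
        return True


def param_layout(spec: ModelSpec) -> dict[str, slice]:
    """Named slices into the flat parameter vector, in likelihood order."""
    layout: dict[str, slice] = {}
    pos = 0

    def add(name: str, k: int) -> None:
        nonlocal pos
        layout[name] = slice(pos, pos + k)
        pos += k

    add("baseline", spec.time_basis.dim if spec.baseline == "spline" else 2)
    td_dim = spec.time_basis.dim - 1
    for v in COVARIATES:
        eff = spec.effect(v)
        if not eff.include:
            continue
        add(f"gamma_{v}", 3 if eff.nonlinear else 1)
        if eff.time_dependent:
            add(f"eta_{v}", td_dim)
    if spec.random_effect:
        add("log_sigma", 1)
    return layout


class ParameterVector:
    """Flat coefficient vector with named access tied to a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, values) -> None:
        self.spec = spec
        self.layout = param_layout(spec)
        values = np.asarray(values, dtype=float).ravel()
        if values.shape[0] != self.n_params:
            raise ValueError(
                f"expected {self.n_params} parameters for this spec, got {values.shape[0]}"
            )
        self.values = values

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ParameterVector":
        n = max(s.stop for s in param_layout(spec).values())
        return cls(spec, np.zeros(n))

    @property
    def n_params(self) -> int:
        return max(s.stop for s in self.layout.values())

    @property
    def n_hazard(self) -> int:
        """Number of parameters entering the hazard (everything but log_sigma)."""
        return self.n_params - (1 if self.spec.random_effect else 0)

    def __len__(self) -> int:
        return self.n_params

    def get(self, name: str) -> np.ndarray:
        return self.values[self.layout[name]]

    def with_values(self, values) -> "ParameterVector":
        return ParameterVector(self.spec, values)

    @property
    def hazard(self) -> np.ndarray:
        return self.values[: self.n_hazard]

    @property
    def log_sigma(self) -> float:
        if not self.spec.random_effect:
            raise AttributeError("model has no random effect")
        return float(self.get("log_sigma")[0])

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def weibull_shape(self) -> float:
        if self.spec.baseline != "weibull":
            raise AttributeError("not a Weibull baseline")
        return float(self.get("baseline")[1] + 1.0)

    @property
    def weibull_scale(self) -> float:
        # hazard (k/s)(t/s)^(k-1) matched to exp(b0) t^(k-1)
        b0 = float(self.get("baseline")[0])
        k = self.weibull_shape
        return float(np.exp(-(b0 - np.log(k)) / k))


# ---------------------------------------------------------------------------
# design matrices and hazard evaluation
# ---------------------------------------------------------------------------


def hazard_design(spec: ModelSpec, t, a, y, i) -> np.ndarray:
    """Design matrix X with log lambda_plus(t,a,y,i | w=0) = X @ theta_hazard."""
    t, a, y, i = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(a, float), np.asarray(y, float), np.asarray(i, float)
    )
    t, a, y, i = np.atleast_1d(t), np.atleast_1d(a), np.atleast_1d(y), np.atleast_1d(i)
    tb = spec.time_basis
    centers = spec.center_map
    cov = {"age": a, "year": y, "edi": i}
    blocks = []
    if spec.baseline == "spline":
        blocks.append(tb.eval(t))
        td = None
    else:
        with np.errstate(divide="ignore"):
            blocks.append(np.column_stack([np.ones_like(t), np.log(t)]))
        td = None
    tp = TruncatedQuadraticBasis(0.0)
    for v in COVARIATES:
        eff = spec.effect(v)
        if not eff.include:
            continue
        xc = cov[v] - centers[v]
        blocks.append(tp.eval(xc) if eff.nonlinear else xc[:, None])
        if eff.time_dependent:
            if td is None:
                td = tb.td(t)
            blocks.append(xc[:, None] * td)
    return np.concatenate(blocks, axis=1)


def _gl_scheme(spec: ModelSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights for integrating on [0, t].

    The integrand exp(quadratic spline) is analytic only between the time
    knots, so ``spec.gl_nodes`` nodes are split across the knot-delimited
    segments of [0, t]; segments beyond t collapse to zero length and get
    zero weight.  Returns arrays of shape (n, gl_nodes).
    """
    knots = spec.time_knots
    nseg = len(knots) + 1
    per = [spec.gl_nodes // nseg + (1 if s < spec.gl_nodes % nseg else 0) for s in range(nseg)]
    lo = spec.time_boundary[0]
    breaks = [np.full_like(t, lo)]
    for k in knots:
        breaks.append(np.minimum(t, k))
    breaks.append(t)
    us, ws = [], []
    for s in range(nseg):
        x, w = leggauss(per[s])
        b0, b1 = breaks[s], breaks[s + 1]
        half = 0.5 * (b1 - b0)
        us.append(0.5 * (b0 + b1)[:, None] + half[:, None] * x[None, :])
        ws.append(half[:, None] * w[None, :])
    return np.concatenate(us, axis=1), np.concatenate(ws, axis=1)


def linear_predictor(spec: ModelSpec, params: ParameterVector, t, a, y, i):
    """log excess hazard at w=0 (dimensionless log of deaths per person-year)."""
    X = hazard_design(spec, t, a, y, i)
    out = X @ params.hazard
    return float(out[0]) if np.ndim(t) == 0 and np.ndim(a) == 0 else out


def cumulative_excess_hazard(spec: ModelSpec, params: ParameterVector, a, y, i, t, w=0.0):
    """Integral of the excess hazard on [0, t] for frailty value ``w``.

    Spline family: Gauss-Legendre quadrature with ``spec.gl_nodes`` nodes
    (the integrand exp of a quadratic spline is smooth).  Weibull family:
    closed form.
    """
    a, y, i, t = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(y, float), np.asarray(i, float), np.asarray(t, float)
    )
    scalar = t.ndim == 0
    a, y, i, t = np.atleast_1d(a), np.atleast_1d(y), np.atleast_1d(i), np.atleast_1d(t)
    lo, hi = spec.time_boundary
    if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-9):
        raise ValueError(f"t outside the analysis window [{lo}, {hi}]")
    theta = params.hazard
    if spec.baseline == "weibull":
        b0, b1 = params.get("baseline")
        Xc = hazard_design(spec, np.ones_like(t), a, y, i)[:, 2:]
        const = Xc @ theta[2:] if Xc.shape[1] else np.zeros(len(t))
        shape = b1 + 1.0
        if shape <= 0:
            raise ValueError("Weibull shape (1 + log-time slope) must be positive")
        out = np.exp(np.clip(b0 + const, None, _LP_MAX)) * t**shape / shape
    else:
        u, qw = _gl_scheme(spec, t)
        K = u.shape[1]
        X = hazard_design(
            spec, u.ravel(), np.repeat(a, K), np.repeat(y, K), np.repeat(i, K)
        )
        lp = np.clip(X @ theta, None, _LP_MAX).reshape(len(t), K)
        out = np.sum(np.exp(lp) * qw, axis=1)
    out = np.exp(np.asarray(w, float)) * out
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class _FitData:
    """Per-dataset precomputation shared across likelihood evaluations."""

    spec: ModelSpec
    t: np.ndarray
    delta: np.ndarray
    lam_e: np.ndarray
    cl: np.ndarray  # cluster codes 0..C-1
    n_clusters: int
    X_event: np.ndarray
    # spline family
    X_quad: np.ndarray | None = None
    qw: np.ndarray | None = None  # flattened (n*K,) quadrature weights
    # weibull family
    logt: np.ndarray | None = None
    X_const: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.t)


def _prepare(spec: ModelSpec, data: pd.DataFrame, lt: LifeTable) -> _FitData:
    data = validate_cohort(data)
    t = data["t"].to_numpy(float)
    hi = spec.time_boundary[1]
    if np.any(t > hi + 1e-9):
        raise ValueError(
            f"follow-up beyond the analysis horizon {hi}; censor administratively first"
        )
    a = data["age"].to_numpy(float)
    y = data["year"].to_numpy(float)
    i = data["edi"].to_numpy(float)
    delta = data["status"].to_numpy(float)
    sex = data["sex"].astype(str).to_numpy()
    region = data["region"].astype(str).to_numpy() if "region" in data.columns else None
    lam_e = expected_hazard(lt, sex, region, a, y, t)
    cl_codes, _ = pd.factorize(data["cluster"], sort=True)
    fd = _FitData(
        spec=spec,
        t=t,
        delta=delta,
        lam_e=np.asarray(lam_e, float),
        cl=cl_codes,
        n_clusters=int(cl_codes.max()) + 1 if len(cl_codes) else 0,
        X_event=hazard_design(spec, t, a, y, i),
    )
    if spec.baseline == "weibull":
        fd.logt = np.log(t)
        fd.X_const = fd.X_event[:, 2:]
    else:
        u, qw = _gl_scheme(spec, t)
        K = u.shape[1]
        fd.X_quad = hazard_design(
            spec, u.ravel(), np.repeat(a, K), np.repeat(y, K), np.repeat(i, K)
        )
        fd.qw = qw.ravel()
    return fd


def _lam_Lam(fd: _FitData, theta_h: np.ndarray):
    """Per-patient w=0 excess hazard and cumulative excess hazard (+ cache)."""
    lam = np.exp(np.clip(fd.X_event @ theta_h, -_LP_MAX, _LP_MAX))
    if fd.spec.baseline == "weibull":
        b1 = theta_h[1]
        shape = b1 + 1.0
        if shape <= 1e-8:
            return None, None, None
        const = fd.X_const @ theta_h[2:] if fd.X_const.shape[1] else 0.0
        Lam = np.exp(np.clip(theta_h[0] + const + shape * fd.logt, -_LP_MAX, _LP_MAX)) / shape
        cache = None
    else:
        E = fd.qw * np.exp(np.clip(fd.X_quad @ theta_h, -_LP_MAX, _LP_MAX))
        Lam = E.reshape(fd.n, -1).sum(axis=1)
        cache = E
    return lam, Lam, cache


def _dLam_T(fd: _FitData, theta_h, Lam, cache, weights):
    """(d Lambda / d theta_h)^T @ weights, the cumulative-hazard gradient part."""
    if fd.spec.baseline == "weibull":
        shape = theta_h[1] + 1.0
        wl = weights * Lam
        g = np.empty_like(theta_h)
        g[0] = wl.sum()
        g[1] = (wl * (fd.logt - 1.0 / shape)).sum()
        if fd.X_const.shape[1]:
            g[2:] = fd.X_const.T @ wl
        return g
    K = fd.X_quad.shape[0] // fd.n
    return fd.X_quad.T @ (cache * np.repeat(weights, K))


def _agh_clusters(fd: _FitData, lam, Lam, sigma, gh_x, gh_w):
    """Adaptive Gauss-Hermite marginalization of the shared frailty.

    Returns per-cluster log marginal likelihoods, node positions W (C,Q) and
    posterior node weights pi (C,Q).
    """
    C = fd.n_clusters
    cl, delta, lam_e = fd.cl, fd.delta, fd.lam_e
    LamC = np.bincount(cl, weights=Lam, minlength=C)
    inv_s2 = 1.0 / (sigma * sigma)
    m = np.zeros(C)
    for _ in range(200):
        ew = np.exp(m)
        z = ew[cl] * lam
        r = z / (lam_e + z)
        S1 = np.bincount(cl, weights=delta * r, minlength=C)
        S2 = np.bincount(cl, weights=delta * r * (1.0 - r), minlength=C)
        g = S1 - ew * LamC - m * inv_s2
        h = np.minimum(S2 - ew * LamC - inv_s2, -1e-8)
        step = np.clip(g / (-h), -1.0, 1.0)
        m += step
        if np.max(np.abs(step)) < 1e-12:
            break
    ew = np.exp(m)
    z = ew[cl] * lam
    r = z / (lam_e + z)
    S2 = np.bincount(cl, weights=fd.delta * r * (1.0 - r), minlength=C)
    h = np.minimum(S2 - ew * LamC - inv_s2, -1e-12)
    s = 1.0 / np.sqrt(-h)
    W = m[:, None] + np.sqrt(2.0) * s[:, None] * gh_x[None, :]
    ewW = np.exp(np.clip(W, -_LP_MAX, _LP_MAX))
    Q = len(gh_x)
    ev = np.zeros((C, Q))
    dmask = delta > 0
    le, lm, clm = lam_e[dmask], lam[dmask], cl[dmask]
    for q in range(Q):
        ev[:, q] = np.bincount(clm, weights=np.log(le + ewW[clm, q] * lm), minlength=C)
    F = (
        ev
        - ewW * LamC[:, None]
        - 0.5 * W * W * inv_s2
        - np.log(sigma)
        - 0.5 * np.log(2.0 * np.pi)
    )
    logterms = np.log(gh_w)[None, :] + gh_x[None, :] ** 2 + F
    logLc = logsumexp(logterms, axis=1) + 0.5 * np.log(2.0) + np.log(s)
    pi = np.exp(logterms - logsumexp(logterms, axis=1, keepdims=True))
    return logLc, W, pi


def _loglik_grad(fd: _FitData, theta: np.ndarray, want_grad: bool = True):
    """Marginal log-likelihood (parameter-free exp(-Lambda_E) factor dropped)
    and its analytic gradient.

    With a random effect the gradient is the posterior (quadrature-weighted)
    expectation of the complete-data score, which is exact for the
    frozen-node quadrature objective.
    """
    spec = fd.spec
    p_h = theta.shape[0] - (1 if spec.random_effect else 0)
    theta_h = theta[:p_h]
    lam, Lam, cache = _lam_Lam(fd, theta_h)
    if lam is None:
        return -np.inf, np.zeros_like(theta)
    if spec.random_effect:
        sigma = float(np.exp(np.clip(theta[-1], -30.0, 10.0)))
        gh_x, gh_w = hermgauss(spec.gh_nodes)
        logLc, W, pi = _agh_clusters(fd, lam, Lam, sigma, gh_x, gh_w)
        ll = float(logLc.sum())
        if not want_grad:
            return ll, None
        ewW = np.exp(np.clip(W, -_LP_MAX, _LP_MAX))
        piW = pi[fd.cl]  # (n, Q)
        zW = ewW[fd.cl] * lam[:, None]
        R = zW / (fd.lam_e[:, None] + zW)
        A = (R * piW).sum(axis=1)
        B = (pi * ewW).sum(axis=1)[fd.cl]
        grad_h = fd.X_event.T @ (fd.delta * A) - _dLam_T(fd, theta_h, Lam, cache, B)
        g_ls = float((pi * (W * W / (sigma * sigma) - 1.0)).sum())
        grad = np.concatenate([grad_h, [g_ls]])
    else:
        ll = float(np.sum(fd.delta * np.log(fd.lam_e + lam)) - Lam.sum())
        if not want_grad:
            return ll, None
        r = lam / (fd.lam_e + lam)
        grad = fd.X_event.T @ (fd.delta * r) - _dLam_T(
            fd, theta_h, Lam, cache, np.ones(fd.n)
        )
    if not np.all(np.isfinite(grad)) or not np.isfinite(ll):
        return -np.inf, np.zeros_like(theta)
    return ll, grad


def loglik(spec: ModelSpec, params: ParameterVector, data: pd.DataFrame, lt: LifeTable) -> float:
    """Marginal log-likelihood of the cohort at the given parameters."""
    fd = _prepare(spec, data, lt)
    ll, _ = _loglik_grad(fd, params.values, want_grad=False)
    return ll


def cluster_marginal_loglik(
    spec: ModelSpec, params: ParameterVector, cluster: pd.DataFrame, lt: LifeTable
) -> float:
    """Log marginal likelihood of one cluster (frailty integrated out)."""
    if len(cluster) == 0:
        raise ValueError("cluster must be non-empty")
    if cluster["cluster"].nunique() != 1:
        raise ValueError("records do not share a single cluster id")
    return loglik(spec, params, cluster, lt)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Maximum-likelihood fit: estimates, covariance and diagnostics."""

    spec: ModelSpec
    params: ParameterVector
    vcov: np.ndarray
    loglik: float
    n_events: int
    n_params: int
    converged: bool
    n_iter: int = 0
    message: str = ""
    gl_nodes: int = 64
    gh_nodes: int = 10

    @property
    def sigma(self) -> float | None:
        return self.params.sigma if self.spec.random_effect else None

    def sigma_ci(self, level: float = 0.95) -> tuple[float, float] | None:
        """Wald interval for sigma, computed on the log scale and back-transformed."""
        if not self.spec.random_effect:
            return None
        from scipy.stats import norm

        k = self.params.layout["log_sigma"].start
        se = float(np.sqrt(max(self.vcov[k, k], 0.0)))
        z = norm.ppf(0.5 + level / 2.0)
        ls = self.params.log_sigma
        return float(np.exp(ls - z * se)), float(np.exp(ls + z * se))


def _observed_information(fd: _FitData, theta: np.ndarray) -> np.ndarray:
    p = len(theta)
    H = np.empty((p, p))
    for k in range(p):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        _, gp = _loglik_grad(fd, tp)
        _, gm = _loglik_grad(fd, tm)
        H[:, k] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return -H


def _initial_theta(fd: _FitData) -> np.ndarray:
    d = max(fd.delta.sum(), 1.0)
    c0 = float(np.log(d / max(fd.t.sum(), 1e-8)))
    p_h = fd.X_event.shape[1]
    theta = np.zeros(p_h)
    nb = fd.spec.time_basis.dim if fd.spec.baseline == "spline" else 2
    if fd.spec.baseline == "spline":
        theta[:nb] = c0  # partition of unity: constant log baseline
    else:
        theta[0] = c0
    return theta


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    lt: LifeTable,
    *,
    allow_few_events: bool = False,
    init: np.ndarray | None = None,
    maxiter: int = 500,
    restarts: int = 2,
    seed: int = 0,
    compute_vcov: bool = True,
) -> FittedModel:
    """Fit the excess-hazard model by maximum marginal likelihood.

    Refuses to fit when the number of events is below 10 per parameter (the
    events-per-variable feasibility rule) unless ``allow_few_events`` is set.
    Quasi-Newton (L-BFGS-B) with analytic gradients; on failure, restarts
    from perturbed initial values.  Stage one fits without the frailty, stage
    two adds it starting from the stage-one solution.
    """
    fd = _prepare(spec, data, lt)
    pv0 = ParameterVector.zeros(spec)
    n_params = pv0.n_params
    n_events = int(fd.delta.sum())
    if n_events < 10 * n_params and not allow_few_events:
        raise EventsPerParameterError(
            f"{n_events} events for {n_params} parameters (< 10 per parameter); "
            "pass allow_few_events=True to override"
        )
    p_h = pv0.n_hazard
    # optimize on internally rescaled coordinates: quadratic covariate columns
    # span orders of magnitude, which cripples quasi-Newton conditioning
    scale = np.ones(n_params)
    col_rms = np.sqrt(np.mean(fd.X_event**2, axis=0))
    scale[:p_h] = np.maximum(col_rms, 1e-8)
    bounds = None
    if spec.baseline == "weibull":
        bounds = [(None, None)] * n_params
        bounds[1] = (-0.95 * scale[1], None)  # shape bounded away from 0

    def negll_scaled(ths, n_active):
        s = scale[:n_active]
        if n_active < n_params and spec.random_effect:
            fd.spec = replace(spec, random_effect=False)
        try:
            ll, g = _loglik_grad(fd, ths / s)
        finally:
            fd.spec = spec
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(ths)
        return -ll, -g / s

    opts = {"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7}
    rng = np.random.default_rng(seed)
    theta_h = init[:p_h].copy() if init is not None else _initial_theta(fd)
    best = None
    for attempt in range(restarts + 1):
        # stage 1: no frailty
        res1 = minimize(
            negll_scaled,
            theta_h * scale[:p_h],
            args=(p_h,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds[:p_h] if bounds else None,
            options=opts,
        )
        theta = res1.x / scale[:p_h]
        n_iter = res1.nit
        if spec.random_effect:
            ls0 = init[-1] if init is not None and len(init) == n_params else np.log(0.2)
            res = minimize(
                negll_scaled,
                np.concatenate([theta, [ls0]]) * scale,
                args=(n_params,),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options=opts,
            )
            theta = res.x / scale
            n_iter += res.nit
        else:
            res = res1
        ll = -res.fun
        ok = bool(res.success) and np.isfinite(ll)
        if best is None or ll > best[0]:
            best = (ll, theta, ok, n_iter, str(res.message))
        if ok:
            break
        logger.warning("fit attempt %d did not converge (%s); restarting", attempt, res.message)
        theta_h = _initial_theta(fd) + rng.normal(0.0, 0.2, size=p_h)

    ll, theta, ok, n_iter, message = best
    pv = pv0.with_values(theta if spec.random_effect else theta[:p_h])
    vcov = np.full((n_params, n_params), np.nan)
    if compute_vcov:
        info = _observed_information(fd, pv.values)
        try:
            vcov = np.linalg.inv(info)
            eig = np.linalg.eigvalsh(0.5 * (vcov + vcov.T))
            if eig.min() < -1e-8 * max(eig.max(), 1.0):
                raise np.linalg.LinAlgError("information not positive definite")
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(info)
            ok = False
            message += "; covariance from pseudo-inverse (information singular)"
        vcov = 0.5 * (vcov + vcov.T)
    return FittedModel(
        spec=spec,
        params=pv,
        vcov=vcov,
        loglik=float(ll),
        n_events=n_events,
        n_params=n_params,
        converged=ok,
        n_iter=int(n_iter),
        message=message,
        gl_nodes=spec.gl_nodes,
        gh_nodes=spec.gh_nodes,
    )


def lrt(nested: FittedModel, full: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller model (same data)."""
    if not nested.spec.is_restriction_of(full.spec):
        raise ValueError("first model is not nested in the second")
    if nested.n_events != full.n_events:
        raise ValueError("models were fitted on different data (event counts differ)")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    df = full.n_params - nested.n_params
    if df == 0:
        p = 1.0 if stat < 1e-8 else 0.0
    else:
        p = float(chi2.sf(stat, df))
    return float(stat), int(df), p


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("t", "status", "age", "year", "edi", "cluster", "sex", "site")


def validate_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Check the patient table invariants; returns the (unmodified) frame."""
    missing = [c for c in COHORT_COLUMNS[:7] if c not in data.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s) {missing}")
    t = data["t"].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("follow-up time t must be strictly positive")
    status = data["status"].to_numpy()
    if not np.isin(status, [0, 1]).all():
        raise ValueError("status must be 0 (censored) or 1 (dead)")
    if np.any(data["age"].to_numpy(float) <= 15):
        raise ValueError("age at diagnosis must exceed 15 years")
    return data


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))
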