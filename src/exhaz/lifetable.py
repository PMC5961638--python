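"""Population ("expected") mortality rate tables.

Expected mortality is the background hazard of cancer-free subjects matched on
sex, attained age, calendar year and region.  It enters the excess-hazard
likelihood as an offset and the Pohar-Perme estimator through inverse
expected-survival weights.  Tables give annual hazards (deaths per
person-year) on a complete grid of single years of age 0-99 for a declared
set of sexes, calendar years and regions.

Lookup convention: a patient diagnosed at age ``a`` in decimal year ``y`` has,
at time ``u`` since diagnosis, attained age ``floor(a + u)`` and calendar year
``floor(y + u)``, both clamped to the table edges (age 99, first/last year).
The expected cumulative hazard is integrated exactly over the piecewise
constant segments delimited by integer birthdays and calendar new years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "load_lifetable",
    "write_lifetable",
    "expected_hazard",
    "expected_cumulative_hazard",
    "invert_expected_cumulative_hazard",
]

AGE_MAX = 99

REQUIRED_COLUMNS = ("sex", "age", "year", "region", "rate")


class LifeTableError(ValueError):
    """Malformed or incomplete life table, or failed lookup."""


@dataclass(frozen=True)
class LifeTable:
    """Dense expected-mortality grid.

    ``rates`` has shape ``(n_sex, 100, n_year, n_region)`` with annual
    hazards; ``sexes``/``regions`` are ordered label tuples and ``years``
    the contiguous calendar-year range covered.
    """

    rates: np.ndarray
    sexes: tuple[str, ...]
    years: np.ndarray  # contiguous integer years
    regions: tuple[str, ...]
    _sex_index: dict = field(init=False, repr=False, compare=False)
    _region_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (len(self.sexes), AGE_MAX + 1, len(self.years), len(self.regions)):
            raise LifeTableError(f"rate grid has shape {rates.shape}, inconsistent with labels")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise LifeTableError("life-table rates must be finite and non-negative")
        years = np.asarray(self.years, dtype=int)
        if len(years) == 0 or not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise LifeTableError("life-table years must form a contiguous range")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "_sex_index", {s: k for k, s in enumerate(self.sexes)})
        object.__setattr__(self, "_region_index", {r: k for k, r in enumerate(self.regions)})

    # -- indexing helpers -------------------------------------------------

    def sex_codes(self, sex) -> np.ndarray:
        return self._codes(sex, self._sex_index, "sex")

    def region_codes(self, region) -> np.ndarray:
        if region is None:
            if len(self.regions) != 1:
                raise LifeTableError("table covers several regions; a region is required")
            return np.zeros(1, dtype=int)
        return self._codes(region, self._region_index, "region")

    @staticmethod
    def _codes(values, index: dict, what: str) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(values, dtype=object))
        try:
            return np.array([index[v] for v in arr], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise LifeTableError(f"unknown {what} {exc.args[0]!r} in life-table lookup") from None

    def hazard(self, sex_code, age, year, region_code) -> np.ndarray:
        """Vectorized grid lookup with age/year clamping (codes, not labels)."""
        age_idx = np.clip(np.floor(age).astype(int), 0, AGE_MAX)
        year_idx = np.clip(np.floor(year).astype(int) - self.years[0], 0, len(self.years) - 1)
        return self.rates[sex_code, age_idx, year_idx, region_code]

    def to_frame(self) -> pd.DataFrame:
        sex, age, year, region = np.meshgrid(
            np.arange(len(self.sexes)), np.arange(AGE_MAX + 1),
            self.years, np.arange(len(self.regions)), indexing="ij",
        )
        return pd.DataFrame(
            {
                "sex": np.asarray(self.sexes, dtype=object)[sex.ravel()],
                "age": age.ravel(),
                "year": year.ravel(),
                "region": np.asarray(self.regions, dtype=object)[region.ravel()],
                "rate": self.rates.ravel(),
            }
        )


def load_lifetable(path) -> LifeTable:
    """Read a life table from delimited text with header sex,age,year,region,rate."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LifeTableError(f"life-table file is missing column(s) {missing}")
    return lifetable_from_frame(df)


def lifetable_from_frame(df: pd.DataFrame) -> LifeTable:
    df = df.copy()
    df["age"] = df["age"].astype(int)
    df["year"] = df["year"].astype(int)
    if df.duplicated(["sex", "age", "year", "region"]).any():
        raise LifeTableError("duplicate (sex, age, year, region) cells in life table")
    if (df["rate"] < 0).any():
        raise LifeTableError("negative expected mortality rate in life table")
    ages = np.sort(df["age"].unique())
    if not np.array_equal(ages, np.arange(0, AGE_MAX + 1)):
        raise LifeTableError("life table must cover every single year of age 0-99")
    sexes = tuple(sorted(df["sex"].astype(str).unique()))
    regions = tuple(sorted(df["region"].astype(str).unique()))
    years = np.arange(df["year"].min(), df["year"].max() + 1)
    shape = (len(sexes), AGE_MAX + 1, len(years), len(regions))
    if len(df) != np.prod(shape):
        raise LifeTableError(
            "life table has gaps: expected a complete "
            f"{len(sexes)} sex x 100 age x {len(years)} year x {len(regions)} region grid"
        )
    rates = np.empty(shape)
    sex_idx = df["sex"].astype(str).map({s: k for k, s in enumerate(sexes)}).to_numpy()
    region_idx = df["region"].astype(str).map({r: k for k, r in enumerate(regions)}).to_numpy()
    rates[sex_idx, df["age"].to_numpy(), df["year"].to_numpy() - years[0], region_idx] = df[
        "rate"
    ].to_numpy(dtype=float)
    return LifeTable(rates, sexes, years, regions)


def write_lifetable(lt: LifeTable, path) -> None:
    # %.17g guarantees bit-exact float round-trip through the text format
    lt.to_frame().to_csv(path, index=False, float_format="%.17g")


def _resolve(lt: LifeTable, sex, region, n: int) -> tuple[np.ndarray, np.ndarray]:
    sex_code = lt.sex_codes(sex)
    region_code = lt.region_codes(region)
    return np.broadcast_to(sex_code, (n,)), np.broadcast_to(region_code, (n,))


def expected_hazard(lt: LifeTable, sex, region, a, y, u):
    """Expected mortality rate lambda_E(a+u, y+u) in deaths per person-year.

    ``sex``/``region`` are labels (scalar or array), ``a`` age at diagnosis,
    ``y`` decimal year of diagnosis, ``u`` time since diagnosis (years).
    """
    a, y, u = np.broadcast_arrays(np.asarray(a, float), np.asarray(y, float), np.asarray(u, float))
    if np.any(u < -1e-12):
        raise ValueError("time since diagnosis u must be non-negative")
    scalar = a.ndim == 0
    a, y, u = np.atleast_1d(a), np.atleast_1d(y), np.atleast_1d(u)
    sex_code, region_code = _resolve(lt, sex, region, a.shape[0])
    out = lt.hazard(sex_code, a + u, y + u, region_code)
    return float(out[0]) if scalar else out


def _segment_grid(a: np.ndarray, y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-row sorted breakpoints in [0, t]: 0, t, integer birthdays, new years.

    Returns shape (n, S) nondecreasing; duplicate points give zero-length
    segments which integrate to nothing.
    """
    t_max = float(np.max(t)) if t.size else 0.0
    m = np.arange(int(np.ceil(t_max)) + 1, dtype=float)
    brk_age = (np.floor(a)[:, None] + 1.0 + m[None, :]) - a[:, None]
    brk_year = (np.floor(y)[:, None] + 1.0 + m[None, :]) - y[:, None]
    pts = np.concatenate(
        [np.zeros((len(a), 1)), t[:, None], brk_age, brk_year], axis=1
    )
    pts = np.clip(pts, 0.0, t[:, None])
    pts.sort(axis=1)
    return pts


def expected_cumulative_hazard(lt: LifeTable, sex, region, a, y, t):
    """Exact integral of the expected hazard from 0 to t (dimensionless).

    Computed as a finite sum of rate x duration over the segments on which
    attained age and calendar year are constant.
    """
    a, y, t = np.broadcast_arrays(np.asarray(a, float), np.asarray(y, float), np.asarray(t, float))
    if np.any(t < -1e-12):
        raise ValueError("t must be non-negative")
    scalar = a.ndim == 0
    a, y, t = np.atleast_1d(a), np.atleast_1d(y), np.atleast_1d(t)
    sex_code, region_code = _resolve(lt, sex, region, a.shape[0])
    pts = _segment_grid(a, y, t)
    mid = 0.5 * (pts[:, 1:] + pts[:, :-1])
    dur = np.diff(pts, axis=1)
    rate = lt.hazard(
        sex_code[:, None], a[:, None] + mid, y[:, None] + mid, region_code[:, None]
    )
    out = np.sum(rate * dur, axis=1)
    return float(out[0]) if scalar else out


def invert_expected_cumulative_hazard(lt: LifeTable, sex, region, a, y, targets, horizon: float):
    """Solve Lambda_E(u) = target for u on [0, horizon]; +inf when unreachable.

    Exact inversion: the cumulative hazard is piecewise linear in u, so the
    solution is found by locating the segment and solving linearly within it.
    Used by the cohort simulator to draw background death times.
    """
    a = np.atleast_1d(np.asarray(a, float))
    y = np.atleast_1d(np.asarray(y, float))
    targets = np.atleast_1d(np.asarray(targets, float))
    n = len(a)
    sex_code, region_code = _resolve(lt, sex, region, n)
    t_h = np.full(n, float(horizon))
    pts = _segment_grid(a, y, t_h)
    mid = 0.5 * (pts[:, 1:] + pts[:, :-1])
    dur = np.diff(pts, axis=1)
    rate = lt.hazard(sex_code[:, None], a[:, None] + mid, y[:, None] + mid, region_code[:, None])
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(rate * dur, axis=1)], axis=1)
    out = np.full(n, np.inf)
    reachable = targets <= cum[:, -1]
    idx = np.clip(
        np.array([np.searchsorted(cum[k], targets[k], side="left") for k in range(n)]) - 1,
        0,
        cum.shape[1] - 2,
    )
    rows = np.arange(n)
    seg_rate = rate[rows, idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(seg_rate > 0, (targets - cum[rows, idx]) / seg_rate, 0.0)
    sol = pts[rows, idx] + frac
    out[reachable] = np.clip(sol[reachable], 0.0, horizon)
    return out
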