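import numpy as np
import pandas as pd
import pytest

from exhaz.lifetable import LifeTable
from exhaz.model import EffectSpec, ModelSpec, ParameterVector
from exhaz.simulate import make_lifetable

YEARS = np.arange(1997, 2014)


@pytest.fixture(scope="session")
def const_lt() -> LifeTable:
    """Constant expected mortality of 0.02 per person-year everywhere."""
    return make_lifetable("constant", rate=0.02, sexes=("male",))


@pytest.fixture(scope="session")
def zero_lt() -> LifeTable:
    """Zero expected mortality: all-cause == excess mortality."""
    return LifeTable(np.zeros((1, 100, len(YEARS), 1)), ("male",), YEARS, ("all",))


@pytest.fixture(scope="session")
def gompertz_lt() -> LifeTable:
    return make_lifetable("gompertz", alpha=1e-4, beta=0.09, sexes=("male",))


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": [1.0, 2.0, 0.5, 3.0, 1.5, 2.5],
            "status": [1, 0, 1, 1, 0, 1],
            "age": [70.0, 65.0, 80.0, 75.0, 60.0, 72.0],
            "year": [2000.0, 2005.0, 1999.0, 2003.0, 2008.0, 2001.0],
            "edi": [0.0, 1.0, -2.0, 3.0, 0.5, -1.0],
            "cluster": ["a", "a", "a", "b", "b", "b"],
            "sex": "male",
            "site": "toy",
        }
    )


FULL_SPEC = ModelSpec(
    age=EffectSpec(nonlinear=True, time_dependent=True),
    year=EffectSpec(nonlinear=True, time_dependent=True),
    edi=EffectSpec(nonlinear=True, time_dependent=True),
)


def sane_full_params(seed: int = 0, log_sigma: float = np.log(0.3)) -> ParameterVector:
    """Random full-model coefficients with epidemiologically plausible scale.

    Quadratic covariate terms are drawn small enough that the hazard stays
    within a realistic range over age 40-90, years 1997-2010, EDI -5..15.
    """
    rng = np.random.default_rng(seed)
    pv = ParameterVector.zeros(FULL_SPEC)
    vals = pv.values.copy()
    L = pv.layout
    vals[L["baseline"]] = np.log(0.3) + rng.normal(0.0, 0.3, 5)
    vals[L["gamma_age"]] = [rng.normal(0.02, 0.01), rng.normal(0, 3e-4), rng.normal(0, 3e-4)]
    vals[L["gamma_year"]] = [rng.normal(-0.01, 0.01), rng.normal(0, 1e-3), rng.normal(0, 1e-3)]
    vals[L["gamma_edi"]] = [rng.normal(0.05, 0.02), rng.normal(0, 2e-3), rng.normal(0, 2e-3)]
    vals[L["eta_age"]] = rng.normal(0.0, 0.004, 4)
    vals[L["eta_year"]] = rng.normal(0.0, 0.01, 4)
    vals[L["eta_edi"]] = rng.normal(0.0, 0.02, 4)
    vals[L["log_sigma"]] = log_sigma
    return pv.with_values(vals)
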