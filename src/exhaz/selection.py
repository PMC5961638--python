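"""Backward elimination of spurious time-dependent and nonlinear effects.

Starting from the full model (nonlinear + time-dependent effects of age,
year and deprivation), each round fits every one-component-simpler model,
tests it against the current model with a likelihood-ratio test, and removes
the single component with the largest p-value among those above the
significance threshold.  The linear, time-constant main effect of each of
the three variables is never a removal candidate, so every final model keeps
the simplest form of every variable.

One component is removed per round and every test performed is recorded in
the trace, so the selection path is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    COVARIATES,
    FittedModel,
    ModelSpec,
    fit,
    lrt,
    param_layout,
)

logger = logging.getLogger(__name__)

__all__ = ["backward_eliminate", "SelectionResult"]


@dataclass
class SelectionResult:
    final: FittedModel
    trace: pd.DataFrame
    aborted: bool = False


def _removable(spec: ModelSpec) -> list[tuple[str, str]]:
    comps = []
    for v in COVARIATES:
        eff = spec.effect(v)
        if eff.time_dependent:
            comps.append((v, "td"))
        if eff.nonlinear:
            comps.append((v, "nl"))
    return comps


def _without(spec: ModelSpec, comp: tuple[str, str]) -> ModelSpec:
    v, kind = comp
    eff = spec.effect(v)
    eff = replace(eff, time_dependent=False) if kind == "td" else replace(eff, nonlinear=False)
    return spec.with_effect(v, eff)


def _shrink_init(fm: FittedModel, new_spec: ModelSpec) -> np.ndarray:
    """Warm start for a reduced spec: copy shared blocks, drop the removed one."""
    new_layout = param_layout(new_spec)
    out = np.zeros(max(s.stop for s in new_layout.values()))
    old_layout = fm.params.layout
    for name, sl in new_layout.items():
        if name in old_layout:
            old = fm.params.values[old_layout[name]]
            out[sl] = old[: sl.stop - sl.start]
    return out


def backward_eliminate(
    full_spec: ModelSpec,
    data: pd.DataFrame,
    lt,
    alpha: float = 0.05,
    **fit_kwargs,
) -> SelectionResult:
    """Iterative backward elimination of NL/TD components by LRT at level alpha.

    Returns the final fit and a trace with one row per test performed
    (step, component, statistic, df, p, removed).  A fit failure aborts the
    procedure and returns the partial trace with ``aborted=True``.
    """
    rows: list[dict] = []
    try:
        current = fit(full_spec, data, lt, **fit_kwargs)
    except Exception:
        logger.exception("fit of the full model failed; selection aborted")
        raise
    step = 0
    while True:
        comps = _removable(current.spec)
        if not comps:
            break
        step += 1
        candidates: dict[tuple[str, str], tuple[FittedModel, float, float, int]] = {}
        for comp in comps:
            cand_spec = _without(current.spec, comp)
            try:
                cand = fit(
                    cand_spec,
                    data,
                    lt,
                    init=_shrink_init(current, cand_spec),
                    **fit_kwargs,
                )
            except Exception:
                logger.exception("fit failed while testing removal of %s; aborting", comp)
                return SelectionResult(current, pd.DataFrame(rows), aborted=True)
            stat, df, p = lrt(cand, current)
            candidates[comp] = (cand, stat, p, df)
        worst = max(comps, key=lambda c: candidates[c][2])
        for comp in comps:
            _, stat, p, df = candidates[comp]
            rows.append(
                {
                    "step": step,
                    "component": f"{comp[0]}:{comp[1]}",
                    "statistic": stat,
                    "df": df,
                    "p": p,
                    "removed": comp == worst and candidates[worst][2] > alpha,
                }
            )
        if candidates[worst][2] > alpha:
            logger.info(
                "step %d: removing %s (p=%.4g)", step, worst, candidates[worst][2]
            )
            current = candidates[worst][0]
        else:
            break
    return SelectionResult(current, pd.DataFrame(rows))
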