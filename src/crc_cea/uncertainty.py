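"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full pipeline at the low and high bound of a
single parameter; multivariate scenario analysis swaps whole utility sets;
probabilistic sensitivity analysis (PrSA) draws every non-excluded
parameter from its assigned distribution (beta for probabilities, rates
and utilities; log-normal for costs), re-evaluates every strategy per
iteration, and summarises the result as cost-effectiveness acceptability
curves (CEAC): for each ceiling ratio, the fraction of iterations in which
each strategy maximises net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult, dominance_analysis, icer
from .engine import StrategyOutcome, evaluate_strategies
from .params import (
    ModelParameters,
    PrsaDistributionSpec,
    get_by_path,
    set_by_path,
)

BASELINE = "no_screening"

#: Default ceiling-ratio grid: USD 0 to 100,000 per LY or QALY in steps of 500.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 100_000.0 + 1, 500.0)


@dataclass
class OneWayResult:
    """Univariate sensitivity of one strategy-pair ICER to one parameter."""

    param_path: str
    low: float
    high: float
    icer_low: object  # ratio or quadrant flag
    icer_high: object
    icer_base: object
    pair: tuple
    measure: str

    @property
    def width(self) -> float:
        """ICER interval width (inf when either bound is a flag)."""
        if isinstance(self.icer_low, float) and isinstance(self.icer_high, float):
            return abs(self.icer_high - self.icer_low)
        return float("inf")


def _pair_icer(params: ModelParameters, pair: tuple, measure: str):
    by_name = {s.name: s for s in params.strategies}
    strategies = [by_name[n] for n in pair]
    outcomes = evaluate_strategies(params, strategies=strategies)
    return icer(outcomes[pair[0]], outcomes[pair[1]], measure)


def one_way(
    param_path: str,
    bounds: tuple,
    pair: tuple,
    measure: str,
    params: ModelParameters,
) -> OneWayResult:
    """Re-run the pipeline at each bound of ``param_path`` (all else fixed)
    and report the ICER of ``pair`` = (less effective, more effective).

    Bounds are validated against the full parameter invariants before any
    model run.
    """
    low, high = bounds
    runs = {}
    for label, value in (("low", low), ("high", high)):
        p = params.copy()
        set_by_path(p, param_path, value)
        p.validate()  # raises before any run when the bound is out of range
        runs[label] = _pair_icer(p, pair, measure)
    base = _pair_icer(params, pair, measure)
    return OneWayResult(param_path, low, high, runs["low"], runs["high"],
                        base, tuple(pair), measure)


def tornado(
    param_bounds: dict,
    pair: tuple,
    measure: str,
    params: ModelParameters,
) -> pd.DataFrame:
    """One-way results for several parameters, ordered by ICER interval
    width descending (tornado-diagram order)."""
    results = [one_way(path, b, pair, measure, params)
               for path, b in param_bounds.items()]
    results.sort(key=lambda r: r.width, reverse=True)
    return pd.DataFrame([{
        "parameter": r.param_path, "low": r.low, "high": r.high,
        "icer_low": r.icer_low, "icer_high": r.icer_high,
        "icer_base": r.icer_base, "width": r.width,
    } for r in results])


def scenario_utilities(set_name: str, params: ModelParameters) -> CEAResult:
    """Swap in a named utility set, re-run every strategy and return the
    QALY-measure dominance analysis."""
    if set_name not in params.utility_sets:
        raise KeyError(f"unknown utility set {set_name!r}; "
                       f"available: {sorted(params.utility_sets)}")
    p = params.copy()
    p.utilities = params.utility_sets[set_name]
    outcomes = evaluate_strategies(p)
    return dominance_analysis(list(outcomes.values()), measure="qaly")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PrsaDraws:
    """Monte Carlo parameter draws and per-iteration incremental outcomes
    versus no screening."""

    n: int
    seed: int
    strategies: list  # names, baseline first
    draws: pd.DataFrame  # one row per iteration, one column per drawn path
    delta_cost: np.ndarray  # (n, n_strategies)
    delta_ly: np.ndarray
    delta_qaly: np.ndarray

    def deltas(self, measure: str) -> np.ndarray:
        if measure == "ly":
            return self.delta_ly
        if measure == "qaly":
            return self.delta_qaly
        raise ValueError(f"unknown effectiveness measure {measure!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j, name in enumerate(self.strategies):
                rows.append({
                    "iteration": i, "strategy": name,
                    "delta_cost": self.delta_cost[i, j],
                    "delta_ly": self.delta_ly[i, j],
                    "delta_qaly": self.delta_qaly[i, j],
                })
        return pd.DataFrame(rows)


def prsa(
    spec: Optional[PrsaDistributionSpec],
    n: int,
    seed: int,
    params: ModelParameters,
) -> PrsaDraws:
    """Monte Carlo parameter uncertainty propagation.

    Each iteration draws every parameter listed in ``spec`` from its
    family (excluded parameters stay at base values), re-runs all
    strategies, and records incremental cost/LY/QALY versus no screening.
    Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    if spec is None:
        spec = params.prsa or PrsaDistributionSpec.default_for(params)
    spec.validate(errors := [])
    if errors:
        from .params import ParameterValidationError

        raise ParameterValidationError(errors)
    rng = np.random.default_rng(seed)
    base_values = {path: get_by_path(params, path) for path in spec.entries}
    names = [s.name for s in params.strategies]
    if BASELINE in names:  # baseline first for CEAC convenience
        names = [BASELINE] + [x for x in names if x != BASELINE]
    by_name = {s.name: s for s in params.strategies}
    strategies = [by_name[x] for x in names]

    work = params.copy()  # all drawn paths are overwritten every iteration
    draw_log = np.empty((n, len(spec.entries)))
    paths = list(spec.entries)
    d_cost = np.empty((n, len(names)))
    d_ly = np.empty((n, len(names)))
    d_qaly = np.empty((n, len(names)))
    for i in range(n):
        for j, path in enumerate(paths):
            value = spec.entries[path].draw(rng, base_values[path])
            set_by_path(work, path, value)
            draw_log[i, j] = value
        outcomes = evaluate_strategies(work, strategies=strategies)
        base = outcomes[BASELINE] if BASELINE in outcomes else StrategyOutcome("", 0, 0, 0)
        for j, name in enumerate(names):
            o = outcomes[name]
            d_cost[i, j] = o.cost_per_person - base.cost_per_person
            d_ly[i, j] = o.ly_per_person - base.ly_per_person
            d_qaly[i, j] = o.qaly_per_person - base.qaly_per_person
    return PrsaDraws(
        n=n, seed=seed, strategies=names,
        draws=pd.DataFrame(draw_log, columns=paths),
        delta_cost=d_cost, delta_ly=d_ly, delta_qaly=d_qaly,
    )


@dataclass
class CeacCurve:
    """Probability each strategy is optimal at each ceiling ratio."""

    measure: str
    lambdas: np.ndarray
    strategies: list
    probabilities: np.ndarray  # (n_lambda, n_strategies), rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lam in enumerate(self.lambdas):
            for j, name in enumerate(self.strategies):
                rows.append({"measure": self.measure, "lambda": lam,
                             "strategy": name,
                             "probability_optimal": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def ceac(
    draws: PrsaDraws,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    measure: str = "qaly",
) -> CeacCurve:
    """Cost-effectiveness acceptability curves.

    Per iteration and ceiling ratio, the optimal strategy maximises net
    monetary benefit lambda * dE - dC over all strategies (no screening
    sits at the origin); the curve reports the optimal fraction per
    strategy.  Ties go to the least effective tied strategy.
    """
    lambdas = np.asarray(lambda_grid, dtype=float)
    de = draws.deltas(measure)  # (n, s)
    dc = draws.delta_cost
    probs = np.empty((lambdas.shape[0], len(draws.strategies)))
    for i, lam in enumerate(lambdas):
        nmb = lam * de - dc  # (n, s)
        best = np.argmax(nmb, axis=1)
        counts = np.bincount(best, minlength=len(draws.strategies))
        probs[i] = counts / draws.n
    return CeacCurve(measure, lambdas, list(draws.strategies), probs)
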