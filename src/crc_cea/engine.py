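"""Deterministic cohort recursion and outcome accounting.

The engine propagates cohort fractions over the expanded (surveillance
track x health state) space for 25 annual cycles per sex: the screening
operator acts at the start of each cycle, then the natural-history matrix,
then surveillance counters advance.  Life-years, QALYs and continuing-care
costs are evaluated on cycle boundaries and half-cycle corrected
(trapezoid rule); one-off event costs (tests, colonoscopies, polypectomy,
initial-phase treatment at diagnosis) are charged in full at their event
cycle.  All streams are discounted at the annual rate with cycle 0
undiscounted, and per-sex results are mixed with the configured sex
weights into per-person outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .natural_history import build_transition_matrix
from .params import ModelParameters, ScreeningStrategy, SEXES
from .screening import (
    EVENT_KEYS,
    CycleEventSummary,
    ScreeningOperator,
    build_screening_operator,
)
from .states import (
    DEATH_STATES,
    DIAG_STATES,
    HealthState,
    N_STATES,
    N_TRACKS,
    TRACKS,
    track_shift_index,
)

_SHIFT = np.array([track_shift_index(i) for i in range(N_TRACKS)])
_COLLAPSE_COLS = np.array([int(s) for s in DIAG_STATES + DEATH_STATES])
_ALIVE_VEC = np.array([0.0 if s in DEATH_STATES else 1.0 for s in HealthState])


class NumericalFailure(RuntimeError):
    """Non-finite occupancy encountered during the cohort recursion."""

    def __init__(self, cycle: int):
        self.cycle = cycle
        super().__init__(f"non-finite cohort occupancy at cycle {cycle}")


# ---------------------------------------------------------------------------
# Economic primitives


def discount(stream, rate: float) -> float:
    """Present value of a per-cycle stream: sum of stream[t] / (1+rate)^t,
    with t = 0 (the first cycle) undiscounted."""
    stream = np.asarray(stream, dtype=float)
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(stream.shape[0])
    return float(np.sum(stream / (1.0 + rate) ** t))


def half_cycle_correct(stream) -> np.ndarray:
    """Trapezoid-rule half-cycle correction.

    ``stream`` holds values evaluated on cycle boundaries (length T+1 for a
    T-cycle horizon); each cycle contributes the average of its start and
    end values, so the result has length T.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.shape[0] < 2:
        raise ValueError("need at least one full cycle (two boundary values)")
    return 0.5 * (stream[:-1] + stream[1:])


def boundary_weights(n_cycles: int, rate: float, half_cycle: bool = True) -> np.ndarray:
    """Discounted weight of each cycle boundary in a half-cycle-corrected
    stream total (length n_cycles + 1).

    Equivalent to discount(half_cycle_correct(boundary stream)): interior
    boundary t carries (d_{t-1} + d_t)/2, the two edges half of their
    adjacent cycle's factor.
    """
    d = 1.0 / (1.0 + rate) ** np.arange(n_cycles)
    w = np.zeros(n_cycles + 1)
    if half_cycle:
        w[:-1] += 0.5 * d
        w[1:] += 0.5 * d
    else:
        w[:-1] = d
    return w


# ---------------------------------------------------------------------------
# Cohort containers


@dataclass
class StrategyOutcome:
    """Discounted per-person cost, life-years and QALYs for one strategy."""

    strategy: str
    cost_per_person: float
    ly_per_person: float
    qaly_per_person: float
    se_cost: Optional[float] = None
    se_ly: Optional[float] = None
    se_qaly: Optional[float] = None

    def effect(self, measure: str) -> float:
        if measure == "ly":
            return self.ly_per_person
        if measure == "qaly":
            return self.qaly_per_person
        raise ValueError(f"unknown effectiveness measure {measure!r}")


@dataclass
class CohortTrace:
    """Cycle-by-cycle record of one (strategy, sex) cohort run.

    ``occupancy`` holds cohort fractions on cycle boundaries with shape
    (horizon+1, n_tracks, n_states); ``event_cost`` the per-cycle one-off
    screening/diagnosis costs; ``events`` the expected screening event
    counts per cycle.
    """

    strategy: str
    sex: str
    occupancy: np.ndarray
    event_cost: np.ndarray
    events: list = field(default_factory=list)  # CycleEventSummary per cycle

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_occupancy(self) -> np.ndarray:
        """Boundary occupancy marginalised over tracks, shape (T+1, 14)."""
        return self.occupancy.sum(axis=1)

    def alive_mass(self) -> np.ndarray:
        return self.state_occupancy() @ _ALIVE_VEC

    def to_frame(self, cohort_size: float = 1.0) -> pd.DataFrame:
        rows = []
        for t in range(self.occupancy.shape[0]):
            for ti, (kind, years) in enumerate(TRACKS):
                for s in HealthState:
                    mass = self.occupancy[t, ti, int(s)]
                    if mass > 0:
                        rows.append({
                            "strategy": self.strategy, "sex": self.sex, "cycle": t,
                            "state": s.name, "track": kind, "years_since_colonoscopy": years,
                            "occupancy": mass * cohort_size,
                        })
        return pd.DataFrame(rows)


def events_frame(traces: dict, params: ModelParameters) -> pd.DataFrame:
    """Per-cycle expected screening event counts, sexes mixed, scaled to the
    cohort size."""
    rows = []
    weights = dict(zip(SEXES, params.econ.sex_weights))
    scale = params.econ.cohort_size
    some = next(iter(traces.values()))
    for t in range(some.n_cycles):
        row = {"strategy": some.strategy, "cycle": t,
               "age": params.econ.entry_age + t}
        for key in EVENT_KEYS:
            row[key] = scale * sum(
                weights[sex] * tr.events[t].counts[key] for sex, tr in traces.items())
        row["screening_cost"] = scale * sum(
            weights[sex] * tr.events[t].screening_cost for sex, tr in traces.items())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The recursion


def natural_matrices(params: ModelParameters, sex: str) -> list[np.ndarray]:
    """Natural-history matrix for each cycle age, cached per mortality band."""
    econ = params.econ
    out, cache = [], {}
    for t in range(econ.horizon_years):
        age = econ.entry_age + t
        band = params.mortality.lookup(sex, age)
        key = (band.age_lo, band.age_hi)
        if key not in cache:
            cache[key] = build_transition_matrix(params, age, sex)
        out.append(cache[key])
    return out


def natural_step(occ: np.ndarray, M: np.ndarray) -> np.ndarray:
    """One natural-history transition on the expanded occupancy (tracks x
    states), followed by the surveillance-counter advance; newly diagnosed
    and dead mass leaves its surveillance track."""
    moved = occ @ M
    out = np.zeros_like(moved)
    np.add.at(out, _SHIFT, moved)
    if N_TRACKS > 1:
        spill = out[1:, _COLLAPSE_COLS].sum(axis=0)
        out[1:, _COLLAPSE_COLS] = 0.0
        out[0, _COLLAPSE_COLS] += spill
    return out


def _initial_occupancy(params: ModelParameters) -> np.ndarray:
    occ = np.zeros((N_TRACKS, N_STATES))
    occ[0, :3] = params.natural_history.initial_distribution
    return occ


def run_cohort(
    strategy: ScreeningStrategy,
    params: ModelParameters,
    sex: str,
    ops: Optional[dict] = None,
    nat: Optional[list] = None,
) -> CohortTrace:
    """Propagate one sex's cohort through the full horizon."""
    econ = params.econ
    if ops is None:
        ops = {"no_round": build_screening_operator(params, None)}
        if strategy.primary_test is not None:
            ops["round"] = build_screening_operator(
                params, params.tests[strategy.primary_test])
    if nat is None:
        nat = natural_matrices(params, sex)
    T = econ.horizon_years
    occ = _initial_occupancy(params)
    bounds = np.zeros((T + 1, N_TRACKS, N_STATES))
    bounds[0] = occ
    event_cost = np.zeros(T)
    events = []
    init_cost = np.asarray(params.costs.initial_cost)
    for t in range(T):
        age = econ.entry_age + t
        op: ScreeningOperator = ops["round"] if strategy.round_due(age) else ops["no_round"]
        flat = occ.reshape(-1)
        cost_t = float(flat @ op.cost)
        summary = CycleEventSummary(
            counts={k: float(flat @ v) for k, v in op.events.items()},
            screening_cost=cost_t,
        )
        occ = (flat @ op.S).reshape(N_TRACKS, N_STATES)
        # Symptomatic presentations diagnosed during the coming transition
        # incur the stage-specific initial-phase cost this cycle.
        M = nat[t]
        for k in range(4):
            u_k = int(HealthState.UNDIAG_CRC_I) + k
            d_k = int(HealthState.DIAG_CRC_I) + k
            flow = occ[:, u_k].sum() * M[u_k, d_k]
            cost_t += flow * init_cost[k]
            summary.counts[f"diagnoses_{k + 1}"] += flow
        occ = natural_step(occ, M)
        if not np.all(np.isfinite(occ)):
            raise NumericalFailure(t)
        bounds[t + 1] = occ
        event_cost[t] = cost_t
        events.append(summary)
    return CohortTrace(strategy.name, sex, bounds, event_cost, events)


def accumulate_outcomes(trace: CohortTrace, params: ModelParameters) -> StrategyOutcome:
    """Discounted, half-cycle-corrected per-person outcomes of one trace.

    Life-years integrate the alive mass, QALYs the utility-weighted
    occupancy; costs combine the per-cycle event costs with the
    half-cycle-corrected continuing-care cost of the diagnosed stock.
    """
    econ = params.econ
    rate = econ.discount_rate
    hcc = econ.half_cycle_correction
    state_occ = trace.state_occupancy()
    u = params.utilities.state_vector()
    cont = np.zeros(N_STATES)
    for k in range(4):
        cont[int(HealthState.DIAG_CRC_I) + k] = params.costs.continuing_cost[k]

    w = boundary_weights(trace.n_cycles, rate, half_cycle=hcc)
    ly = float(w @ (state_occ @ _ALIVE_VEC))
    qaly = float(w @ (state_occ @ u))
    cost = discount(trace.event_cost, rate) + float(w @ (state_occ @ cont))
    return StrategyOutcome(trace.strategy, cost, ly, qaly)


def run_strategy(
    strategy: ScreeningStrategy,
    params: ModelParameters,
    ops: Optional[dict] = None,
    nat_by_sex: Optional[dict] = None,
) -> tuple[dict, StrategyOutcome]:
    """Run one strategy for both sexes and mix the per-sex outcomes.

    Returns ({sex: CohortTrace}, StrategyOutcome).
    """
    traces = {}
    parts = []
    for sex, weight in zip(SEXES, params.econ.sex_weights):
        nat = nat_by_sex[sex] if nat_by_sex else None
        trace = run_cohort(strategy, params, sex, ops=ops, nat=nat)
        traces[sex] = trace
        parts.append((weight, accumulate_outcomes(trace, params)))
    outcome = StrategyOutcome(
        strategy.name,
        cost_per_person=sum(w * o.cost_per_person for w, o in parts),
        ly_per_person=sum(w * o.ly_per_person for w, o in parts),
        qaly_per_person=sum(w * o.qaly_per_person for w, o in parts),
    )
    return traces, outcome


def evaluate_strategies(
    params: ModelParameters,
    strategies: Optional[list] = None,
    with_traces: bool = False,
):
    """Outcomes for every strategy, sharing screening operators and
    natural-history matrices across strategies.

    Returns {name: StrategyOutcome}, or ({name: outcome}, {name: traces})
    when ``with_traces`` is set.
    """
    strategies = strategies if strategies is not None else params.strategies
    no_round = build_screening_operator(params, None)
    round_ops = {}
    nat_by_sex = {sex: natural_matrices(params, sex) for sex in SEXES}
    outcomes, all_traces = {}, {}
    for strat in strategies:
        ops = {"no_round": no_round}
        if strat.primary_test is not None:
            if strat.primary_test not in round_ops:
                round_ops[strat.primary_test] = build_screening_operator(
                    params, params.tests[strat.primary_test])
            ops["round"] = round_ops[strat.primary_test]
        traces, outcome = run_strategy(strat, params, ops=ops, nat_by_sex=nat_by_sex)
        outcomes[strat.name] = outcome
        if with_traces:
            all_traces[strat.name] = traces
    if with_traces:
        return outcomes, all_traces
    return outcomes
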