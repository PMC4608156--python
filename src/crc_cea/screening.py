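"""Screening overlay: participation, test outcome, follow-up colonoscopy,
polypectomy, post-polypectomy surveillance, diagnosis and complications.

Screening acts at the start of each cycle, before the natural-history
transition.  A positive stool test leads immediately (within the cycle) to
a follow-up colonoscopy, attended with probability ``c_followup``.
Colonoscopy is perfectly accurate: a polyp found is removed (polypectomy)
and the patient returns to normal epithelium on a surveillance track
(5-yearly colonoscopy after a low-risk polyp, annual after a high-risk
polyp); a cancer found becomes a diagnosed cancer and triggers the
initial-phase treatment cost.  Patients on a surveillance track receive
their surveillance colonoscopy in place of routine screening; diagnosed
patients receive no further screening.

Complication accounting: every colonoscopy carries bleeding and
perforation risks; the fatal fraction moves to death-from-complication,
and complication treatment costs are charged as their per-procedure
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .params import ModelParameters, ScreeningStrategy, TestCharacteristics
from .states import (
    DIAG_STATES,
    DEATH_STATES,
    SURVEILLANCE_INTERVALS,
    TRACKS,
    TRACK_HIGH0,
    TRACK_INDEX,
    TRACK_LOW0,
    TRACK_NONE,
    HealthState,
    N_EXPANDED,
    N_STATES,
    N_TRACKS,
    Track,
    expanded_index,
)
from .states import UNDIAG_STATES


@dataclass(frozen=True)
class SurveillanceTrack:
    """Post-polypectomy surveillance status of a cohort slice."""

    kind: str = "none"  # 'none' | 'post_low_risk_polypectomy' | 'post_high_risk_polypectomy'
    years_since_last_colonoscopy: int = 0

    @property
    def index(self) -> int:
        cap = SURVEILLANCE_INTERVALS.get(self.kind)
        years = self.years_since_last_colonoscopy if cap is None else min(
            self.years_since_last_colonoscopy, cap)
        return TRACK_INDEX[Track(self.kind, 0 if cap is None else years)]


def surveillance_due(track: SurveillanceTrack, cycle_index: int = 0) -> bool:
    """True when the track's surveillance colonoscopy is due this cycle
    (5-year interval after a low-risk polypectomy, 1-year after high-risk)."""
    if track.kind == "none":
        raise ValueError("surveillance_due is undefined for the 'none' track")
    return track.years_since_last_colonoscopy >= SURVEILLANCE_INTERVALS[track.kind]


class Branch(NamedTuple):
    """One probability-weighted outcome of the per-state screening kernel."""

    prob: float
    state: HealthState
    track: int  # track index after the event
    cost: float  # cost incurred along this branch (per participant, expectation)


EVENT_KEYS = (
    "tests",
    "positives",
    "followup_colonoscopies",
    "surveillance_colonoscopies",
    "colonoscopies",
    "polypectomies",
    "diagnoses_1",
    "diagnoses_2",
    "diagnoses_3",
    "diagnoses_4",
    "bleeds",
    "perforations",
    "complication_deaths",
)


@dataclass
class CycleEventSummary:
    """Expected per-person-cycle screening event counts and cost."""

    counts: dict = field(default_factory=lambda: {k: 0.0 for k in EVENT_KEYS})
    screening_cost: float = 0.0


def _fatal_prob(colo: TestCharacteristics) -> float:
    return colo.p_bleed * colo.m_bleed + colo.p_perforation * colo.m_perforation


def _colonoscopy_cascade(
    state: HealthState,
    normal_track: int,
    base_cost: float,
    params: ModelParameters,
) -> tuple[list[Branch], dict]:
    """Branches and expected events for one performed colonoscopy on a
    patient in ``state`` (conditional probability mass 1)."""
    colo = params.tests["colonoscopy"]
    uc = params.costs.unit_cost
    p_fatal = _fatal_prob(colo)
    scope_cost = (
        base_cost
        + uc["colonoscopy"]
        + uc["specialist_visit"]
        + colo.p_bleed * uc["complication_bleed"]
        + colo.p_perforation * uc["complication_perforation"]
    )
    survive = 1.0 - p_fatal
    events = {
        "colonoscopies": 1.0,
        "bleeds": colo.p_bleed,
        "perforations": colo.p_perforation,
        "complication_deaths": p_fatal,
    }
    branches = []
    if p_fatal > 0:
        branches.append(Branch(p_fatal, HealthState.DEATH_COMPLICATION, TRACK_NONE, scope_cost))
    if state == HealthState.NORMAL:
        branches.append(Branch(survive, HealthState.NORMAL, normal_track, scope_cost))
    elif state == HealthState.LOW_RISK_POLYP:
        branches.append(Branch(survive, HealthState.NORMAL, TRACK_LOW0,
                               scope_cost + uc["polypectomy"]))
        events["polypectomies"] = survive
    elif state == HealthState.HIGH_RISK_POLYP:
        branches.append(Branch(survive, HealthState.NORMAL, TRACK_HIGH0,
                               scope_cost + uc["polypectomy"]))
        events["polypectomies"] = survive
    elif state in UNDIAG_STATES:
        k = int(state) - int(HealthState.UNDIAG_CRC_I)
        branches.append(Branch(survive, HealthState(int(HealthState.DIAG_CRC_I) + k),
                               TRACK_NONE, scope_cost + params.costs.initial_cost[k]))
        events[f"diagnoses_{k + 1}"] = survive
    else:
        raise ValueError(f"colonoscopy cascade undefined for state {state!r}")
    return branches, events


def _scale_events(events: dict, factor: float) -> dict:
    return {k: v * factor for k, v in events.items()}


def _merge_events(*event_dicts: dict) -> dict:
    out: dict = {}
    for d in event_dicts:
        for k, v in d.items():
            out[k] = out.get(k, 0.0) + v
    return out


def _kernel(
    state: HealthState,
    track_idx: int,
    test: Optional[TestCharacteristics],
    params: ModelParameters,
) -> tuple[list[Branch], dict]:
    """Screening-phase outcome distribution for one expanded cohort slice.

    ``test`` is the strategy's primary test when a routine round is due this
    cycle, else None.  Returns (branches, expected events per unit mass).
    """
    kind, years = TRACKS[track_idx]
    comp = params.compliance

    if state in DEATH_STATES or state in DIAG_STATES:
        return [Branch(1.0, state, TRACK_NONE, 0.0)], {}

    # Surveillance colonoscopy supersedes routine screening.
    if kind != "none" and years >= SURVEILLANCE_INTERVALS[kind]:
        reset_track = TRACK_INDEX[Track(kind, 0)]
        c = comp.c_followup
        branches = [Branch(1.0 - c, state, track_idx, 0.0)] if c < 1.0 else []
        scope_branches, scope_events = _colonoscopy_cascade(state, reset_track, 0.0, params)
        branches += [Branch(b.prob * c, b.state, b.track, b.cost) for b in scope_branches]
        events = _scale_events(scope_events, c)
        events["surveillance_colonoscopies"] = c
        return branches, events

    if test is None or kind != "none":
        return [Branch(1.0, state, track_idx, 0.0)], {}

    c = comp.c_screen
    if c == 0.0:
        return [Branch(1.0, state, track_idx, 0.0)], {}

    if test.name == "colonoscopy":
        branches = [Branch(1.0 - c, state, track_idx, 0.0)] if c < 1.0 else []
        scope_branches, scope_events = _colonoscopy_cascade(state, TRACK_NONE, 0.0, params)
        branches += [Branch(b.prob * c, b.state, b.track, b.cost) for b in scope_branches]
        return branches, _scale_events(scope_events, c)

    # Stool test cascade.
    test_cost = params.costs.unit_cost[test.name]
    if state == HealthState.NORMAL:
        p_pos = 1.0 - test.specificity
    else:
        p_pos = test.sensitivity_for(state)
    c_fu = comp.c_followup
    branches = []
    if c < 1.0:
        branches.append(Branch(1.0 - c, state, track_idx, 0.0))  # non-participant
    stay_after_test = c * (1.0 - p_pos) + c * p_pos * (1.0 - c_fu)  # negative, or refuses scope
    if stay_after_test > 0:
        branches.append(Branch(stay_after_test, state, track_idx, test_cost))
    attend = c * p_pos * c_fu
    events = {"tests": c, "positives": c * p_pos}
    if attend > 0:
        scope_branches, scope_events = _colonoscopy_cascade(state, TRACK_NONE, test_cost, params)
        branches += [Branch(b.prob * attend, b.state, b.track, b.cost) for b in scope_branches]
        events = _merge_events(events, _scale_events(scope_events, attend),
                               {"followup_colonoscopies": attend})
    return branches, events


def screening_round_kernel(
    state: HealthState,
    track: SurveillanceTrack,
    strategy: ScreeningStrategy,
    cycle_index: int,
    params: ModelParameters,
) -> tuple[list[Branch], dict]:
    """Probability-weighted screening outcomes for one (state, track) slice
    in cycle ``cycle_index`` under ``strategy``.

    Branch probabilities sum to one; events are expected counts per unit of
    occupancy.  Diagnosed and dead slices pass through untouched.
    """
    if state in DEATH_STATES:
        return [Branch(1.0, state, TRACK_NONE, 0.0)], {}
    age = params.econ.entry_age + cycle_index
    due = strategy.round_due(age)
    test = params.tests[strategy.primary_test] if due else None
    return _kernel(state, track.index, test, params)


# ---------------------------------------------------------------------------
# Matrix form of the screening phase (used by the cohort engine,
# the microsimulation and PrSA)


@dataclass
class ScreeningOperator:
    """Linear representation of the screening phase over the expanded
    (track x state) space: transition matrix, per-origin expected cost,
    and per-origin expected event counts."""

    S: np.ndarray  # (N_EXPANDED, N_EXPANDED)
    cost: np.ndarray  # (N_EXPANDED,)
    events: dict  # key -> (N_EXPANDED,)


def build_cycle_operators(
    strategy: ScreeningStrategy, params: ModelParameters
) -> dict:
    """Screening operators keyed by 'round' and 'no_round' for a strategy.

    The no-round operator (surveillance alone) is strategy-independent.
    """
    ops = {"no_round": build_screening_operator(params, None)}
    if strategy.primary_test is not None:
        ops["round"] = build_screening_operator(params, params.tests[strategy.primary_test])
    return ops


def build_screening_operator(
    params: ModelParameters, test: Optional[TestCharacteristics]
) -> ScreeningOperator:
    """Operator for one cycle: ``test`` is the routine test when a round is
    due this cycle, else None (surveillance alone still runs)."""
    S = np.zeros((N_EXPANDED, N_EXPANDED))
    cost = np.zeros(N_EXPANDED)
    events = {k: np.zeros(N_EXPANDED) for k in EVENT_KEYS}
    for ti in range(N_TRACKS):
        for s in HealthState:
            i = expanded_index(ti, s)
            branches, ev = _kernel(s, ti, test, params)
            for b in branches:
                j = expanded_index(b.track, b.state)
                S[i, j] += b.prob
                cost[i] += b.prob * b.cost
            for k, v in ev.items():
                events[k][i] = v
    return ScreeningOperator(S, cost, events)
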