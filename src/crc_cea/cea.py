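"""ICERs, dominance, the efficiency frontier and optimal-strategy ranges.

A strategy is (strictly) dominated when a competitor is at least as
effective and no more costly (one strictly); it is extended-dominated when
it breaks the strictly-increasing ICER ladder along the
effectiveness-sorted chain of non-dominated strategies, i.e. a convex
combination of its neighbours buys effectiveness more cheaply.  The
surviving chain is the efficiency frontier; the ceiling ratio intervals on
which each frontier strategy is optimal are delimited by consecutive
frontier ICERs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Union

import math

import pandas as pd

from .engine import StrategyOutcome

#: Quadrant flags returned by :func:`icer` instead of a ratio.
DOMINATED = "dominated"
COST_SAVING = "cost_saving"
DOMINANCE_REVERSED = "dominance_reversed"
UNDEFINED = "undefined"
EQUIVALENT = "equivalent"

FRONTIER = "frontier"
EXTENDED_DOMINATED = "extended_dominated"

IcerValue = Union[float, Fraction, str]


def round_half_away(x, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables,
    unlike banker's rounding).  Exact for Fraction inputs."""
    if isinstance(x, Fraction):
        scaled = x * 10**ndigits
        q, r = divmod(abs(scaled.numerator), scaled.denominator)
        magnitude = q + (1 if 2 * r >= scaled.denominator else 0)
        return math.copysign(magnitude, scaled) / 10**ndigits
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def icer(
    a: StrategyOutcome,
    b: StrategyOutcome,
    measure: str = "qaly",
    exact: bool = False,
) -> IcerValue:
    """Incremental cost-effectiveness ratio of ``b`` versus ``a`` (the less
    effective comparator): (cost_b - cost_a) / (eff_b - eff_a).

    Returns a ratio when ``b`` buys extra effectiveness at extra cost, and
    a quadrant flag otherwise: ``dominated`` (b less effective, more
    costly), ``cost_saving`` (more effective, no more costly),
    ``dominance_reversed`` (less effective but cheaper), ``undefined``
    (equal effectiveness, different cost) or ``equivalent``.

    With ``exact`` the ratio is computed in exact rational arithmetic on
    the decimal string representations of the inputs, as needed when
    reproducing ratios from printed, rounded incremental columns.
    """
    if exact:
        dc = Fraction(str(b.cost_per_person)) - Fraction(str(a.cost_per_person))
        de = Fraction(str(b.effect(measure))) - Fraction(str(a.effect(measure)))
    else:
        dc = b.cost_per_person - a.cost_per_person
        de = b.effect(measure) - a.effect(measure)
    if de == 0:
        return EQUIVALENT if dc == 0 else UNDEFINED
    if de > 0:
        if dc > 0:
            return dc / de if exact else float(dc / de)
        return COST_SAVING
    return DOMINATED if dc > 0 else DOMINANCE_REVERSED


def net_monetary_benefit(o: StrategyOutcome, lam: float, measure: str = "qaly") -> float:
    return lam * o.effect(measure) - o.cost_per_person


@dataclass
class CEAResult:
    """Dominance labels, efficiency frontier and optimal ceiling-ratio
    ranges for one effectiveness measure."""

    measure: str
    ordered: list  # StrategyOutcome, ascending effectiveness
    labels: dict  # strategy name -> frontier | dominated | extended_dominated
    frontier: list  # strategy names along the frontier, ascending effectiveness
    frontier_icers: list  # incremental ICERs between consecutive frontier points
    optimal_ranges: list = field(default_factory=list)  # (lambda_low, lambda_high, name)
    icer_matrix: Optional[pd.DataFrame] = None

    def outcome(self, name: str) -> StrategyOutcome:
        for o in self.ordered:
            if o.strategy == name:
                return o
        raise KeyError(name)


def _strictly_dominated(outcomes: list, measure: str) -> set:
    flagged = set()
    for i, a in enumerate(outcomes):
        for j, b in enumerate(outcomes):
            if i == j:
                continue
            better_eff = b.effect(measure) >= a.effect(measure)
            cheaper = b.cost_per_person <= a.cost_per_person
            strict = (b.effect(measure) > a.effect(measure)
                      or b.cost_per_person < a.cost_per_person)
            if better_eff and cheaper and strict:
                flagged.add(a.strategy)
                break
            # Exact tie in both dimensions: collapse to the first by input order.
            if (j < i and b.effect(measure) == a.effect(measure)
                    and b.cost_per_person == a.cost_per_person):
                flagged.add(a.strategy)
                break
    return flagged


def dominance_analysis(
    outcomes: list, measure: str = "qaly"
) -> CEAResult:
    """Label every strategy, build the efficiency frontier and the optimal
    ceiling-ratio partition.

    Requires at least two strategies unless called with one (whose frontier
    is then itself).
    """
    if not outcomes:
        raise ValueError("no strategy outcomes supplied")
    ordered = sorted(outcomes, key=lambda o: (o.effect(measure), o.cost_per_person))
    labels = {o.strategy: FRONTIER for o in ordered}
    for name in _strictly_dominated(list(outcomes), measure):
        labels[name] = DOMINATED

    chain = [o for o in ordered if labels[o.strategy] == FRONTIER]
    # Iteratively drop strategies that break the increasing-ICER ladder.
    changed = True
    while changed and len(chain) >= 3:
        changed = False
        icers = [icer(chain[i], chain[i + 1], measure) for i in range(len(chain) - 1)]
        for i in range(len(icers) - 1):
            if not (isinstance(icers[i], float) and isinstance(icers[i + 1], float)):
                continue
            if icers[i] >= icers[i + 1]:
                labels[chain[i + 1].strategy] = EXTENDED_DOMINATED
                del chain[i + 1]
                changed = True
                break

    frontier = [o.strategy for o in chain]
    frontier_icers = [float(icer(chain[i], chain[i + 1], measure))
                      for i in range(len(chain) - 1)]

    ranges = []
    bounds = [0.0] + frontier_icers + [math.inf]
    for i, name in enumerate(frontier):
        ranges.append((bounds[i], bounds[i + 1], name))

    matrix = pd.DataFrame(index=[o.strategy for o in ordered[:-1]],
                          columns=[o.strategy for o in ordered[1:]], dtype=object)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            matrix.loc[a.strategy, b.strategy] = icer(a, b, measure)

    return CEAResult(
        measure=measure, ordered=ordered, labels=labels, frontier=frontier,
        frontier_icers=frontier_icers, optimal_ranges=ranges, icer_matrix=matrix,
    )


def optimal_strategy(result: CEAResult, lam: float) -> str:
    """The frontier strategy whose incremental ICER is the largest value
    not exceeding the ceiling ratio ``lam``; below the first frontier ICER
    this is the least effective frontier strategy (no screening)."""
    if lam < 0:
        raise ValueError("ceiling ratio must be >= 0")
    idx = sum(1 for r in result.frontier_icers if r <= lam)
    return result.frontier[idx]
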