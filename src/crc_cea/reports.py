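"""Report writers: outcome, ICER-matrix, optimal-range and CEAC tables,
plus the run manifest that makes every output traceable to its inputs.

Monetary columns are rounded half-away-from-zero to whole dollars and
LY/QALY columns to four decimals, the convention of published
cost-effectiveness tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cea import CEAResult, round_half_away
from .engine import StrategyOutcome
from .params import ModelParameters, dumps_parameters

BASELINE = "no_screening"

TABLE1_COLUMNS = [
    "strategy",
    "cost_per_person",
    "incremental_cost",
    "expected_lys",
    "incremental_lys",
    "expected_qalys",
    "incremental_qalys",
]


def render_table1(
    outcomes: list,
    baseline: str = BASELINE,
    sort_measure: str = "qaly",
) -> pd.DataFrame:
    """Per-strategy cost/LY/QALY table with increments versus no screening,
    sorted by ascending effectiveness.

    Raises ``ValueError`` when the no-screening comparator is absent.
    """
    by_name = {o.strategy: o for o in outcomes}
    if baseline not in by_name:
        raise ValueError(f"missing comparator {baseline!r}")
    ref = by_name[baseline]
    ordered = sorted(outcomes, key=lambda o: (o.effect(sort_measure), o.cost_per_person))
    rows = []
    for o in ordered:
        is_ref = o.strategy == baseline
        rows.append({
            "strategy": o.strategy,
            "cost_per_person": round_half_away(o.cost_per_person),
            "incremental_cost": "" if is_ref
            else round_half_away(o.cost_per_person - ref.cost_per_person),
            "expected_lys": round_half_away(o.ly_per_person, 4),
            "incremental_lys": "" if is_ref
            else round_half_away(o.ly_per_person - ref.ly_per_person, 4),
            "expected_qalys": round_half_away(o.qaly_per_person, 4),
            "incremental_qalys": "" if is_ref
            else round_half_away(o.qaly_per_person - ref.qaly_per_person, 4),
        })
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS)


def render_icer_matrix(result: CEAResult) -> pd.DataFrame:
    """Pairwise ICER matrix with dominance annotations (printed-table
    style: whole dollars, flags spelled out)."""
    matrix = result.icer_matrix.copy()

    def fmt(x):
        if isinstance(x, float):
            return round_half_away(x)
        return x if isinstance(x, str) else ""

    out = matrix.map(fmt)
    out.insert(0, "dominance", [result.labels[i] for i in matrix.index])
    out.index.name = "strategy"
    return out


def render_optimal_ranges(result: CEAResult) -> pd.DataFrame:
    """Ceiling-ratio partition, printed-interval convention: the first
    range closed, later ranges half-open (low, high]."""
    rows = []
    for i, (low, high, name) in enumerate(result.optimal_ranges):
        low_txt = f"[{int(round_half_away(low))}" if i == 0 else f"({int(round_half_away(low))}"
        high_txt = "+inf)" if math.isinf(high) else f"{int(round_half_away(high))}]"
        rows.append({
            "measure": result.measure,
            "lambda_low": low,
            "lambda_high": high,
            "interval": f"{low_txt}, {high_txt}",
            "optimal_strategy": name,
        })
    return pd.DataFrame(rows)


def build_manifest(
    params: ModelParameters,
    seed: Optional[int] = None,
    command: str = "",
    settings: Optional[dict] = None,
) -> dict:
    """Run record: parameter digest, seed, version, timestamp, settings."""
    doc = dumps_parameters(params)
    return {
        "parameter_digest": hashlib.sha256(doc.encode()).hexdigest(),
        "strategies": [s.name for s in params.strategies],
        "seed": seed,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "command": command,
        "settings": settings or {},
    }


def write_manifest(manifest: dict, out_dir: Path) -> Path:
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
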