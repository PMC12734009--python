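"""Scenario-table CSV and JSONL event/action stream I/O.

Scenario CSVs mirror the published column layout (KTemp, DDO, MTemp, MDO,
Scost, Dcost, Sprofit, Dprofit) plus the output-input ratio Dn, with RMB
amounts printed half-up at 2 decimals so generated files diff cleanly
against the packaged reference tables.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._common import round_half_up
from .strategy_optimizer import ScenarioResult

__all__ = ["scenario_frame", "write_scenario_csv", "write_jsonl", "read_jsonl", "round_half_up"]

SCENARIO_COLUMNS = [
    "plan", "ambient_T", "current_DO", "target_T", "target_DO",
    "cost_exp", "cost_ctl", "profit_exp", "profit_ctl", "ratio",
]


def scenario_frame(results: Sequence[ScenarioResult], baseline: ScenarioResult | None = None) -> pd.DataFrame:
    """Sweep rows (plus the fixed-set-point baseline columns) as a DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "plan": r.plan_id,
                "ambient_T": r.ambient_T,
                "current_DO": r.current_DO,
                "target_T": r.target_T,
                "target_DO": r.target_DO,
                "cost_exp": round_half_up(r.control_cost),
                "cost_ctl": round_half_up(baseline.control_cost) if baseline else math.nan,
                "profit_exp": round_half_up(r.profit),
                "profit_ctl": round_half_up(baseline.profit) if baseline else math.nan,
                "ratio": round_half_up(r.ratio) if r.ratio_defined else math.nan,
            }
        )
    frame = pd.DataFrame(rows, columns=SCENARIO_COLUMNS)
    if not frame.empty:
        for col in ("plan", "ambient_T", "current_DO", "target_T", "target_DO"):
            if (frame[col] == frame[col].round()).all():
                frame[col] = frame[col].astype(int)
    return frame


def write_scenario_csv(
    results: Sequence[ScenarioResult],
    path: str | Path,
    baseline: ScenarioResult | None = None,
) -> Path:
    """Write a sweep as CSV (header-only file for an empty result list)."""
    path = Path(path)
    frame = scenario_frame(results, baseline)
    frame.to_csv(path, index=False, float_format="%.2f")
    return path


def write_jsonl(records: Iterable[dict], path: str | Path) -> Path:
    """One JSON object per line; records round-trip exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def read_jsonl(path: str | Path) -> list[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]
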