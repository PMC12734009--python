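"""Loaders for the packaged reference tables.

The package ships small CSV transcriptions of the published calibration and
validation tables for the 8000 kg container system (see ``data/README.md``).
These are the inputs for value-model calibration, optimizer diffing, and the
published composite stress-score model.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

AMBIENTS = (2, 8, 14)


def _read(name: str) -> pd.DataFrame:
    with resources.files("rasctl.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def scenario_table(ambient: int) -> pd.DataFrame:
    """Published scenario sweep for one ambient temperature (2, 8 or 14 °C).

    Columns: plan, ambient_T, current_DO, target_T, target_DO,
    cost_exp, cost_ctl, profit_exp, profit_ctl (RMB per cycle).
    """
    if ambient not in AMBIENTS:
        raise ValueError(f"no packaged scenario table for ambient {ambient!r} °C; have {AMBIENTS}")
    return _read(f"scenario_ambient{ambient}.csv")


def detection_table() -> pd.DataFrame:
    """Per-behavior detector metrics (AP/P/R/F1, percent)."""
    return _read("detection_metrics.csv")


def pca_eigenvalue_table() -> pd.DataFrame:
    """Correlation-matrix PCA eigenvalues of the five serum indicators."""
    return _read("pca_eigenvalues.csv")


def pca_loading_table() -> pd.DataFrame:
    """Component loading matrix (indicator x component)."""
    return _read("pca_loadings.csv")


def value_calibration_rows(anchor_targets: tuple[int, int] = (10, 20)) -> list[tuple[float, float, float]]:
    """Anchor rows (target_T, cost, profit) used to calibrate the cycle-value model.

    Defaults to the ambient-8 sweep rows at 10 and 20 °C, which span the
    sweep's growth-rate range.
    """
    tab = scenario_table(8)
    rows = []
    for t in anchor_targets:
        row = tab[tab.target_T == t]
        if row.empty:
            raise ValueError(f"no anchor row at target_T={t}")
        rows.append((float(t), float(row.cost_exp.iloc[0]), float(row.profit_exp.iloc[0])))
    return rows
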