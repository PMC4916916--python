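"""Prevalence sweeps: test performance as a function of true prevalence.

Two mechanisms change the true prevalence while the threshold stays put:

* ``shift-mean`` — slide the mean of a single normal trait distribution
  (different settings along a referral pathway);
* ``mixture-weight`` — reweight a well-separated bimodal trait
  (different case mixes / severity spectra).

Each sweep row evaluates the same measurement-error model at one
prevalence, either analytically (exact, deterministic) or by simulation.
With the shift-mean mechanism, lowering prevalence pushes the bulk of the
population toward the threshold from below, so specificity and both
likelihood ratios rise while sensitivity falls; with the mixture-weight
mechanism, raising prevalence moves mass into the far "diseased" mode, so
sensitivity rises and LR- falls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .measurement import (
    MeasurementModel,
    analytic_test_performance,
    simulate_test_performance,
)
from .population import (
    DEFAULT_THRESHOLD,
    SCENARIO2_HIGH,
    SCENARIO2_LOW,
    scenario1_model,
    scenario2_model,
)

__all__ = [
    "DEFAULT_PREV_GRID",
    "SWEEP_COLUMNS",
    "sweep_scenario1",
    "sweep_scenario2",
    "summarize_sweep",
]

#: 49 equally spaced prevalences spanning 2%..50%, the illustrated range.
DEFAULT_PREV_GRID = np.linspace(0.02, 0.50, 49)

SWEEP_COLUMNS = [
    "prevalence",
    "sensitivity",
    "specificity",
    "lr_pos",
    "lr_neg",
    "ppv",
    "npv",
    "scenario",
    "model_param",
]


def _check_grid(prev_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(prev_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("prevalence grid must be a non-empty 1-d sequence")
    if not ((grid > 0.0) & (grid < 1.0)).all():
        raise ValueError("grid prevalences must lie strictly inside (0, 1)")
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid prevalences must be strictly increasing")
    return grid


def _run_sweep(
    grid: np.ndarray,
    build_model,
    param_of,
    scenario: str,
    mm: MeasurementModel,
    mode: str,
    n: int | None,
    seed: int | None,
) -> pd.DataFrame:
    if mode not in ("analytic", "simulate"):
        raise ValueError(f"mode must be 'analytic' or 'simulate', got {mode!r}")
    if mode == "simulate":
        if n is None or seed is None:
            raise ValueError("simulate mode requires both n and seed")
        row_seeds = np.random.SeedSequence(seed).generate_state(len(grid))
    rows = []
    for i, p in enumerate(grid):
        try:
            model = build_model(p)
            if mode == "analytic":
                perf = analytic_test_performance(model, mm)
            else:
                perf = simulate_test_performance(model, mm, n, int(row_seeds[i]))
        except ValueError as exc:
            raise ValueError(f"grid point prevalence={p}: {exc}") from exc
        row = perf.as_dict()
        row["prevalence"] = float(p)  # target prevalence labels the row
        row["scenario"] = scenario
        row["model_param"] = param_of(model)
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def sweep_scenario1(
    prev_grid: np.ndarray = DEFAULT_PREV_GRID,
    sd: float = 1.0,
    mm: MeasurementModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "analytic",
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Shift-mean sweep; ``model_param`` echoes the trait mean per row."""
    grid = _check_grid(prev_grid)
    mm = MeasurementModel(error_sd=0.0) if mm is None else mm
    return _run_sweep(
        grid,
        lambda p: scenario1_model(p, sd=sd, threshold=threshold),
        lambda m: m.components[0].mean,
        "shift-mean",
        mm,
        mode,
        n,
        seed,
    )


def sweep_scenario2(
    prev_grid: np.ndarray = DEFAULT_PREV_GRID,
    low_component: tuple[float, float] = SCENARIO2_LOW,
    high_component: tuple[float, float] = SCENARIO2_HIGH,
    mm: MeasurementModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "analytic",
    n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mixture-weight sweep; ``model_param`` echoes the high-mode weight."""
    grid = _check_grid(prev_grid)
    mm = MeasurementModel(error_sd=0.0) if mm is None else mm
    return _run_sweep(
        grid,
        lambda p: scenario2_model(p, low_component, high_component, threshold),
        lambda m: m.components[1].weight,
        "mixture-weight",
        mm,
        mode,
        n,
        seed,
    )


def summarize_sweep(table: pd.DataFrame) -> dict[str, float]:
    """Range summary of a sweep: metric extremes, likelihood-ratio fold
    changes, and sensitivity/specificity ranges in percentage points.

    The negative likelihood ratio is summarized through its inverse
    (1/LR-), matching how an LR- that shrinks with prevalence is usually
    displayed.
    """
    if table.empty:
        raise ValueError("sweep table is empty")
    out: dict[str, float] = {}
    for col in ("sensitivity", "specificity", "lr_pos", "lr_neg", "ppv", "npv"):
        out[f"{col}_min"] = float(table[col].min())
        out[f"{col}_max"] = float(table[col].max())
    out["lr_pos_fold_change"] = out["lr_pos_max"] / out["lr_pos_min"]
    inv_lr_neg = 1.0 / table["lr_neg"]
    out["inv_lr_neg_fold_change"] = float(inv_lr_neg.max() / inv_lr_neg.min())
    out["sensitivity_range_pp"] = 100.0 * (out["sensitivity_max"] - out["sensitivity_min"])
    out["specificity_range_pp"] = 100.0 * (out["specificity_max"] - out["specificity_min"])
    return out
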