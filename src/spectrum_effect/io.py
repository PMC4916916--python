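"""Plain-text IO: cohort and sweep CSVs, YAML configuration.

Internal values are written at full float precision (shortest round-trip
repr); display rounding belongs to the presentation layer only.  Cohort
CSVs use the documented column order x, z, disease, test, stratum,
then covariates, omitting optional columns that are absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CORE_COLUMNS, Cohort
from .measurement import MeasurementModel
from .population import PopulationModel, scenario1_model, scenario2_model
from .simulate import CovariateEffect, LogitTestModel, ScenarioConfig

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_sweep_csv",
    "write_sweep_csv",
    "load_config",
    "scenario_config_from_dict",
]


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    df = cohort.data
    cols = [c for c in CORE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in CORE_COLUMNS]
    df[cols].to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
    design: str = "cross-sectional",
    test_threshold: float | None = None,
) -> Cohort:
    """Read a cohort table; numeric validation reports the offending row.

    ``test`` may be derived from ``z`` when a ``test_threshold`` is given;
    otherwise both ``disease`` and ``test`` must be present.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"disease"}
    if "test" not in df.columns and test_threshold is None:
        needed.add("test (or z plus a test_threshold)")
    missing = sorted(c for c in needed if c.split()[0] not in df.columns)
    if missing:
        raise ValueError(f"cohort file {path} is missing mandatory columns: {missing}")
    for col in ("x", "z"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"unparseable value {df[col].iloc[row]!r} in column {col!r} "
                    f"at data row {row}"
                )
            df[col] = coerced
    if "test" not in df.columns:
        df["test"] = (df["z"] >= test_threshold).astype(int)
    return Cohort(data=df, design=design, provenance={"source": str(path)})


def write_sweep_csv(table: pd.DataFrame, path: str | Path) -> None:
    if table.empty:
        raise ValueError("refusing to write an empty sweep table")
    table.to_csv(path, index=False)


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    return cfg


def _population_from_dict(d: dict) -> PopulationModel:
    if "prevalence" in d:
        scenario = d.get("scenario", "scenario1")
        if scenario == "scenario1":
            return scenario1_model(
                d["prevalence"], sd=d.get("sd", 1.0), threshold=d.get("threshold", 7.0)
            )
        if scenario == "scenario2":
            return scenario2_model(
                d["prevalence"],
                low_component=tuple(d.get("low_component", (4.0, 1.0))),
                high_component=tuple(d.get("high_component", (9.0, 1.0))),
                threshold=d.get("threshold", 7.0),
            )
        raise ValueError(f"unknown population scenario {scenario!r}")
    return PopulationModel.mixture(
        [tuple(c) for c in d["components"]], threshold=d["threshold"]
    )


def scenario_config_from_dict(cfg: dict, seed: int | None = None) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a parsed YAML ``scenario:`` block."""
    block = cfg.get("scenario", cfg)
    mm_block = block.get("measurement", {})
    mm = MeasurementModel(
        error_sd=mm_block.get("error_sd", 0.0), bias=mm_block.get("bias", 0.0)
    )
    effects = {
        name: CovariateEffect(on=spec["on"], coef=spec["coef"])
        for name, spec in block.get("covariate_effects", {}).items()
    }
    logit_test = None
    if "logit_test" in block:
        lt = block["logit_test"]
        logit_test = LogitTestModel(
            intercept_diseased=lt["intercept_diseased"],
            intercept_nondiseased=lt["intercept_nondiseased"],
            coefs_diseased=dict(lt.get("coefs_diseased", {})),
            coefs_nondiseased=dict(lt.get("coefs_nondiseased", {})),
        )
    kind = block.get("design", "cross-sectional")
    use_seed = seed if seed is not None else block.get("seed", 0)
    if kind == "case-control":
        return ScenarioConfig(
            scenario="case-control",
            measurement=mm,
            seed=use_seed,
            n_cases=block["n_cases"],
            n_controls=block["n_controls"],
            case_model=_population_from_dict(block["case_population"]),
            control_model=_population_from_dict(block["control_population"]),
        )
    return ScenarioConfig(
        scenario=block.get("name", "custom"),
        measurement=mm,
        seed=use_seed,
        population=_population_from_dict(block["population"]),
        n=block["n"],
        covariate_effects=effects,
        logit_test=logit_test,
    )
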