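"""Individual-level cohort container shared by the generator, IO and
subgroup analysis.

A cohort is a tidy table with one row per individual.  Recognised columns:

* ``x``       — latent trait value (simulation only; optional)
* ``z``       — observed score (optional if ``test`` present)
* ``disease`` — true disease status, 0/1 (required)
* ``test``    — dichotomised test result, 0/1 (required)
* ``stratum`` — categorical subgroup label (optional)

Any further columns are treated as named covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["Cohort", "CORE_COLUMNS", "combine_strata"]

CORE_COLUMNS = ("x", "z", "disease", "test", "stratum")


@dataclass
class Cohort:
    data: pd.DataFrame
    design: str = "cross-sectional"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("cross-sectional", "case-control"):
            raise ValueError(f"unknown design {self.design!r}")
        df = self.data
        if df.empty:
            raise ValueError("cohort must contain at least one record")
        missing = [c for c in ("disease", "test") if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing mandatory columns: {missing}")
        for col in ("disease", "test"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"column {col!r} must be binary; first offending row {row} "
                    f"has value {df[col].iloc[row]!r}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in CORE_COLUMNS]

    @property
    def n_diseased(self) -> int:
        return int(self.data["disease"].sum())

    @property
    def n_nondiseased(self) -> int:
        return len(self.data) - self.n_diseased

    def empirical_prevalence(self) -> float:
        return self.n_diseased / len(self.data)


def combine_strata(strata: Mapping[str, Cohort]) -> Cohort:
    """Stack labelled cohorts into one stratified cohort.

    Each input cohort gets (or overwrites) a ``stratum`` column with its
    label; designs must agree.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    designs = {c.design for c in strata.values()}
    if len(designs) > 1:
        raise ValueError(f"cannot combine cohorts of mixed designs {sorted(designs)}")
    frames = []
    for label, cohort in strata.items():
        df = cohort.data.copy()
        df["stratum"] = label
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    return Cohort(
        data=combined,
        design=designs.pop(),
        provenance={label: c.provenance for label, c in strata.items()},
    )
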