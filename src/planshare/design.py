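"""Design matrices for the two-part model and the outcome generator.

One dummy-coding convention is shared by the generator and the estimator so
that planted coefficients and recovered coefficients live on identical
columns: ``intercept``, ``plan:<type>`` (reference = lowest-cost-sharing
type), ``race:<level>`` (reference White), ``age:<group>`` (reference 40-64),
``cci:<category>`` (reference 0) and ``region:<level>`` (reference = first
level in sorted order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["DesignSpec", "build_design", "build_design_from_betas"]

OUTCOMES = ("all_imaging", "diagnostic_mammo", "ultrasound", "mri", "biopsy")

_FACTORS = (
    ("plan", "plan_type"),
    ("race", "race_ethnicity"),
    ("age", "age_group"),
    ("cci", "cci_category"),
    ("region", "region"),
)


@dataclass(frozen=True)
class DesignSpec:
    """Which outcome to model and which factor levels act as references."""

    outcome: str = "all_imaging"
    plan_ref: str = "coinsurance"
    race_ref: str = "White"
    age_ref: str = "40-64"
    cci_ref: str = "0"
    region_ref: str | None = None  # None = first region level in sorted order
    include_region: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise InvalidInputError(f"unknown outcome {self.outcome!r}")

    def references(self, data: pd.DataFrame) -> dict[str, str]:
        refs = {
            "plan": self.plan_ref,
            "race": self.race_ref,
            "age": self.age_ref,
            "cci": self.cci_ref,
        }
        if self.include_region:
            region_ref = self.region_ref
            if region_ref is None:
                region_ref = sorted(data["region"].astype(str).unique())[0]
            refs["region"] = region_ref
        return refs

    def outcome_column(self) -> str:
        return "n_services" if self.outcome == "all_imaging" else f"n_{self.outcome}"


def _dummies(data: pd.DataFrame, prefix: str, column: str, ref: str):
    levels = sorted(data[column].astype(str).unique())
    if ref in levels:
        levels.remove(ref)
    cols = {}
    vals = data[column].astype(str).to_numpy()
    for lv in levels:
        cols[f"{prefix}:{lv}"] = (vals == lv).astype(float)
    return cols


def build_design(data: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with intercept; raises if rank deficient."""
    refs = spec.references(data)
    names = ["intercept"]
    arrays = [np.ones(len(data))]
    for prefix, column in _FACTORS:
        if prefix == "region" and not spec.include_region:
            continue
        if column not in data.columns:
            raise InvalidInputError(f"covariate column {column!r} missing")
        for name, col in _dummies(data, prefix, column, refs[prefix]).items():
            names.append(name)
            arrays.append(col)
    X = np.column_stack(arrays)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidInputError("design matrix is rank deficient")
    return X, names


def build_design_from_betas(
    data: pd.DataFrame, betas: dict[str, float], plan_ref: str
) -> tuple[np.ndarray, list[str]]:
    """Design used by the outcome generator.

    Includes every non-reference level present in the data so that
    coefficients named in ``betas`` always find their column; unnamed
    columns simply act with coefficient zero.
    """
    spec = DesignSpec(plan_ref=plan_ref, include_region="region" in data.columns)
    return build_design(data, spec)
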