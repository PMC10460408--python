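"""Counterfactual engine: flip a dichotomized subgroup variable, compute Z.

For each subject the fitted outcome model yields a probability on the row
as observed and on a "virtual twin" row identical except that the subgroup
variable (e.g. "attended one or more self-help groups") is switched to its
opposite.  The pair is oriented by the subject's actual arm so that

    z_i = p1_i - p0_i,

with p1 the probability under the active state and p0 under the inactive
state, for every subject regardless of which arm was observed.  Z becomes
the regression target of the stage-2 subgroup tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CohortTable, SchemaError, ValidationError
from .stage1 import FittedOutcomeModel

__all__ = ["CounterfactualResult", "flip_variable", "flip_table", "compute_z"]


@dataclass
class CounterfactualResult:
    """Per-subject (p1, p0, z) for one subgroup variable."""

    subgroup_variable: str
    p1: np.ndarray
    p0: np.ndarray
    observed_arm: np.ndarray
    model_tag: str

    @property
    def z(self) -> np.ndarray:
        return self.p1 - self.p0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_arm": self.observed_arm.astype(int),
                "p1": self.p1,
                "p0": self.p0,
                "z": self.z,
            }
        )


def _check_binary(values: np.ndarray, variable: str) -> None:
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValidationError(
            f"variable {variable!r} must be dichotomized to {{0,1}} before flipping"
        )


def flip_variable(row: pd.Series, variable: str) -> pd.Series:
    """Return a copy of ``row`` with the binary ``variable`` switched to 1 - value."""
    if variable not in row.index:
        raise SchemaError(f"variable {variable!r} absent from row")
    val = float(row[variable])
    _check_binary(np.array([val]), variable)
    out = row.copy()
    out[variable] = 1.0 - val
    return out


def flip_table(table: CohortTable, variable: str) -> CohortTable:
    """Whole-table counterpart of :func:`flip_variable`; input unmodified."""
    spec = table.schema[variable]
    if spec.vtype != "binary":
        raise ValidationError(f"variable {variable!r} is {spec.vtype}, not binary")
    vals = table.df[variable].to_numpy(dtype=float)
    _check_binary(vals, variable)
    df = table.df.copy()
    df[variable] = 1.0 - vals
    return CohortTable(df, table.schema, validate=False)


def compute_z(
    model: FittedOutcomeModel,
    table: CohortTable,
    variable: str,
) -> CounterfactualResult:
    """Compute the per-subject counterfactual probability difference.

    The model predicts once on the table as observed and once with the
    subgroup variable flipped for every row; each subject's (p1, p0) is then
    assembled from their observed arm, so subjects observed active
    contribute their plain prediction as p1, and subjects observed inactive
    contribute it as p0.
    """
    if variable not in model.training_schema:
        raise SchemaError(f"model was not trained with variable {variable!r}")
    arm = table.df[variable].to_numpy(dtype=float)
    _check_binary(arm, variable)
    p_obs = model.predict_proba(table)
    p_cf = model.predict_proba(flip_table(table, variable))
    p1 = np.where(arm == 1.0, p_obs, p_cf)
    p0 = np.where(arm == 1.0, p_cf, p_obs)
    return CounterfactualResult(
        subgroup_variable=variable,
        p1=p1,
        p0=p0,
        observed_arm=arm,
        model_tag=f"{model.spec.family}:{model.target}",
    )
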