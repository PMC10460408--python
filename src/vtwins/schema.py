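"""Cohort data model: variable specs, validated tables, target encodings.

A cohort is a flat table of mixed-type clinical/social predictors plus
binary outcome targets.  Every column is declared by a :class:`VariableSpec`
(role, type, levels), and :class:`CohortTable` couples a pandas DataFrame to
such a schema with validation on construction.  The module also implements
the two study-specific encodings: dichotomization of a length-of-stay count
at 90 days and mapping of discharge codes to a success indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "CohortSchema",
    "CohortTable",
    "TargetEncoding",
    "SchemaError",
    "ValidationError",
    "DEFAULT_DISCHARGE_CODES",
    "MISSING_LEVEL",
    "encode_targets",
    "dichotomize",
    "load_cohort",
    "write_cohort",
    "load_schema",
    "schema_to_dict",
]

ROLES = ("predictor", "target", "id")
VTYPES = ("binary", "categorical", "count", "continuous")

#: Explicit level assigned to missing categorical values.
MISSING_LEVEL = "Unknown"

#: Discharge code -> successful-completion indicator.  Only a clinician
#: approved discharge counts as success; leaving against medical advice or
#: any administrative exit (transfer to a higher-level facility, extended
#: incarceration) codes 0.
DEFAULT_DISCHARGE_CODES: Mapping[str, int] = {
    "completed": 1,
    "ama": 0,
    "administrative": 0,
    "incarcerated": 0,
    "transferred": 0,
}


class SchemaError(ValueError):
    """A schema is internally inconsistent or does not match the data header."""


class ValidationError(ValueError):
    """A data value violates its declared VariableSpec."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single cohort column.

    Parameters
    ----------
    name:
        Column identifier; unique within a schema.
    role:
        One of ``predictor``, ``target``, ``id``.
    vtype:
        One of ``binary``, ``categorical``, ``count``, ``continuous``.
    levels:
        Category labels; required iff ``vtype == "categorical"``.
    dichotomize_at:
        Optional threshold for count/continuous variables; the variable's
        "active" state is ``value > dichotomize_at``.
    """

    name: str
    role: str
    vtype: str
    levels: tuple[str, ...] | None = None
    dichotomize_at: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.vtype not in VTYPES:
            raise SchemaError(f"unknown vtype {self.vtype!r} for variable {self.name!r}")
        if (self.vtype == "categorical") != (self.levels is not None):
            raise SchemaError(
                f"variable {self.name!r}: levels must be present iff vtype is categorical"
            )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"variable {self.name!r}: duplicate levels")
        if self.dichotomize_at is not None and self.vtype not in ("count", "continuous"):
            raise SchemaError(
                f"variable {self.name!r}: dichotomize_at only valid for count/continuous"
            )

    @property
    def is_numeric(self) -> bool:
        return self.vtype in ("binary", "count", "continuous")

    @property
    def active_threshold(self) -> float:
        """Threshold defining the variable's dichotomous "active" state."""
        if self.vtype == "binary":
            return 0.0
        if self.dichotomize_at is not None:
            return float(self.dichotomize_at)
        if self.vtype in ("count", "continuous"):
            return 0.0
        raise SchemaError(f"variable {self.name!r} has no dichotomous interpretation")


class CohortSchema:
    """Ordered collection of :class:`VariableSpec` with unique names."""

    def __init__(self, variables: Iterable[VariableSpec]):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names in schema: {dup}")
        self._by_name = {v.name: v for v in self.variables}

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"variable {name!r} not in schema") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortSchema) and self.variables == other.variables

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def predictors(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "predictor"]

    def targets(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.role == "target"]

    def replace_variable(self, name: str, new: VariableSpec) -> "CohortSchema":
        return CohortSchema(new if v.name == name else v for v in self.variables)


@dataclass(frozen=True)
class TargetEncoding:
    """The study's two binary success outcomes for one client."""

    los_gt90: int
    completed: int


def encode_targets(
    raw_los_days: int,
    raw_discharge: str,
    discharge_codes: Mapping[str, int] = DEFAULT_DISCHARGE_CODES,
) -> TargetEncoding:
    """Encode raw length-of-stay and discharge code as the two binary targets.

    ``los_gt90`` is 1 iff the stay strictly exceeds 90 days (90 itself codes
    0).  ``completed`` is 1 iff the discharge code maps to clinician-approved
    completion under ``discharge_codes``.
    """
    if raw_los_days < 0:
        raise ValidationError(f"length of stay must be non-negative, got {raw_los_days}")
    code = str(raw_discharge)
    if code not in discharge_codes:
        raise ValidationError(
            f"unknown discharge code {code!r}; known codes: {sorted(discharge_codes)}"
        )
    return TargetEncoding(
        los_gt90=int(raw_los_days > 90),
        completed=int(discharge_codes[code]),
    )


class CohortTable:
    """A validated cohort: pandas DataFrame + :class:`CohortSchema`.

    Construction validates every value against its spec: binary in {0,1},
    counts non-negative integers, categorical values within declared levels
    (missing categorical values become the explicit ``"Unknown"`` level),
    targets never missing.  Numeric predictors may be missing (NaN); model
    encoders impute them from training data only.
    """

    def __init__(self, df: pd.DataFrame, schema: CohortSchema, validate: bool = True):
        if set(df.columns) != set(schema.names):
            unknown = sorted(set(df.columns) - set(schema.names))
            missing = sorted(set(schema.names) - set(df.columns))
            raise SchemaError(
                f"columns do not match schema (unknown: {unknown}, missing: {missing})"
            )
        self.schema = schema
        self.df = df[schema.names].reset_index(drop=True)
        if validate:
            self._coerce_and_validate()

    # -- construction helpers -------------------------------------------------

    def _coerce_and_validate(self) -> None:
        df = self.df
        for spec in self.schema:
            col = df[spec.name]
            if spec.vtype == "categorical":
                vals = col.astype("object").where(~col.isna(), MISSING_LEVEL).astype(str)
                vals = vals.where(vals != "nan", MISSING_LEVEL)
                allowed = set(spec.levels) | {MISSING_LEVEL}
                bad = ~vals.isin(allowed)
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValidationError(
                        f"variable {spec.name!r}: value {vals.iloc[i]!r} at row {i} "
                        f"not in declared levels {list(spec.levels)}"
                    )
                df[spec.name] = vals
                continue
            vals = pd.to_numeric(col, errors="coerce")
            new_na = vals.isna() & ~col.isna()
            if new_na.any():
                i = int(np.flatnonzero(new_na.to_numpy())[0])
                raise ValidationError(
                    f"variable {spec.name!r}: non-numeric value {col.iloc[i]!r} at row {i}"
                )
            na = vals.isna()
            if na.any() and spec.role != "predictor":
                i = int(np.flatnonzero(na.to_numpy())[0])
                raise ValidationError(
                    f"variable {spec.name!r} (role {spec.role}): missing value at row {i}"
                )
            present = vals[~na]
            if spec.vtype == "binary":
                if not present.isin([0, 1]).all():
                    i = int(np.flatnonzero((~vals.isin([0, 1]) & ~na).to_numpy())[0])
                    raise ValidationError(
                        f"variable {spec.name!r}: binary value {vals.iloc[i]!r} at row {i} "
                        "not in {0, 1}"
                    )
            elif spec.vtype == "count":
                bad = (~na) & ((vals < 0) | (vals != np.floor(vals)))
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValidationError(
                        f"variable {spec.name!r}: count value {vals.iloc[i]!r} at row {i} "
                        "must be a non-negative integer"
                    )
            df[spec.name] = vals.astype(float)

    # -- basic protocol -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.schema, validate=False)

    def column(self, name: str) -> pd.Series:
        self.schema[name]  # raises SchemaError if absent
        return self.df[name]


def dichotomize(table: CohortTable, variable: str, threshold: float) -> CohortTable:
    """Return a copy of ``table`` with ``variable`` recoded as 1 iff value > threshold.

    The variable's spec becomes ``binary``; the input table is unmodified.
    Used to turn counts such as "self-help groups attended" into the 0 vs >0
    subgroup indicator the counterfactual flip operates on.
    """
    spec = table.schema[variable]
    if spec.vtype not in ("count", "continuous", "binary"):
        raise ValidationError(
            f"variable {variable!r} has vtype {spec.vtype!r}; dichotomize needs a numeric variable"
        )
    df = table.df.copy()
    vals = df[variable]
    if vals.isna().any():
        raise ValidationError(f"variable {variable!r} has missing values; impute before dichotomizing")
    df[variable] = (vals > threshold).astype(float)
    new_spec = VariableSpec(name=spec.name, role=spec.role, vtype="binary")
    return CohortTable(df, table.schema.replace_variable(variable, new_spec), validate=False)


# -- I/O ----------------------------------------------------------------------

def load_cohort(path: str | Path, schema: CohortSchema) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row mandatory) against ``schema``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype="object", keep_default_na=True)
    return CohortTable(df, schema)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; counts/binaries are written as integers."""
    out = table.df.copy()
    for spec in table.schema:
        if spec.vtype in ("binary", "count"):
            col = out[spec.name]
            mask = col.notna()
            out[spec.name] = col.astype("object")
            out.loc[mask, spec.name] = col[mask].astype(int)
    out.to_csv(path, index=False)


def _spec_from_dict(d: Mapping) -> VariableSpec:
    return VariableSpec(
        name=str(d["name"]),
        role=str(d.get("role", "predictor")),
        vtype=str(d["vtype"]),
        levels=tuple(d["levels"]) if d.get("levels") is not None else None,
        dichotomize_at=(float(d["dichotomize_at"]) if d.get("dichotomize_at") is not None else None),
    )


def load_schema(path: str | Path) -> tuple[CohortSchema, Mapping[str, int]]:
    """Load a YAML schema file: variable declarations + discharge-code map."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "variables" not in doc:
        raise SchemaError(f"schema file {path} lacks a 'variables' section")
    schema = CohortSchema(_spec_from_dict(d) for d in doc["variables"])
    codes = dict(doc.get("discharge_codes", DEFAULT_DISCHARGE_CODES))
    return schema, {str(k): int(v) for k, v in codes.items()}


def schema_to_dict(schema: CohortSchema, discharge_codes: Mapping[str, int] | None = None) -> dict:
    """Serializable form of a schema, suitable for ``yaml.safe_dump``."""
    doc: dict = {
        "variables": [
            {
                "name": v.name,
                "role": v.role,
                "vtype": v.vtype,
                **({"levels": list(v.levels)} if v.levels is not None else {}),
                **(
                    {"dichotomize_at": v.dichotomize_at}
                    if v.dichotomize_at is not None
                    else {}
                ),
            }
            for v in schema
        ]
    }
    if discharge_codes is not None:
        doc["discharge_codes"] = dict(discharge_codes)
    return doc
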