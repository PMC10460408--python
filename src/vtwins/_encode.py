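"""Deterministic model-matrix encoding of cohort tables.

Categorical predictors are one-hot encoded with a fixed, sorted level order
recorded at fit time (so counterfactual rows encode identically); numeric
predictors pass through, with missing values imputed by the fitting split's
median.  The encoder remembers which output columns belong to which schema
variable so that importance scores can be aggregated back to source
variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import MISSING_LEVEL, CohortTable, SchemaError


@dataclass
class CohortEncoder:
    """One-hot + median-imputation encoder fitted on (a subset of) a cohort."""

    feature_names_: list[str] = field(default_factory=list, init=False)
    groups_: dict[str, list[int]] = field(default_factory=dict, init=False)
    levels_: dict[str, list[str]] = field(default_factory=dict, init=False)
    medians_: dict[str, float] = field(default_factory=dict, init=False)
    predictors_: list[str] = field(default_factory=list, init=False)
    fitted_: bool = field(default=False, init=False)

    def fit(self, table: CohortTable, rows: np.ndarray | None = None) -> "CohortEncoder":
        """Learn level orders and imputation medians from ``rows`` of ``table``.

        ``rows`` defaults to all rows; pass the training-split indices to keep
        imputation leakage-free.
        """
        df = table.df if rows is None else table.df.iloc[rows]
        self.feature_names_ = []
        self.groups_ = {}
        self.levels_ = {}
        self.medians_ = {}
        self.predictors_ = [v.name for v in table.schema.predictors()]
        col = 0
        for spec in table.schema.predictors():
            if spec.vtype == "categorical":
                observed = set(df[spec.name].astype(str))
                levels = sorted(set(spec.levels) | (observed & {MISSING_LEVEL}))
                self.levels_[spec.name] = levels
                idx = []
                for lev in levels:
                    self.feature_names_.append(f"{spec.name}={lev}")
                    idx.append(col)
                    col += 1
                self.groups_[spec.name] = idx
            else:
                vals = pd.to_numeric(df[spec.name])
                med = float(np.nanmedian(vals)) if vals.notna().any() else 0.0
                self.medians_[spec.name] = med
                self.feature_names_.append(spec.name)
                self.groups_[spec.name] = [col]
                col += 1
        self.fitted_ = True
        return self

    def transform(self, table: CohortTable) -> np.ndarray:
        """Encode predictors of ``table`` to a dense float matrix."""
        if not self.fitted_:
            raise SchemaError("encoder not fitted")
        names = [v.name for v in table.schema.predictors()]
        if names != self.predictors_:
            raise SchemaError(
                "table predictors do not match the encoder's training schema"
            )
        n = table.n
        X = np.zeros((n, len(self.feature_names_)), dtype=float)
        for spec in table.schema.predictors():
            cols = self.groups_[spec.name]
            if spec.vtype == "categorical":
                vals = table.df[spec.name].astype(str).to_numpy()
                for j, lev in zip(cols, self.levels_[spec.name]):
                    X[:, j] = vals == lev
            else:
                vals = pd.to_numeric(table.df[spec.name]).to_numpy(dtype=float)
                vals = np.where(np.isnan(vals), self.medians_[spec.name], vals)
                X[:, cols[0]] = vals
        return X

    def fit_transform(self, table: CohortTable, rows: np.ndarray | None = None) -> np.ndarray:
        return self.fit(table, rows).transform(table)
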