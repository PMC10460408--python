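import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vtwins._encode import CohortEncoder
from vtwins.schema import CohortSchema, CohortTable, VariableSpec
from vtwins.stage1 import FittedOutcomeModel, ModelSpec


@pytest.fixture
def tiny_schema():
    return CohortSchema(
        [
            VariableSpec("race", "predictor", "categorical", ("Black", "White", "Other")),
            VariableSpec("snap", "predictor", "binary"),
            VariableSpec("goals", "predictor", "count", dichotomize_at=0.0),
            VariableSpec("los_gt90", "target", "binary"),
        ]
    )


@pytest.fixture
def tiny_table(tiny_schema):
    df = pd.DataFrame(
        {
            "race": ["Black", "White", "Black"],
            "snap": [1, 0, 1],
            "goals": [0, 2, 5],
            "los_gt90": [0, 1, 1],
        }
    )
    return CohortTable(df, tiny_schema)


class _AnalyticLogistic:
    """sklearn-like estimator computing an exact logistic form over encoded columns."""

    def __init__(self, encoder: CohortEncoder, coefs: dict, intercept: float):
        self.feature_names = encoder.feature_names_
        self.beta = np.zeros(len(self.feature_names))
        for name, c in coefs.items():
            self.beta[self.feature_names.index(name)] = c
        self.intercept = intercept

    def predict_proba(self, X):
        p = expit(self.intercept + X @ self.beta)
        return np.column_stack([1 - p, p])


def analytic_model(table: CohortTable, target: str, coefs: dict, intercept: float = 0.0):
    """A FittedOutcomeModel whose probabilities follow an exact logistic formula.

    ``coefs`` maps encoded feature names (e.g. "snap" or "race=Black") to
    log-odds coefficients; everything else gets coefficient zero.
    """
    encoder = CohortEncoder().fit(table)
    est = _AnalyticLogistic(encoder, coefs, intercept)
    return FittedOutcomeModel(
        spec=ModelSpec("logistic_regression"),
        target=target,
        estimator=est,
        encoder=encoder,
        training_schema=table.schema,
    )


def binary_cohort(n: int, names: list[str], target: str, seed: int) -> CohortTable:
    """Random all-binary cohort with an independent fair-coin target."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.integers(0, 2, n) for name in names})
    df[target] = rng.integers(0, 2, n)
    schema = CohortSchema(
        [VariableSpec(name, "predictor", "binary") for name in names]
        + [VariableSpec(target, "target", "binary")]
    )
    return CohortTable(df, schema)
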