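"""Benchmark generator configurations with known ground truth.

Small, fully-specified cohorts for scoring each pipeline stage against the
generator's closed form: a planted two-literal interaction for subgroup
recovery, a two-signal design for importance ranking, and a null design
(outcome independent of every predictor) for calibration checks.  These are
the package's own recovery benchmarks; the study-like default lives in
:func:`vtwins.simulate.paper_like_config`.
"""

from __future__ import annotations

from .schema import CohortSchema, VariableSpec
from .simulate import (
    Bernoulli,
    CohortGeneratorConfig,
    Literal,
    ModelTerm,
    OutcomeModel,
    PlantedEffect,
    ZeroInflatedPoisson,
)

__all__ = [
    "planted_interaction_config",
    "two_signal_config",
    "null_config",
]

_TARGET = "outcome"


def _schema(extra: list[VariableSpec], n_null_binary: int, n_null_count: int) -> CohortSchema:
    nulls: list[VariableSpec] = [
        VariableSpec(f"noise_b{i}", "predictor", "binary") for i in range(n_null_binary)
    ] + [
        VariableSpec(f"noise_c{i}", "predictor", "count") for i in range(n_null_count)
    ]
    return CohortSchema(extra + nulls + [VariableSpec(_TARGET, "target", "binary")])


def _null_marginals(n_null_binary: int, n_null_count: int) -> dict:
    m: dict = {f"noise_b{i}": Bernoulli(0.5) for i in range(n_null_binary)}
    m.update({f"noise_c{i}": ZeroInflatedPoisson(0.3, 2.0) for i in range(n_null_count)})
    return m


def planted_interaction_config(
    n: int,
    seed: int,
    shift: float = 0.85,
    main_effect: float = 0.0,
    n_null_binary: int = 8,
    n_null_count: int = 2,
) -> CohortGeneratorConfig:
    """Treatment ``T``, moderators ``A``/``B``, and nulls; one planted effect.

    The outcome's log-odds gain ``shift`` when T is active AND (A=1, B=0).
    With the default shift 0.85 and intercept 0, the true counterfactual
    difference is expit(0.85) - expit(0) ≈ 0.20 inside the subgroup and
    ``main_effect``'s logistic contrast (0 by default) outside — the planted
    heterogeneity the stage-2 tree must recover as splits on A and B.
    """
    schema = _schema(
        [
            VariableSpec("T", "predictor", "binary"),
            VariableSpec("A", "predictor", "binary"),
            VariableSpec("B", "predictor", "binary"),
        ],
        n_null_binary,
        n_null_count,
    )
    marginals = {
        "T": Bernoulli(0.5),
        "A": Bernoulli(0.5),
        "B": Bernoulli(0.5),
        **_null_marginals(n_null_binary, n_null_count),
    }
    terms = (ModelTerm("T", main_effect),) if main_effect != 0.0 else (ModelTerm("T", 0.0),)
    outcome = OutcomeModel(
        _TARGET,
        0.0,
        terms,
        (
            PlantedEffect(
                (Literal("A", "eq", 1.0), Literal("B", "eq", 0.0)),
                "T",
                shift,
            ),
        ),
    )
    return CohortGeneratorConfig(schema, n, seed, marginals, (outcome,))


def two_signal_config(
    n: int,
    seed: int,
    n_null_binary: int = 14,
    n_null_count: int = 6,
    coefs: tuple[float, float] = (1.6, 1.2),
) -> CohortGeneratorConfig:
    """Exactly two signal-carrying predictors among 20 nulls.

    ``signal_1`` and ``signal_2`` carry all outcome signal (main effects
    ``coefs``); the other twenty predictors are independent noise, so a
    correct importance ranking puts the two signals on top with the leader
    scaled to exactly 1.
    """
    schema = _schema(
        [
            VariableSpec("signal_1", "predictor", "binary"),
            VariableSpec("signal_2", "predictor", "binary"),
        ],
        n_null_binary,
        n_null_count,
    )
    marginals = {
        "signal_1": Bernoulli(0.5),
        "signal_2": Bernoulli(0.5),
        **_null_marginals(n_null_binary, n_null_count),
    }
    outcome = OutcomeModel(
        _TARGET,
        -(coefs[0] + coefs[1]) / 2.0,  # centre the prevalence near 1/2
        (ModelTerm("signal_1", coefs[0]), ModelTerm("signal_2", coefs[1])),
    )
    return CohortGeneratorConfig(schema, n, seed, marginals, (outcome,))


def null_config(
    n: int,
    seed: int,
    n_null_binary: int = 10,
    n_null_count: int = 2,
) -> CohortGeneratorConfig:
    """Outcome independent of every predictor (intercept-only model).

    Any holdout AUC far from 1/2, or any sizeable subgroup effect, is a
    false positive of the pipeline.  Includes a binary ``T`` to flip.
    """
    schema = _schema(
        [VariableSpec("T", "predictor", "binary")], n_null_binary, n_null_count
    )
    marginals = {"T": Bernoulli(0.5), **_null_marginals(n_null_binary, n_null_count)}
    outcome = OutcomeModel(_TARGET, 0.0, (ModelTerm("T", 0.0),))
    return CohortGeneratorConfig(schema, n, seed, marginals, (outcome,))
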