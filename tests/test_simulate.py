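"""Synthetic cohort generator: reproducibility, marginals, true effects."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from vtwins.schema import CohortSchema, VariableSpec, write_cohort
from vtwins.simulate import (
    Bernoulli,
    Categorical,
    CohortGeneratorConfig,
    ConfigError,
    Literal,
    ModelTerm,
    Normal,
    OutcomeModel,
    PlantedEffect,
    ZeroInflatedPoisson,
    generate,
    paper_like_config,
    probabilities,
    true_effect,
    true_effects,
)


def simple_config(n=100, seed=0, coef=0.0, intercept=0.0, planted=()):
    schema = CohortSchema(
        [
            VariableSpec("T", "predictor", "binary"),
            VariableSpec("A", "predictor", "binary"),
            VariableSpec("k", "predictor", "count"),
            VariableSpec("y", "target", "binary"),
        ]
    )
    marginals = {
        "T": Bernoulli(0.5),
        "A": Bernoulli(0.4),
        "k": ZeroInflatedPoisson(0.3, 2.0),
    }
    outcome = OutcomeModel("y", intercept, (ModelTerm("T", coef),), tuple(planted))
    return CohortGeneratorConfig(schema, n, seed, marginals, (outcome,))


class TestConfigValidation:
    def test_n_zero_rejected(self):
        with pytest.raises(ConfigError, match="n must be >= 1"):
            simple_config(n=0)

    def test_bad_marginal_probs(self):
        with pytest.raises(ConfigError, match="sum"):
            Categorical({"a": 0.5, "b": 0.6})

    def test_missing_marginal(self):
        schema = CohortSchema(
            [VariableSpec("T", "predictor", "binary"), VariableSpec("y", "target", "binary")]
        )
        with pytest.raises(ConfigError, match="no marginal"):
            CohortGeneratorConfig(schema, 10, 0, {}, (OutcomeModel("y", 0.0),))

    def test_planted_unknown_variable(self):
        with pytest.raises(ConfigError, match="unknown predictor"):
            simple_config(
                planted=[PlantedEffect((Literal("ghost", "eq", 1),), "T", 0.5)]
            )


class TestGenerate:
    def test_exact_row_count_and_schema(self):
        table = generate(simple_config(n=57))
        assert table.n == 57
        assert set(table.df.columns) == {"T", "A", "k", "y"}

    def test_byte_identical_reproducibility(self, tmp_path):
        cfg = paper_like_config(n=300, seed=11)
        a, b = generate(cfg), generate(cfg)
        write_cohort(a, tmp_path / "a.csv")
        write_cohort(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_differs(self):
        a = generate(simple_config(n=200, seed=1))
        b = generate(simple_config(n=200, seed=2))
        assert not a.df.equals(b.df)

    def test_marginal_calibration(self):
        cfg = paper_like_config(n=4000, seed=5)
        table = generate(cfg)
        p = 0.879
        se = math.sqrt(p * (1 - p) / table.n)
        assert abs((table.df["race"] == "Black").mean() - p) < 3 * se

    def test_outcome_prevalence_calibration(self):
        cfg = paper_like_config(n=4000, seed=6)
        table = generate(cfg)
        for target, p in [("los_gt90", 0.578), ("completed", 0.449)]:
            se = math.sqrt(p * (1 - p) / table.n)
            assert abs(table.df[target].mean() - p) < 3 * se + 0.01

    def test_null_planted_effect_indistinguishable(self):
        # same seed -> identical covariates; a zero shift must leave the
        # outcome frequencies statistically indistinguishable (two-proportion
        # z-test at alpha = 0.01)
        base = generate(simple_config(n=2000, seed=3, coef=0.4))
        shifted = generate(
            simple_config(
                n=2000,
                seed=3,
                coef=0.4,
                planted=[PlantedEffect((Literal("A", "eq", 1.0),), "T", 0.0)],
            )
        )
        p1, p2 = base.df["y"].mean(), shifted.df["y"].mean()
        pool = (base.df["y"].sum() + shifted.df["y"].sum()) / 4000
        z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (2 / 2000))
        assert abs(z) < norm.ppf(0.995)

    def test_copula_induces_association(self):
        schema = CohortSchema(
            [
                VariableSpec("a", "predictor", "binary"),
                VariableSpec("b", "predictor", "binary"),
                VariableSpec("y", "target", "binary"),
            ]
        )
        cfg = CohortGeneratorConfig(
            schema,
            4000,
            7,
            {"a": Bernoulli(0.5), "b": Bernoulli(0.5)},
            (OutcomeModel("y", 0.0),),
            correlations=(("a", "b", 0.7),),
        )
        df = generate(cfg).df
        assert np.corrcoef(df["a"], df["b"])[0, 1] > 0.3


class TestTrueEffect:
    def test_zero_coefficient_gives_zero(self):
        cfg = simple_config(coef=0.0)
        row = {"T": 1, "A": 0, "k": 2, "y": 0}
        assert true_effect(cfg, row, "T", "y") == 0.0

    def test_log3_main_effect_closed_form(self):
        # expit(ln 3) - expit(0) = 0.75 - 0.5 = 0.25
        cfg = simple_config(coef=math.log(3))
        row = {"T": 0, "A": 1, "k": 0, "y": 0}
        assert true_effect(cfg, row, "T", "y") == pytest.approx(0.25, abs=1e-12)

    def test_unmodelled_variable_rejected(self):
        cfg = simple_config(coef=1.0)
        with pytest.raises(ConfigError):
            true_effect(cfg, {"T": 0, "A": 1, "k": 0, "y": 0}, "A", "y")

    def test_planted_contrast_between_rows(self):
        shift = 0.9
        cfg = simple_config(coef=0.2, planted=[PlantedEffect((Literal("A", "eq", 1.0),), "T", shift)])
        holds = {"T": 0, "A": 1, "k": 0, "y": 0}
        fails = {"T": 0, "A": 0, "k": 0, "y": 0}
        eff_in = true_effect(cfg, holds, "T", "y")
        eff_out = true_effect(cfg, fails, "T", "y")
        assert eff_in == pytest.approx(expit(0.2 + shift) - expit(0.0), abs=1e-12)
        assert eff_out == pytest.approx(expit(0.2) - expit(0.0), abs=1e-12)

    def test_matches_monte_carlo_oracle(self):
        # independent oracle: simulate the outcome Bernoulli at both forced
        # arms and difference the empirical rates
        cfg = simple_config(
            coef=0.6,
            intercept=-0.3,
            planted=[PlantedEffect((Literal("k", "gt", 2.0),), "T", 0.8)],
        )
        table = generate(simple_config(n=20, seed=42))
        rng = np.random.default_rng(123)
        draws = 1_000_000
        for _, row in table.df.iterrows():
            analytic = true_effect(cfg, row.to_dict(), "T", "y")
            df1 = pd.DataFrame([row.to_dict()])
            p1 = probabilities(cfg, df1, "y", {"T": 1})[0]
            p0 = probabilities(cfg, df1, "y", {"T": 0})[0]
            mc = (rng.uniform(size=draws) < p1).mean() - (rng.uniform(size=draws) < p0).mean()
            assert abs(analytic - mc) < 0.005

    def test_vectorized_matches_scalar(self):
        cfg = simple_config(coef=0.7, planted=[PlantedEffect((Literal("A", "eq", 1.0),), "T", 0.5)])
        table = generate(simple_config(n=10, seed=9))
        vec = true_effects(cfg, table.df, "T", "y")
        scal = [true_effect(cfg, r.to_dict(), "T", "y") for _, r in table.df.iterrows()]
        np.testing.assert_allclose(vec, scal, atol=1e-15)


class TestMarginals:
    def test_zip_mass_at_zero(self):
        m = ZeroInflatedPoisson(0.4, 5.0)
        u = np.random.default_rng(0).uniform(size=20000)
        vals = m.from_uniform(u)
        assert abs((vals == 0).mean() - (0.4 + 0.6 * math.exp(-5.0))) < 0.02
        assert vals.min() >= 0 and (vals == np.floor(vals)).all()

    def test_categorical_inverse_cdf(self):
        m = Categorical({"a": 0.2, "b": 0.5, "c": 0.3})
        vals = m.from_uniform(np.array([0.1, 0.25, 0.69, 0.71, 0.999999]))
        assert vals.tolist() == ["a", "b", "b", "c", "c"]

    def test_normal_marginal(self):
        m = Normal(10.0, 2.0)
        u = np.random.default_rng(1).uniform(size=5000)
        vals = m.from_uniform(u)
        assert abs(vals.mean() - 10.0) < 0.15
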