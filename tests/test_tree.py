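"""Subgroup tree: splits, conservation, exclusion, rendering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from vtwins.schema import CohortSchema, CohortTable, ValidationError, VariableSpec
from vtwins.tree import (
    Subgroup,
    TreeParams,
    extract_subgroups,
    fit_tree,
    render_tree,
    top_split_variables,
)

from conftest import binary_cohort


def make_table(df: pd.DataFrame, target="y") -> CohortTable:
    specs = []
    for col in df.columns:
        if col == target:
            specs.append(VariableSpec(col, "target", "binary"))
        elif df[col].dtype == object:
            specs.append(
                VariableSpec(col, "predictor", "categorical", tuple(sorted(set(df[col]))))
            )
        elif set(np.unique(df[col])) <= {0, 1}:
            specs.append(VariableSpec(col, "predictor", "binary"))
        else:
            specs.append(VariableSpec(col, "predictor", "continuous"))
    return CohortTable(df, CohortSchema(specs))


class TestFitTree:
    def test_constant_z_single_node(self):
        table = binary_cohort(50, ["a", "b"], "y", seed=0)
        tree = fit_tree(np.full(50, 0.2), table, TreeParams())
        assert tree.root.is_leaf
        assert tree.root.mean_effect == pytest.approx(0.2)
        assert tree.root.coverage == 1.0

    def test_perfect_binary_split(self):
        table = binary_cohort(200, ["a", "b"], "y", seed=1)
        z = np.where(table.df["a"] == 1, 0.3, 0.0)
        tree = fit_tree(z, table, TreeParams())
        assert tree.root.split.variable == "a"
        effects = sorted(l.mean_effect for l in tree.leaves())
        assert effects == pytest.approx([0.0, 0.3])
        assert sum(l.coverage for l in tree.leaves()) == pytest.approx(1.0)

    def test_misaligned_lengths_rejected(self):
        table = binary_cohort(50, ["a"], "y", seed=2)
        with pytest.raises(ValidationError, match="rows"):
            fit_tree(np.zeros(49), table, TreeParams())

    def test_excluded_variable_never_splits(self):
        rng = np.random.default_rng(3)
        table = binary_cohort(400, ["t", "a", "b"], "y", seed=3)
        # z driven mostly by the excluded variable: it must still never appear
        z = 0.4 * table.df["t"].to_numpy() + 0.1 * table.df["a"].to_numpy()
        z += rng.normal(0, 0.01, 400)
        tree = fit_tree(z, table, TreeParams(), exclude="t")
        assert "t" not in tree.split_variables()

    def test_categorical_subset_split_recovered(self):
        rng = np.random.default_rng(4)
        levels = np.array(["a", "b", "c", "d"], dtype=object)
        col = levels[rng.integers(0, 4, 500)]
        df = pd.DataFrame({"grp": col, "y": rng.integers(0, 2, 500)})
        table = make_table(df)
        z = np.where(np.isin(col, ["a", "c"]), 0.25, -0.05) + rng.normal(0, 0.01, 500)
        tree = fit_tree(z, table, TreeParams(max_depth=1))
        split = tree.root.split
        assert split.variable == "grp"
        assert split.levels in (frozenset({"a", "c"}), frozenset({"b", "d"}))

    def test_midpoint_thresholds_on_counts(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 8, 600).astype(float)
        df = pd.DataFrame({"k": counts, "y": rng.integers(0, 2, 600)})
        schema = CohortSchema(
            [VariableSpec("k", "predictor", "count"), VariableSpec("y", "target", "binary")]
        )
        table = CohortTable(df, schema)
        z = np.where(counts > 2, 0.2, 0.0)
        tree = fit_tree(z, table, TreeParams(max_depth=1))
        assert tree.root.split.threshold == pytest.approx(2.5)

    def test_depth_monotone_training_mse(self):
        rng = np.random.default_rng(6)
        table = binary_cohort(500, ["a", "b", "c", "d"], "y", seed=6)
        z = rng.normal(0, 0.1, 500) + 0.1 * table.df["a"].to_numpy()
        prev = np.inf
        for depth in range(0, 6):
            tree = fit_tree(z, table, TreeParams(max_depth=depth))
            mse = tree.training_mse()
            assert mse <= prev + 1e-12
            prev = mse

    def test_matches_sklearn_on_numeric_data(self):
        # independent greedy-CART cross-check: same criterion, same stopping
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
                "y": rng.integers(0, 2, n),
            }
        )
        schema = CohortSchema(
            [VariableSpec(c, "predictor", "continuous") for c in ["x1", "x2", "x3"]]
            + [VariableSpec("y", "target", "binary")]
        )
        table = CohortTable(df, schema)
        z = rng.normal(size=n) + df["x1"].to_numpy() * 0.5
        min_leaf = 20
        mine = fit_tree(
            z, table, TreeParams(max_depth=3, min_leaf_fraction=min_leaf / n)
        )
        sk = DecisionTreeRegressor(max_depth=3, min_samples_leaf=min_leaf, random_state=0)
        sk.fit(df[["x1", "x2", "x3"]].to_numpy(), z)
        sk_mse = np.mean((sk.predict(df[["x1", "x2", "x3"]].to_numpy()) - z) ** 2)
        assert mine.training_mse() == pytest.approx(sk_mse, rel=1e-9)

    def test_conservation_invariants(self):
        rng = np.random.default_rng(8)
        table = binary_cohort(700, ["a", "b", "c"], "y", seed=8)
        z = rng.normal(0, 0.2, 700)
        tree = fit_tree(z, table, TreeParams())
        for node in tree.nodes():
            if node.children:
                l, r = node.children
                assert l.coverage + r.coverage == pytest.approx(node.coverage, abs=1e-12)
                weighted = (
                    l.coverage * l.mean_effect + r.coverage * r.mean_effect
                ) / node.coverage
                assert weighted == pytest.approx(node.mean_effect, abs=1e-10)
        total = sum(l.coverage * l.mean_effect for l in tree.leaves())
        assert total == pytest.approx(z.mean(), abs=1e-10)


class TestExtractSubgroups:
    def test_single_node_tree(self):
        table = binary_cohort(40, ["a"], "y", seed=9)
        tree = fit_tree(np.full(40, 0.15), table, TreeParams())
        groups = extract_subgroups(tree, min_effect=0.0)
        assert groups == [Subgroup((), pytest.approx(0.15), 1.0)]

    def test_perfect_split_min_effect_filter(self):
        table = binary_cohort(200, ["a", "b"], "y", seed=10)
        z = np.where(table.df["a"] == 1, 0.3, 0.0)
        tree = fit_tree(z, table, TreeParams())
        groups = extract_subgroups(tree, min_effect=0.1)
        assert len(groups) == 1
        assert groups[0].condition == ("a = 1",)
        assert groups[0].mean_effect == pytest.approx(0.3)

    def test_sorted_by_effect_descending(self):
        rng = np.random.default_rng(11)
        table = binary_cohort(400, ["a", "b", "c"], "y", seed=11)
        z = rng.normal(0, 0.1, 400)
        groups = extract_subgroups(fit_tree(z, table, TreeParams()))
        effects = [g.mean_effect for g in groups]
        assert effects == sorted(effects, reverse=True)

    def test_internal_nodes_give_coarser_subgroups(self):
        table = binary_cohort(300, ["a", "b"], "y", seed=12)
        z = np.where(table.df["a"] == 1, 0.3, 0.0) + 0.05 * table.df["b"].to_numpy()
        tree = fit_tree(z, table, TreeParams(max_depth=2))
        with_internal = extract_subgroups(tree, include_internal=True)
        leaves_only = extract_subgroups(tree)
        assert len(with_internal) > len(leaves_only)
        assert any(g.condition == () for g in with_internal)


class TestRender:
    def test_single_node_label(self):
        table = binary_cohort(40, ["a"], "y", seed=13)
        tree = fit_tree(np.full(40, 0.2), table, TreeParams())
        dot, outline = render_tree(tree)
        assert '"20.0%\\n100.0%"' in dot
        assert "effect +20.0%, coverage 100.0%" in outline

    def test_left_branch_is_condition_satisfied(self):
        table = binary_cohort(200, ["a", "b"], "y", seed=14)
        z = np.where(table.df["a"] == 1, 0.3, 0.0)
        tree = fit_tree(z, table, TreeParams(max_depth=1))
        dot, _ = render_tree(tree)
        # left edge is labelled with the satisfied condition, right with "no"
        assert 'n0 -> n1 [label="a = 0"]' in dot
        assert 'n0 -> n2 [label="no"]' in dot

    def test_fill_shade_monotone_in_effect(self):
        rng = np.random.default_rng(15)
        table = binary_cohort(600, ["a", "b", "c"], "y", seed=15)
        z = (
            0.3 * table.df["a"].to_numpy()
            + 0.15 * table.df["b"].to_numpy()
            + rng.normal(0, 0.01, 600)
        )
        tree = fit_tree(z, table, TreeParams(max_depth=2))
        dot, _ = render_tree(tree)
        import re

        shades = {}
        for m in re.finditer(r'n(\d+) \[label="(-?[\d.]+)%.*?fillcolor="#([0-9a-f]{6})"', dot):
            effect = float(m.group(2))
            rgb = int(m.group(3), 16)
            brightness = sum((rgb >> s) & 0xFF for s in (16, 8, 0))
            shades[m.group(1)] = (effect, brightness)
        pairs = sorted(shades.values())
        assert len(pairs) >= 3
        # higher effect -> darker (lower brightness)
        for (e1, b1), (e2, b2) in zip(pairs, pairs[1:]):
            if e2 > e1:
                assert b2 <= b1
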