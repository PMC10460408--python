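"""Stage-2 subgroup tree: explain Z with covariates.

The counterfactual probability difference Z is a continuous quantity, so
the subgroup model is a variance-reduction regression tree (recursive
binary partitioning minimising within-node sum of squares), grown over all
predictors except the flipped subgroup variable.  Nodes carry the two
numbers the method reports per subgroup: the mean effect (displayable as a
percentage-point change in outcome probability) and the coverage (fraction
of the cohort the node applies to).

Numeric splits use midpoints between adjacent observed values, which is why
integer counts yield fractional thresholds such as "goals_set <= 2.5".
Categorical variables with at most 8 levels are split by exhaustive
level-subset search; beyond that, one-vs-rest splits only.  All
tie-breaking is deterministic: first by variable order in the schema, then
by lowest threshold / lexicographically earliest subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import CohortTable, SchemaError, ValidationError, VariableSpec
from .vtwin import CounterfactualResult

__all__ = [
    "TreeParams",
    "Split",
    "SubgroupNode",
    "SubgroupTree",
    "Subgroup",
    "fit_tree",
    "extract_subgroups",
    "top_split_variables",
    "render_tree",
]

_GAIN_EPS = 1e-12
_MAX_SUBSET_LEVELS = 8


@dataclass(frozen=True)
class TreeParams:
    """Growth controls for the subgroup tree.

    max_depth caps specificity (deep trees find narrow, possibly
    non-generalizable subgroups); min_leaf_fraction keeps every reported
    subgroup covering a meaningful share of the cohort; complexity_penalty
    is the minimum split gain as a fraction of the root's total variance.
    """

    max_depth: int = 5
    min_leaf_fraction: float = 0.05
    complexity_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if not 0.0 < self.min_leaf_fraction <= 0.5:
            raise ValueError("min_leaf_fraction must be in (0, 0.5]")
        if self.complexity_penalty < 0:
            raise ValueError("complexity_penalty must be >= 0")


@dataclass(frozen=True)
class Split:
    """A binary split; the left child is where the condition is satisfied.

    Numeric: condition is ``value <= threshold``.  Categorical: condition is
    ``value in levels``.
    """

    variable: str
    threshold: float | None = None
    levels: frozenset[str] | None = None

    def goes_left(self, col: np.ndarray) -> np.ndarray:
        if self.levels is not None:
            return np.isin(col, list(self.levels))
        return col.astype(float) <= self.threshold

    def describe(self, spec: VariableSpec, satisfied: bool = True) -> str:
        if self.levels is not None:
            levs = ", ".join(sorted(self.levels))
            return f"{self.variable} in {{{levs}}}" if satisfied else f"{self.variable} not in {{{levs}}}"
        if spec.vtype == "binary":
            return f"{self.variable} = 0" if satisfied else f"{self.variable} = 1"
        op = "<=" if satisfied else ">"
        return f"{self.variable} {op} {self.threshold:g}"


@dataclass
class SubgroupNode:
    mean_effect: float
    coverage: float
    depth: int
    n: int
    sse: float
    split: Split | None = None
    split_gain: float = 0.0
    children: tuple["SubgroupNode", "SubgroupNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SubgroupTree:
    root: SubgroupNode
    excluded_variable: str | None
    fitting_params: TreeParams
    schema_snapshot: object  # CohortSchema of the fitted table

    def nodes(self) -> list[SubgroupNode]:
        """All nodes in breadth-first order."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            if node.children:
                queue.extend(node.children)
        return out

    def leaves(self) -> list[SubgroupNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def training_mse(self) -> float:
        """Mean squared error of leaf-mean predictions on the fitting data."""
        total_n = self.root.n
        return sum(l.sse for l in self.leaves()) / total_n

    def split_variables(self) -> list[str]:
        return [n.split.variable for n in self.nodes() if n.split is not None]


@dataclass(frozen=True)
class Subgroup:
    """A covariate-defined subgroup: path conditions, mean effect, coverage."""

    condition: tuple[str, ...]
    mean_effect: float
    coverage: float


# -- split search -------------------------------------------------------------


def _best_numeric_split(vals: np.ndarray, z: np.ndarray, min_leaf: int):
    """Best between-group sum-of-squares gain over midpoint thresholds."""
    order = np.argsort(vals, kind="stable")
    v, zz = vals[order], z[order]
    n = len(zz)
    csum = np.cumsum(zz)
    total = csum[-1]
    nl = np.arange(1, n)  # size of left side at each cut position
    valid = (v[1:] != v[:-1]) & (nl >= min_leaf) & (n - nl >= min_leaf)
    if not valid.any():
        return None
    suml = csum[:-1]
    gain = suml**2 / nl + (total - suml) ** 2 / (n - nl) - total**2 / n
    gain = np.where(valid, gain, -np.inf)
    i = int(np.argmax(gain))  # argmax takes the first max: lowest threshold wins ties
    return float(gain[i]), float((v[i] + v[i + 1]) / 2.0)


def _best_subset_split(vals: np.ndarray, z: np.ndarray, levels: list[str], min_leaf: int):
    """Best level-subset split; exhaustive for <= 8 levels, else one-vs-rest."""
    sums, counts = [], []
    for lev in levels:
        m = vals == lev
        sums.append(z[m].sum())
        counts.append(int(m.sum()))
    sums, counts = np.asarray(sums), np.asarray(counts)
    n, total = counts.sum(), sums.sum()
    L = len(levels)
    if L < 2:
        return None
    if L <= _MAX_SUBSET_LEVELS:
        # masks that include the first level enumerate each bipartition once;
        # increasing mask order = lexicographically earliest subset wins ties
        masks = [m for m in range(1, 2**L - 1) if m & 1]
    else:
        masks = [1 << i for i in range(L)]
    best = None
    for m in masks:
        sel = [(m >> i) & 1 == 1 for i in range(L)]
        nl = int(counts[sel].sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        sl = float(sums[sel].sum())
        gain = sl**2 / nl + (total - sl) ** 2 / (n - nl) - total**2 / n
        if best is None or gain > best[0] + _GAIN_EPS:
            best = (float(gain), frozenset(lev for lev, s in zip(levels, sel) if s))
    return best


def _grow(
    idx: np.ndarray,
    depth: int,
    z: np.ndarray,
    columns: dict[str, np.ndarray],
    candidates: list[VariableSpec],
    levels_of: dict[str, list[str]],
    min_leaf: int,
    gain_floor: float,
    params: TreeParams,
    n_total: int,
) -> SubgroupNode:
    zn = z[idx]
    mean = float(zn.mean())
    sse = float(((zn - mean) ** 2).sum())
    node = SubgroupNode(
        mean_effect=mean,
        coverage=len(idx) / n_total,
        depth=depth,
        n=len(idx),
        sse=sse,
    )
    if depth >= params.max_depth or len(idx) < 2 * min_leaf or sse <= 1e-14:
        return node
    best = None  # (gain, Split); schema order + strict improvement = deterministic ties
    for spec in candidates:
        col = columns[spec.name][idx]
        if spec.vtype == "categorical":
            res = _best_subset_split(col, zn, levels_of[spec.name], min_leaf)
            if res is not None:
                gain, subset = res
                if best is None or gain > best[0] + _GAIN_EPS:
                    best = (gain, Split(spec.name, levels=subset))
        else:
            res = _best_numeric_split(col.astype(float), zn, min_leaf)
            if res is not None:
                gain, thr = res
                if best is None or gain > best[0] + _GAIN_EPS:
                    best = (gain, Split(spec.name, threshold=thr))
    if best is None or best[0] <= gain_floor:
        return node
    split = best[1]
    left_mask = split.goes_left(columns[split.variable][idx])
    left_idx, right_idx = idx[left_mask], idx[~left_mask]
    if len(left_idx) < min_leaf or len(right_idx) < min_leaf:
        return node
    node.split = split
    node.split_gain = float(best[0])
    node.children = (
        _grow(left_idx, depth + 1, z, columns, candidates, levels_of, min_leaf, gain_floor, params, n_total),
        _grow(right_idx, depth + 1, z, columns, candidates, levels_of, min_leaf, gain_floor, params, n_total),
    )
    return node


def fit_tree(
    z: CounterfactualResult | Sequence[float],
    table: CohortTable,
    params: TreeParams = TreeParams(),
    exclude: str | Sequence[str] | None = None,
) -> SubgroupTree:
    """Grow the subgroup tree on z over all predictors except the flipped one.

    ``z`` may be a :class:`~vtwins.vtwin.CounterfactualResult` (its subgroup
    variable is excluded automatically) or a plain vector aligned with
    ``table``.  Constant z yields a single-node tree.
    """
    if isinstance(z, CounterfactualResult):
        excluded = {z.subgroup_variable}
        zvec = z.z
    else:
        excluded = set()
        zvec = np.asarray(z, dtype=float)
    if exclude is not None:
        excluded |= {exclude} if isinstance(exclude, str) else set(exclude)
    if len(zvec) != table.n:
        raise ValidationError(
            f"z has {len(zvec)} entries but the table has {table.n} rows"
        )
    for name in excluded:
        table.schema[name]  # raises SchemaError if absent
    candidates = [v for v in table.schema.predictors() if v.name not in excluded]
    columns = {
        v.name: (
            table.df[v.name].to_numpy(dtype=object)
            if v.vtype == "categorical"
            else table.df[v.name].to_numpy(dtype=float)
        )
        for v in candidates
    }
    levels_of = {
        v.name: sorted(set(map(str, columns[v.name])))
        for v in candidates
        if v.vtype == "categorical"
    }
    n = table.n
    min_leaf = max(1, int(np.ceil(params.min_leaf_fraction * n)))
    root_var = float(np.var(zvec))
    gain_floor = params.complexity_penalty * root_var * n
    root = _grow(
        np.arange(n), 0, zvec, columns, candidates, levels_of, min_leaf, gain_floor, params, n
    )
    return SubgroupTree(
        root=root,
        excluded_variable=(next(iter(excluded)) if len(excluded) == 1 else None),
        fitting_params=params,
        schema_snapshot=table.schema,
    )


def extract_subgroups(
    tree: SubgroupTree,
    min_effect: float = 0.0,
    include_internal: bool = False,
) -> list[Subgroup]:
    """Subgroups whose |mean effect| >= min_effect, sorted by effect descending.

    Each subgroup is described by the conjunction of split conditions along
    its root path; the root itself has the empty condition.  By default only
    leaves are reported; internal nodes give the coarser, more generalizable
    subgroups closer to the root.
    """
    out: list[Subgroup] = []

    def walk(node: SubgroupNode, path: tuple[str, ...]) -> None:
        eligible = node.is_leaf or include_internal
        if eligible and abs(node.mean_effect) >= min_effect:
            out.append(Subgroup(path, node.mean_effect, node.coverage))
        if node.children:
            spec = tree.schema_snapshot[node.split.variable]
            walk(node.children[0], path + (node.split.describe(spec, True),))
            walk(node.children[1], path + (node.split.describe(spec, False),))

    walk(tree.root, ())
    return sorted(out, key=lambda s: -s.mean_effect)


def top_split_variables(tree: SubgroupTree, k: int) -> list[str]:
    """The k distinct variables behind the largest variance-reduction splits.

    Internal nodes are ranked by their split's sum-of-squares gain, so the
    result names the covariates that explain the most effect heterogeneity
    (the root split plus the strongest descendants), not merely the
    shallowest ones.
    """
    ranked = sorted(
        (n for n in tree.nodes() if n.split is not None),
        key=lambda n: -n.split_gain,
    )
    seen: list[str] = []
    for node in ranked:
        if node.split.variable not in seen:
            seen.append(node.split.variable)
        if len(seen) == k:
            break
    return seen


# -- rendering ----------------------------------------------------------------


def _shade(effect: float, lo: float, hi: float) -> tuple[str, str]:
    """Fill and font colors; darker fill for larger effect (monotone)."""
    t = 0.5 if hi <= lo else (effect - lo) / (hi - lo)
    # interpolate white -> dark blue
    r = int(round(255 + t * (8 - 255)))
    g = int(round(255 + t * (48 - 255)))
    b = int(round(255 + t * (107 - 255)))
    fill = f"#{r:02x}{g:02x}{b:02x}"
    font = "#ffffff" if t > 0.6 else "#000000"
    return fill, font


def _node_label(node: SubgroupNode) -> str:
    return f"{100 * node.mean_effect:.1f}%\\n{100 * node.coverage:.1f}%"


def render_tree(tree: SubgroupTree) -> tuple[str, str]:
    """Render as (DOT graph, indented text outline).

    Node labels carry the two reported numbers — effect (top) and % of
    sample (bottom); fill hue darkens monotonically with effect.  Left
    branches mean the split condition is satisfied ("yes"), right branches
    mean it is not.
    """
    nodes = tree.nodes()
    lo = min(n.mean_effect for n in nodes)
    hi = max(n.mean_effect for n in nodes)
    ids = {id(n): i for i, n in enumerate(nodes)}
    lines = [
        "digraph subgroup_tree {",
        '  node [shape=box, style="filled,rounded"];',
    ]
    for n in nodes:
        fill, font = _shade(n.mean_effect, lo, hi)
        lines.append(
            f'  n{ids[id(n)]} [label="{_node_label(n)}", fillcolor="{fill}", fontcolor="{font}"];'
        )
    for n in nodes:
        if n.children:
            spec = tree.schema_snapshot[n.split.variable]
            yes = n.split.describe(spec, True).replace('"', "'")
            lines.append(f'  n{ids[id(n)]} -> n{ids[id(n.children[0])]} [label="{yes}"];')
            lines.append(f'  n{ids[id(n)]} -> n{ids[id(n.children[1])]} [label="no"];')
    lines.append("}")
    dot = "\n".join(lines)

    out: list[str] = []

    def walk(node: SubgroupNode, prefix: str, label: str) -> None:
        out.append(
            f"{prefix}{label}effect {100 * node.mean_effect:+.1f}%, "
            f"coverage {100 * node.coverage:.1f}%"
        )
        if node.children:
            spec = tree.schema_snapshot[node.split.variable]
            walk(node.children[0], prefix + "  ", f"[{node.split.describe(spec, True)}] ")
            walk(node.children[1], prefix + "  ", f"[{node.split.describe(spec, False)}] ")

    walk(tree.root, "", "")
    return dot, "\n".join(out)
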