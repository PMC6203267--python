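"""Regression trees for discovering covariate dichotomization thresholds.

A small, deterministic CART variant fits each well-being measure on the
ability proxy and the two ages, purely to discover where the response
mean jumps: the resulting split thresholds (e.g. child age <= 8 vs > 8)
define the binary indicator features handed to the model-averaging
stage.  Splits minimize within-node sum of squared deviations; candidate
thresholds are the observed values of each covariate ("x <= t" goes
left); ties are broken toward the smaller threshold and then the
covariate order as given.  There is no pruning — trees are kept shallow
by design since only coarse dichotomies are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TreeParams", "TreeNode", "fit_tree", "extract_thresholds"]


@dataclass(frozen=True)
class TreeParams:
    """Tree-growing controls.

    ``min_split_improvement`` is the minimum SSE reduction a split must
    achieve, as a fraction of the parent node's SSE.
    """

    max_depth: int = 3
    min_leaf: int = 20
    min_split_improvement: float = 0.01

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.min_split_improvement < 0:
            raise ValueError("min_split_improvement must be >= 0")


@dataclass
class TreeNode:
    mean: float
    size: int
    variable: str | None = None   # None at a leaf
    threshold: float | None = None  # x <= threshold goes left
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def predict_row(self, row: dict) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.variable] <= node.threshold else node.right
        return node.mean

    def render(self, indent: str = "") -> str:
        """Plain-text rendering of the tree structure."""
        if self.is_leaf:
            return f"{indent}leaf: mean={self.mean:.3f} n={self.size}"
        head = (f"{indent}{self.variable} <= {self.threshold:g} "
                f"(mean={self.mean:.3f} n={self.size})")
        return "\n".join([head,
                          self.left.render(indent + "  "),
                          self.right.render(indent + "  ")])


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[float, float] | None:
    """Best (threshold, child SSE) for one covariate, or None.

    Scans thresholds at observed values using prefix sums over the
    sorted order; equal child SSEs resolve to the smaller threshold.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(ys)
    cum = np.cumsum(ys)
    cum2 = np.cumsum(ys**2)
    total, total2 = cum[-1], cum2[-1]

    # last index of each run of equal x values = candidate left-block end
    ends = np.flatnonzero(np.diff(xs) > 0)  # split between ends[i] and ends[i]+1
    best: tuple[float, float] | None = None
    for e in ends:
        nl = e + 1
        nr = n - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        sse_l = cum2[e] - cum[e]**2 / nl
        sse_r = (total2 - cum2[e]) - (total - cum[e])**2 / nr
        sse = sse_l + sse_r
        if best is None or sse < best[1] - 1e-12:
            best = (float(xs[e]), sse)
    return best


def _grow(X: dict[str, np.ndarray], y: np.ndarray, params: TreeParams,
          depth: int, variables: Sequence[str]) -> TreeNode:
    node = TreeNode(mean=float(np.mean(y)), size=len(y))
    parent_sse = float(np.sum((y - node.mean) ** 2))
    if depth >= params.max_depth or len(y) < 2 * params.min_leaf or parent_sse == 0:
        return node

    best_var, best_thr, best_sse = None, None, np.inf
    for var in variables:  # earlier variables win exact ties
        cand = _best_split(X[var], y, params.min_leaf)
        if cand is not None and cand[1] < best_sse - 1e-12:
            best_var, best_thr, best_sse = var, cand[0], cand[1]
    if best_var is None:
        return node
    if parent_sse - best_sse < params.min_split_improvement * parent_sse:
        return node

    mask = X[best_var] <= best_thr
    node.variable, node.threshold = best_var, best_thr
    node.left = _grow({v: X[v][mask] for v in variables}, y[mask],
                      params, depth + 1, variables)
    node.right = _grow({v: X[v][~mask] for v in variables}, y[~mask],
                       params, depth + 1, variables)
    return node


def fit_tree(cohort: pd.DataFrame, measure: str,
             covariates: Sequence[str] = ("wessex", "child_age", "maternal_age"),
             params: TreeParams | None = None) -> TreeNode:
    """Fit a regression tree of one measure on the given covariates.

    Rows with a missing response are dropped.  A constant response
    yields a single-leaf tree.  Refitting on permuted rows gives an
    identical tree (all tie-breaks are deterministic).
    """
    params = params or TreeParams()
    df = cohort.loc[cohort[measure].notna()]
    if len(df) < 2 * params.min_leaf:
        raise ValueError(f"need at least {2 * params.min_leaf} rows with "
                         f"non-missing {measure!r}")
    for cov in covariates:
        if cov == "wessex_max":
            continue
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
    X = {}
    for cov in covariates:
        if cov == "wessex_max":
            X[cov] = (df["wessex"].to_numpy(float) == 9.0).astype(float)
        else:
            X[cov] = df[cov].to_numpy(float)
    y = df[measure].to_numpy(float)
    return _grow(X, y, params, depth=0, variables=list(covariates))


def extract_thresholds(tree: TreeNode, variable: str) -> list[float]:
    """All split thresholds used for a variable, de-duplicated and sorted."""
    found: set[float] = set()
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        if node.variable == variable:
            found.add(float(node.threshold))
        stack.extend([node.left, node.right])
    return sorted(found)
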