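"""Recursive trait trees and host-pattern assignment.

The tree is grown by repeated hierarchical partitioning: at each node the
remaining candidate predictors are scored by the randomisation z-test; if
none is significant the node becomes a leaf, otherwise the node splits on
the most significant predictor — one child per observed level for a
categorical trait, a two-way split at the members' median for a
quantitative one — and the chosen predictor is removed from every
descendant's candidate set.  Leaves carry the mean response of their
members, which drives the Best/Worst (abundance) and Trunk/Branches
(within-crown distribution) host-pattern labels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import Dataset
from .hierpart import HierarchicalPartitioner

__all__ = [
    "TreeNode",
    "SuccessivePartitionTree",
    "grow_tree",
    "PatternThresholds",
    "assign_patterns",
    "pattern_overlap_counts",
]

log = logging.getLogger(__name__)

PATTERNS = ("best", "worst", "trunk", "branches")


@dataclasses.dataclass
class TreeNode:
    """One node of the recursive partition."""

    members: list
    candidates: list[str]
    depth: int
    mean: float
    split_var: str | None = None
    split_kind: str | None = None  # 'categorical' | 'quantitative'
    threshold: float | None = None  # quantitative only; '<=' goes left
    z: float | None = None
    pct: float | None = None
    children: dict = dataclasses.field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children.values():
                yield from child.leaves()

    def to_dict(self) -> dict:
        d = {
            "n": len(self.members),
            "mean": self.mean,
            "members": [str(m) for m in self.members],
        }
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                split_kind=self.split_kind,
                z=self.z,
                pct=self.pct,
            )
            if self.split_kind == "quantitative":
                d["threshold"] = self.threshold
            d["children"] = {str(k): c.to_dict() for k, c in self.children.items()}
        return d

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf n={len(self.members)} mean={self.mean:.3g}"
        head = f"{pad}split on {self.split_var} (z={self.z:.2f}, {self.pct:.1f}%)"
        lines = [head]
        for key, child in self.children.items():
            if self.split_kind == "quantitative":
                op = "<=" if key == "le" else ">"
                label = f"{self.split_var} {op} {self.threshold:.4g}"
            else:
                label = f"{self.split_var} = {key}"
            lines.append("  " * (indent + 1) + label + ":")
            lines.append(child.render(indent + 2))
        return "\n".join(lines)


def _node_mean(y, family: str) -> float:
    if family == "binomial":
        s = float(y[:, 0].sum())
        t = float(y.sum())
        return s / t if t > 0 else np.nan
    return float(np.mean(y))


class SuccessivePartitionTree(BaseEstimator):
    """Sklearn-style recursive partitioning by hierarchical-partition z-tests.

    Parameters
    ----------
    family : {'gaussian', 'poisson', 'binomial'}
        Node-level GLM family (binomial ``y`` is (n, 2) successes/failures).
    min_node : int
        Nodes smaller than this become leaves (default 10).
    n_rand : int
        Permutations for the per-node randomisation test.
    alpha : float
        Per-node family-wise significance level.  With m candidates at a
        node, a split requires an exact permutation p-value ≤ alpha/m
        (Bonferroni), keeping the node's false-split rate at ≤ alpha.
        Note the resolution limit: n_rand must satisfy
        1/(n_rand+1) ≤ alpha/m for a split to be possible at all.
    random_state : int, optional
    kinds : dict, optional
        Predictor kinds; inferred from dtypes when omitted.

    Attributes (after ``fit``)
    --------------------------
    root_ : TreeNode
    leaf_means_ : pd.Series mapping member id -> leaf mean
    """

    def __init__(self, family: str = "poisson", min_node: int = 10,
                 n_rand: int = 1000, alpha: float = 0.05,
                 random_state=None, kinds: dict[str, str] | None = None):
        self.family = family
        self.min_node = min_node
        self.n_rand = n_rand
        self.alpha = alpha
        self.random_state = random_state
        self.kinds = kinds

    # ------------------------------------------------------------------
    def _viable_candidates(self, X: pd.DataFrame, kinds, candidates):
        out = []
        for c in candidates:
            col = X[c]
            if kinds[c] == "quantitative":
                vals = col.to_numpy(dtype=float)
                med = float(np.median(vals))
                if (vals <= med).all() or (vals > med).all():
                    continue
            else:
                if col.astype(str).nunique() < 2:
                    continue
            out.append(c)
        return out

    def _grow(self, X: pd.DataFrame, y, kinds, candidates, depth, rng) -> TreeNode:
        node = TreeNode(
            members=list(X.index),
            candidates=list(candidates),
            depth=depth,
            mean=_node_mean(y, self.family),
        )
        if len(X) < self.min_node:
            return node
        yflat = y[:, 0] / np.maximum(y.sum(axis=1), 1) if self.family == "binomial" else y
        if np.ptp(np.asarray(yflat, dtype=float)) == 0:
            return node
        viable = self._viable_candidates(X, kinds, candidates)
        if not viable:
            return node

        hp = HierarchicalPartitioner(
            family=self.family,
            n_rand=self.n_rand,
            random_state=np.random.default_rng(rng.integers(2**31)),
            kinds=kinds,
        ).fit(X[viable], y)
        z = hp.z_
        # exact permutation p-values with Bonferroni across the m candidates:
        # the null distribution of I is right-skewed, so a normal z cutoff
        # under-controls the per-node false-split rate
        p_crit = self.alpha / len(viable)
        passing = hp.perm_p_[hp.perm_p_ <= p_crit]
        if passing.empty:
            return node
        # most significant variable: smallest permutation p, ties by z
        best_p = passing.min()
        tied = passing.index[passing == best_p]
        var = z[tied].idxmax()
        node.split_var = var
        node.z = float(z[var])
        node.pct = float(hp.pct_[var])
        node.split_kind = "categorical" if kinds[var] in ("categorical", "binary") else "quantitative"

        remaining = [c for c in candidates if c != var]
        if node.split_kind == "quantitative":
            vals = X[var].to_numpy(dtype=float)
            med = float(np.median(vals))
            node.threshold = med
            groups = {"le": vals <= med, "gt": vals > med}
        else:
            col = X[var].astype(str)
            groups = {lv: (col == lv).to_numpy() for lv in dict.fromkeys(col)}
        for key, mask in groups.items():
            if mask.sum() == 0:
                log.info("dropping empty child %r of split on %r", key, var)
                continue
            node.children[key] = self._grow(
                X[mask], y[mask], kinds, remaining, depth + 1, rng
            )
        return node

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of named predictors")
        kinds = self.kinds
        if kinds is None:
            from .hierpart import infer_kinds

            kinds = infer_kinds(X)
        if self.family == "binomial":
            yarr = np.asarray(y, dtype=float)
            if yarr.ndim != 2 or yarr.shape[1] != 2:
                raise ValueError("binomial response must be (n, 2) successes/failures")
        else:
            yarr = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self.kinds_ = dict(kinds)
        self.root_ = self._grow(X, yarr, kinds, list(X.columns), 0, rng)
        means = {}
        for leaf in self.root_.leaves():
            for m in leaf.members:
                means[m] = leaf.mean
        self.leaf_means_ = pd.Series(means).reindex(X.index)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf mean for each row, routed down the fitted splits."""
        out = np.empty(len(X))
        for i, (_, row) in enumerate(X.iterrows()):
            node = self.root_
            while not node.is_leaf:
                if node.split_kind == "quantitative":
                    key = "le" if float(row[node.split_var]) <= node.threshold else "gt"
                else:
                    key = str(row[node.split_var])
                if key not in node.children:
                    break  # unseen level: stop at this node
                node = node.children[key]
            out[i] = node.mean
        return out

    def depth(self) -> int:
        return max(leaf.depth for leaf in self.root_.leaves())

    def n_leaves(self) -> int:
        return sum(1 for _ in self.root_.leaves())

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.root_.to_dict(), **kwargs)

    def render(self) -> str:
        return self.root_.render()


def grow_tree(
    dataset: Dataset,
    response: str,
    predictors: list[str] | None = None,
    min_node: int = 10,
    n_rand: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SuccessivePartitionTree:
    """Grow a trait tree for a survey response.

    ``response='abund'`` models total bromeliad count per tree (Poisson,
    hosts and non-hosts alike); ``response='dist'`` models the trunk share
    AB_dst (binomial over (trunk, branch) counts, hosts only).
    """
    if response not in ("abund", "dist"):
        raise ValueError(f"unknown response {response!r}")
    X = dataset.predictor_frame()
    kinds = dataset.predictor_kinds()
    if predictors is not None:
        X = X[list(predictors)]
        kinds = {k: kinds[k] for k in predictors}
    if response == "abund":
        y = dataset.trees["a_total"].to_numpy(dtype=float)
        family = "poisson"
    else:
        hosts = dataset.trees["a_total"] > 0
        X = X[hosts]
        y = dataset.trees.loc[hosts, ["a_trunk", "a_branch"]].to_numpy(dtype=float)
        family = "binomial"
    est = SuccessivePartitionTree(
        family=family, min_node=min_node, n_rand=n_rand, alpha=alpha,
        random_state=seed, kinds=kinds,
    )
    return est.fit(X, y)


# ---------------------------------------------------------------------------
# Host patterns


@dataclasses.dataclass
class PatternThresholds:
    """Leaf-mean thresholds for the four host patterns.

    Best hosts sit in abundance leaves averaging above ``best_min``
    individuals, worst hosts below ``worst_max``; trunk (branches) hosts
    sit in distribution leaves averaging above ``trunk_min_share`` (below
    ``branches_max_share``) trunk share.
    """

    best_min: float = 400.0
    worst_max: float = 10.0
    trunk_min_share: float = 0.9
    branches_max_share: float = 0.1

    def __post_init__(self) -> None:
        if not self.worst_max < self.best_min:
            raise ValueError("worst_max must be < best_min")
        if not self.branches_max_share < self.trunk_min_share:
            raise ValueError("branches_max_share must be < trunk_min_share")


def assign_patterns(
    abund_tree: SuccessivePartitionTree,
    dist_tree: SuccessivePartitionTree,
    thresholds: PatternThresholds | None = None,
) -> pd.DataFrame:
    """Boolean best/worst/trunk/branches assignment per tree.

    Trees absent from the distribution tree (non-hosts) get trunk and
    branches False; intermediate leaves assign no label.
    """
    thresholds = thresholds or PatternThresholds()
    abund_means = abund_tree if isinstance(abund_tree, pd.Series) else abund_tree.leaf_means_
    dist_means = dist_tree if isinstance(dist_tree, pd.Series) else dist_tree.leaf_means_
    missing = set(dist_means.index) - set(abund_means.index)
    if missing:
        raise ValueError(f"trees in distribution tree but not abundance tree: {sorted(missing)[:5]}")
    out = pd.DataFrame(False, index=abund_means.index, columns=list(PATTERNS))
    out["best"] = abund_means > thresholds.best_min
    out["worst"] = abund_means < thresholds.worst_max
    trunk = dist_means > thresholds.trunk_min_share
    branches = dist_means < thresholds.branches_max_share
    out.loc[trunk.index[trunk], "trunk"] = True
    out.loc[branches.index[branches], "branches"] = True
    return out


def pattern_overlap_counts(
    assignment: pd.DataFrame,
    species_of: Mapping,
) -> dict[tuple[str, ...], int]:
    """Species counts per exact combination of host patterns.

    For every tree species, the union of patterns over its individuals is
    taken; species with at least one labelled individual are counted under
    that exact combination (single-pattern combinations are the exclusive
    species of an Euler diagram).
    """
    combos: dict[tuple[str, ...], int] = {}
    by_species: dict[str, set] = {}
    for tid, row in assignment.iterrows():
        sp = species_of[tid]
        pats = {p for p in PATTERNS if row[p]}
        if pats:
            by_species.setdefault(sp, set()).update(pats)
    for pats in by_species.values():
        key = tuple(sorted(pats))
        combos[key] = combos.get(key, 0) + 1
    return combos
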