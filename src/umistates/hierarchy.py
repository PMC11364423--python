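"""Hierarchical merging of cellstates into a binary tree of higher-order clusters.

The pairwise similarity of two clusters is the likelihood ratio of the
partition with the two merged versus kept separate; the tree distance is
minus its logarithm.  The most similar pair (maximal merge log-ratio) is
merged iteratively.  Only similarities involving the newly merged cluster
need recomputation, because a pair's ratio depends only on the two clusters'
own counts and the prior.  At the optimizer's output every ratio is negative
(merging would otherwise have improved the partition), but after a few
merges positive ratios can reappear; heights are therefore monotonicised for
display while raw values are preserved.

The prior strength is held fixed (as fitted by the optimizer) throughout
tree building.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .data import DataError, DirichletPrior, Partition, build_partition

logger = logging.getLogger(__name__)

__all__ = ["MergeTree", "build_merge_tree", "cut_tree", "to_newick"]


@dataclass
class Merge:
    step: int
    child_a: int  # node ids; leaves are 0..K-1, internal K..2K-2
    child_b: int
    log_ratio: float
    height: float  # cumulative sum of -log_ratio (raw, may decrease)


@dataclass
class MergeTree:
    """Binary merge tree over the cellstates of a partition.

    Leaves are the partition's clusters (node ids ``0..K-1``); internal node
    ``K+t`` is created by merge step ``t``.  ``merges`` is in merge order;
    there are ``K-1`` merges for ``K`` leaves.
    """

    partition: Partition
    prior: DirichletPrior
    merges: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.partition.n_clusters

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1 if self.merges else 0

    def children(self, node: int):
        t = node - self.n_leaves
        if t < 0:
            return None
        return self.merges[t].child_a, self.merges[t].child_b

    def leaves_under(self, node: int) -> list:
        """Leaf node ids in the subtree rooted at ``node``."""
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            ch = self.children(nd)
            if ch is None:
                out.append(nd)
            else:
                stack.extend(ch)
        return sorted(out)

    def branch_sides(self, node: int):
        """Leaf sets under the two children of an internal node."""
        ch = self.children(node)
        if ch is None:
            raise DataError(f"node {node} is a leaf")
        return self.leaves_under(ch[0]), self.leaves_under(ch[1])

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": m.step,
                    "child_a": m.child_a,
                    "child_b": m.child_b,
                    "merge_log_ratio": m.log_ratio,
                    "cumulative_height": m.height,
                }
                for m in self.merges
            ]
        )


def _ratio_table(prior: DirichletPrior, gene_totals_max: int, kmax=4096):
    theta = prior.concentrations
    km = int(max(1, min(kmax, gene_totals_max + 2)))
    return theta, _kernels.build_lgamma_table(theta, km)


def build_merge_tree(partition: Partition, prior: DirichletPrior) -> MergeTree:
    """Iteratively merge the most similar pair of clusters into a binary tree.

    Ties (equal log-ratios) are broken toward the lexicographically smallest
    node-id pair.  Conservation holds at every internal node: its counts are
    the sum of its descendant leaves'.
    """
    k = partition.n_clusters
    tree = MergeTree(partition, prior)
    if k < 2:
        logger.warning("merge tree of a partition with < 2 clusters is trivial")
        return tree

    theta, table = _ratio_table(prior, int(partition.matrix.gene_totals.max()))
    ts = prior.concentration_sum

    counts = {i: partition.cluster_counts[i].copy() for i in range(k)}
    totals = {i: int(partition.cluster_totals[i]) for i in range(k)}
    # cache pair ratios; recompute only pairs involving the newly merged node
    ccnt = np.vstack([counts[i] for i in range(k)])
    ctot = np.array([totals[i] for i in range(k)], dtype=np.int64)
    ratio = {}
    ids = list(range(k))
    arr_index = {i: i for i in range(k)}  # node id -> row in ccnt

    def pair_ratio(a, b):
        return _kernels._pair_merge_ratio(
            ccnt, ctot, theta, ts, table, arr_index[a], arr_index[b]
        )

    for i in range(k):
        for j in range(i + 1, k):
            ratio[(i, j)] = pair_ratio(i, j)

    height = 0.0
    nrows = ccnt.shape[0]
    for step in range(k - 1):
        (a, b), r = max(
            ratio.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1])
        )
        new_id = k + step
        height += -r
        tree.merges.append(Merge(step, a, b, float(r), float(height)))
        # merged node's counts = sum of children (appended as a new row)
        merged = ccnt[arr_index[a]] + ccnt[arr_index[b]]
        ccnt = np.vstack([ccnt, merged[None, :]])
        ctot = np.append(ctot, ctot[arr_index[a]] + ctot[arr_index[b]])
        arr_index[new_id] = nrows
        nrows += 1
        ids = [i for i in ids if i not in (a, b)]
        for key in [key for key in ratio if a in key or b in key]:
            del ratio[key]
        for other in ids:
            ratio[(min(other, new_id), max(other, new_id))] = pair_ratio(
                other, new_id
            )
        ids.append(new_id)
    return tree


def cut_tree(tree: MergeTree, k: int) -> Partition:
    """Partition of the cells into ``k`` higher-order clusters.

    Applies the first ``n_leaves - k`` merges (equivalently undoes the last
    ``k - 1``); ``k = n_leaves`` reproduces the input partition, ``k = 1``
    puts all cells in one cluster.  Successive cuts are nested.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise DataError(f"k must be in [1, {n}], got {k}")
    membership = {i: i for i in range(n)}
    for m in tree.merges[: n - k]:
        rep = n + m.step
        for leaf in tree.leaves_under(rep):
            membership[leaf] = rep
    labels = [membership[leaf] for leaf in tree.partition.assignment]
    return build_partition(tree.partition.matrix, labels)


def _display_heights(tree: MergeTree) -> dict:
    """Monotone node heights: cumulative maximum of the raw heights."""
    heights = {i: 0.0 for i in range(tree.n_leaves)}
    running = 0.0
    for m in tree.merges:
        running = max(running, m.height)
        heights[tree.n_leaves + m.step] = running
    return heights


def to_newick(tree: MergeTree, branch_length_mode: str = "monotone") -> str:
    """Newick text of the tree; leaf names are the cellstate labels.

    ``branch_length_mode``: ``"monotone"`` (default) uses display heights
    made non-decreasing by cumulative maximum (raw values stay available in
    :meth:`MergeTree.merge_table`); ``"raw"`` uses raw cumulative heights
    (branch lengths may be negative); ``"none"`` omits branch lengths.
    """
    if branch_length_mode not in ("monotone", "raw", "none"):
        raise DataError(f"unknown branch_length_mode {branch_length_mode!r}")
    if branch_length_mode == "raw":
        heights = {i: 0.0 for i in range(tree.n_leaves)}
        for m in tree.merges:
            heights[tree.n_leaves + m.step] = m.height
    else:
        heights = _display_heights(tree)

    def name(leaf):
        lab = tree.partition.labels[leaf]
        return str(lab).replace(" ", "_").replace(",", "_").replace(":", "_")

    def render(node, parent_height):
        ch = tree.children(node)
        if ch is None:
            body = name(node)
        else:
            body = f"({render(ch[0], heights[node])},{render(ch[1], heights[node])})"
        if branch_length_mode == "none":
            return body
        return f"{body}:{parent_height - heights[node]:.6g}"

    root = tree.root
    if tree.n_leaves == 1:
        return f"{name(0)};"
    ch = tree.children(root)
    inner = f"({render(ch[0], heights[root])},{render(ch[1], heights[root])})"
    return inner + ";"
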