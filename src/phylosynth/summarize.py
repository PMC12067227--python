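"""Summaries of dated tree clouds: MCC selection and majority consensus.

A cloud of dated, taxonomically complete trees (same leaf set, varying
topology and ages) is reduced to a single tree.  The maximum clade
credibility (MCC) tree is the member maximizing the sum of log clade
frequencies over the cloud; the majority-rule consensus assembles all
clusters occurring in more than half the trees (mutually compatible by
pigeonhole).  In both cases node ages are replaced by the mean age of the
clade across the trees containing it, with child means clamped just below
their parent when sampling noise would invert them, and 2.5-97.5
percentile intervals report the age spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import dendropy
import numpy as np

from .trees import (
    TreeError,
    canonicalize,
    copy_tree,
    leaf_labels,
    leafset,
    new_internal,
    new_leaf,
    new_tree,
    node_ages_from_lengths,
    set_branch_lengths_from_ages,
)

__all__ = [
    "CladeTable",
    "clade_frequencies",
    "mcc_tree",
    "majority_consensus",
    "POSITIVITY_EPSILON",
]

# minimum parent-child age gap enforced when clamping mean ages (Myr)
POSITIVITY_EPSILON = 1e-6


@dataclass
class CladeTable:
    """Occurrence fractions and age samples per cluster across a cloud."""

    n_trees: int
    frequencies: Dict[FrozenSet[str], float] = field(default_factory=dict)
    age_samples: Dict[FrozenSet[str], List[float]] = field(default_factory=dict)


def _node_ages(tree: dendropy.Tree) -> None:
    if any(
        getattr(n, "age", None) is None for n in tree.preorder_internal_node_iter()
    ):
        node_ages_from_lengths(tree)


def clade_frequencies(trees: Sequence[dendropy.Tree]) -> CladeTable:
    """Cluster occurrence fractions and per-cluster age samples.

    The root cluster (full leaf set, frequency 1) is included so that root
    ages are summarized like any other node's.  All trees must share one
    leaf set.
    """
    if not trees:
        raise TreeError("empty tree cloud")
    leaves = leaf_labels(trees[0])
    counts: Dict[FrozenSet[str], int] = {}
    ages: Dict[FrozenSet[str], List[float]] = {}
    for tree in trees:
        if leaf_labels(tree) != leaves:
            raise TreeError("trees in the cloud have differing leaf sets")
        _node_ages(tree)
        for node in tree.preorder_internal_node_iter():
            cl = leafset(node)
            counts[cl] = counts.get(cl, 0) + 1
            ages.setdefault(cl, []).append(float(node.age))
    n = len(trees)
    return CladeTable(
        n_trees=n,
        frequencies={cl: c / n for cl, c in counts.items()},
        age_samples=ages,
    )


def _interval(samples: Sequence[float]) -> Tuple[float, float]:
    lo, hi = np.percentile(np.asarray(samples, dtype=float), [2.5, 97.5])
    return float(lo), float(hi)


def _apply_mean_ages(
    tree: dendropy.Tree, table: CladeTable
) -> Dict[FrozenSet[str], Tuple[float, float]]:
    """Mean ages (clamped for positivity) + percentile intervals per node."""
    intervals: Dict[FrozenSet[str], Tuple[float, float]] = {}
    for node in tree.preorder_internal_node_iter():
        cl = leafset(node)
        samples = table.age_samples[cl]
        age = float(np.mean(samples))
        parent = node.parent_node
        if parent is not None and age >= parent.age:
            age = parent.age - POSITIVITY_EPSILON
        node.age = age
        intervals[cl] = _interval(samples)
    for node in tree.leaf_node_iter():
        node.age = 0.0
    set_branch_lengths_from_ages(tree)
    return intervals


def mcc_tree(
    trees: Sequence[dendropy.Tree],
) -> Tuple[dendropy.Tree, Dict[FrozenSet[str], Tuple[float, float]]]:
    """Maximum clade credibility tree of a cloud.

    Selects the member tree maximizing the sum of log clade frequencies
    (ties resolved by cloud order), then replaces its node ages with
    cross-cloud clade means and attaches 2.5-97.5 percentile intervals.
    The returned topology is always a member of the input cloud.
    """
    if not trees:
        raise TreeError("empty tree cloud")
    table = clade_frequencies(trees)
    best, best_score = None, -math.inf
    for tree in trees:
        score = sum(
            math.log(table.frequencies[leafset(n)])
            for n in tree.preorder_internal_node_iter()
        )
        if score > best_score:
            best, best_score = tree, score
    out = copy_tree(best)
    intervals = _apply_mean_ages(out, table)
    canonicalize(out)
    return out, intervals


def majority_consensus(
    trees: Sequence[dendropy.Tree],
) -> Tuple[dendropy.Tree, Dict[FrozenSet[str], Tuple[float, float]]]:
    """Majority-rule consensus (clusters in > 1/2 of the cloud) with ages.

    Majority clusters are pairwise compatible (two incompatible clusters
    cannot both occur in more than half the trees); this is asserted, not
    assumed.  With no majority cluster below the root the result is a
    star tree.
    """
    if not trees:
        raise TreeError("empty tree cloud")
    table = clade_frequencies(trees)
    leaves = leaf_labels(trees[0])
    majority = [
        cl
        for cl, freq in table.frequencies.items()
        if freq > 0.5 and cl != leaves and len(cl) >= 2
    ]
    for i, a in enumerate(majority):
        for b in majority[i + 1 :]:
            assert not ((a & b) and (a - b) and (b - a)), (
                "majority clusters are not pairwise compatible"
            )
    tree = _tree_from_clusters(leaves, majority)
    intervals = _apply_mean_ages(tree, table)
    canonicalize(tree)
    return tree, intervals


def _tree_from_clusters(
    leaves: FrozenSet[str], clusters: Sequence[FrozenSet[str]]
) -> dendropy.Tree:
    """Assemble the rooted tree displaying exactly a laminar cluster family."""
    ordered = sorted(set(clusters), key=lambda c: (-len(c), tuple(sorted(c))))
    nodes: List[Tuple[FrozenSet[str], dendropy.Node]] = []
    root = new_internal([])
    nodes.append((leaves, root))
    for cl in ordered:
        node = new_internal([])
        # parent: the smallest already-placed cluster strictly containing cl
        parent = min(
            (entry for entry in nodes if cl < entry[0]),
            key=lambda entry: len(entry[0]),
        )
        parent[1].add_child(node)
        nodes.append((cl, node))
    for tip in sorted(leaves):
        parent = min(
            (entry for entry in nodes if tip in entry[0]),
            key=lambda entry: len(entry[0]),
        )
        parent[1].add_child(new_leaf(tip))
    return new_tree(root)
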