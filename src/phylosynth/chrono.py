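"""Chronogram synthesis: node-age aggregation and bladj even-spacing.

Published node ages are harvested from dated source trees by mapping each
dated source node onto the synthetic-tree node it *supports* (identical
descendant sets after restriction to the shared leaves, parent retained).
Each synthetic node thus accumulates zero, one or many age records.  A
calibration draw turns the record sets into a single age per calibrated
node -- either the per-node arithmetic mean, or a stochastic sample in
which a node with exactly one record is included with probability 1/2
(mirroring equal-probability sample-or-exclude for single dates) and a
root-to-tip sweep enforces strictly decreasing ages.  The bladj smoothing
step then fixes calibrated ages and spaces every uncalibrated node evenly
between its nearest dated ancestor and its nearest dated-or-terminal
descendants, yielding ultrametric trees with strictly positive branch
lengths.  Credible intervals attached to source ages are deliberately not
consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .conflict import align_nodes
from .trees import (
    InputTree,
    assign_node_ids,
    copy_tree,
    leaf_labels,
    leafset,
    mrca,
    set_branch_lengths_from_ages,
)

__all__ = [
    "ChronoError",
    "AgeRecord",
    "NodeAgeSet",
    "CalibrationSet",
    "collect_node_ages",
    "draw_calibrations",
    "bladj_date",
    "date_sample",
    "write_age_records",
    "read_age_records",
]


class ChronoError(ValueError):
    pass


@dataclass(frozen=True)
class AgeRecord:
    synth_node: str
    age: float
    source_tree: str
    source_node: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ChronoError(f"age record must be positive, got {self.age}")


@dataclass
class NodeAgeSet:
    """Per-node multisets of age evidence, tied to the tree they map onto."""

    tree: dendropy.Tree
    records: Dict[str, List[AgeRecord]] = field(default_factory=dict)

    def add(self, record: AgeRecord) -> None:
        self.records.setdefault(record.synth_node, []).append(record)

    def ages_of(self, node_id: str) -> List[float]:
        return [r.age for r in self.records.get(node_id, [])]

    @property
    def root_id(self) -> str:
        return self.tree.seed_node.node_id


@dataclass
class CalibrationSet:
    """A single age per calibrated node; ages strictly decrease rootward->tipward."""

    ages: Dict[str, float]


def _tree_of(obj) -> dendropy.Tree:
    return obj.tree if hasattr(obj, "tree") else obj


# ---------------------------------------------------------------------------
# Collecting evidence
# ---------------------------------------------------------------------------

def collect_node_ages(synth, dated_trees: Sequence[InputTree]) -> NodeAgeSet:
    """Map ages from dated source nodes onto the synthetic tree.

    Only *supported* alignments contribute: when the synthesis topology
    disagrees with a dated source, the conflicting source nodes simply
    yield no usable dates.
    """
    synth_tree = _tree_of(synth)
    ages = NodeAgeSet(tree=synth_tree)
    for src in dated_trees:
        if not src.node_ages:
            continue
        alignment = align_nodes(synth_tree, src)
        for pair in alignment.supported():
            age = src.node_ages.get(pair.source_node)
            if age is None or age <= 0:
                continue
            ages.add(
                AgeRecord(
                    synth_node=pair.synth_node,
                    age=float(age),
                    source_tree=src.tree_id,
                    source_node=pair.source_node,
                )
            )
    return ages


# ---------------------------------------------------------------------------
# Age record files (two-tip MRCA fingerprints)
# ---------------------------------------------------------------------------

def write_age_records(ages: NodeAgeSet, path: str) -> None:
    """Tab-separated: synth_node_fingerprint, age_mya, source_tree, source_node."""
    nodes = {n.node_id: n for n in ages.tree.preorder_internal_node_iter()}

    def fingerprint(node: dendropy.Node) -> str:
        kids = node.child_nodes()
        mins = sorted(min(leafset(k)) for k in kids)
        return f"mrca:{mins[0]}+{mins[1]}"

    with open(path, "w", encoding="utf-8") as handle:
        handle.write("synth_node_fingerprint\tage_mya\tsource_tree\tsource_node\n")
        for node_id in sorted(ages.records):
            node = nodes[node_id]
            for rec in ages.records[node_id]:
                handle.write(
                    f"{fingerprint(node)}\t{rec.age}\t{rec.source_tree}\t{rec.source_node}\n"
                )


def read_age_records(path: str, tree) -> NodeAgeSet:
    """Re-attach an age-record file to a tree via MRCA fingerprints."""
    target = _tree_of(tree)
    assign_node_ids(target) if not hasattr(target.seed_node, "node_id") else None
    ages = NodeAgeSet(tree=target)
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("synth_node_fingerprint"):
            raise ChronoError(f"{path}: not an age-record file")
        for line in handle:
            fp, age, source_tree, source_node = line.rstrip("\n").split("\t")
            if not fp.startswith("mrca:"):
                raise ChronoError(f"{path}: bad fingerprint {fp!r}")
            a, b = fp[5:].split("+")
            node = mrca(target, [a, b])
            ages.add(
                AgeRecord(
                    synth_node=node.node_id,
                    age=float(age),
                    source_tree=source_tree,
                    source_node=source_node,
                )
            )
    return ages


# ---------------------------------------------------------------------------
# Calibration draws
# ---------------------------------------------------------------------------

def draw_calibrations(
    ages: NodeAgeSet,
    mode: str = "sample",
    seed: Optional[int] = None,
) -> CalibrationSet:
    """Reduce per-node age evidence to one calibration per node.

    ``mean`` mode: per-node arithmetic mean.  ``sample`` mode: a uniform
    draw from the node's records; a node with exactly one record is
    included with probability 1/2 (the root is exempt -- it is always
    calibrated, from a uniform draw over its records, and its absence is
    an error).  In both modes a root-to-tip sweep enforces strictly
    decreasing ages: a value at or above the nearest retained ancestor's
    age triggers a redraw restricted to the valid records, or exclusion of
    the node when none are valid (in mean mode, exclusion directly).
    """
    if mode not in ("sample", "mean"):
        raise ChronoError(f"unknown calibration mode {mode!r}")
    rng = np.random.default_rng(seed)
    tree = ages.tree
    root_id = ages.root_id
    if not ages.records.get(root_id):
        raise ChronoError("root calibration required: the root has no age records")

    out: Dict[str, float] = {}
    # preorder sweep carrying the nearest retained calibrated ancestor's age
    stack: List[Tuple[dendropy.Node, float]] = [(tree.seed_node, float("inf"))]
    while stack:
        node, ceiling = stack.pop()
        drawn: Optional[float] = None
        if not node.is_leaf():
            recs = ages.ages_of(node.node_id)
            if recs:
                if mode == "mean":
                    value = float(np.mean(recs))
                    drawn = value if value < ceiling else None
                else:
                    include = True
                    if node.node_id != root_id and len(recs) == 1:
                        include = bool(rng.random() < 0.5)
                    if include:
                        value = float(recs[int(rng.integers(len(recs)))])
                        if value >= ceiling:
                            valid = [r for r in recs if r < ceiling]
                            if valid:
                                value = float(valid[int(rng.integers(len(valid)))])
                            else:
                                value = None  # type: ignore[assignment]
                        drawn = value
                if node.node_id == root_id and drawn is None:
                    raise ChronoError("root calibration required: no valid root age")
        if drawn is not None:
            out[node.node_id] = drawn
            ceiling = drawn
        for child in node.child_nodes():
            stack.append((child, ceiling))
    return CalibrationSet(ages=out)


# ---------------------------------------------------------------------------
# bladj even-spacing
# ---------------------------------------------------------------------------

def bladj_date(tree, cal: CalibrationSet) -> dendropy.Tree:
    """Smooth a topology into a chronogram by bladj even spacing.

    Calibrated ages are preserved exactly; every uncalibrated internal
    node is placed evenly between its nearest dated ancestor (which, in a
    top-down pass, is its already-aged parent) and its nearest
    calibrated-or-terminal descendant: at one step below an ancestor of
    age a, with k+1 node-steps in total down to a descendant anchor of age
    d, the node's age is a - (a - d)/(k + 1).  Among multiple descendant
    anchors the one giving the oldest age wins (minimum steps, ties broken
    by the older age, in the benign cases) -- this keeps every branch
    length strictly positive even when a shallow tip and a deeper, older
    calibration share the subtree.  Terminal taxa sit at age 0, so the
    result is ultrametric for extant tips.
    """
    source = _tree_of(tree)
    out = copy_tree(source)
    if not hasattr(out.seed_node, "node_id"):
        assign_node_ids(out)
    calibrated = dict(cal.ages)
    internal_ids = {n.node_id for n in out.preorder_internal_node_iter()}
    bad = set(calibrated) - internal_ids
    if bad:
        raise ChronoError(f"calibrations reference unknown internal nodes: {sorted(bad)}")
    root_id = out.seed_node.node_id
    if root_id not in calibrated:
        raise ChronoError("root calibration required")

    # reject non-monotone calibration sets before smoothing
    stack = [(out.seed_node, float("inf"))]
    while stack:
        node, ceiling = stack.pop()
        a = calibrated.get(getattr(node, "node_id", None))
        if a is not None:
            if a >= ceiling:
                raise ChronoError(
                    f"non-monotone calibrations: node {node.node_id} has age {a} "
                    f">= ancestor age {ceiling}"
                )
            ceiling = a
        for child in node.child_nodes():
            stack.append((child, ceiling))

    # descendant anchors: (steps, age, is_calibrated) of the first
    # calibrated-or-tip node on each downward path
    anchors: Dict[int, List[Tuple[int, float, bool]]] = {}

    def collect_anchors(node: dendropy.Node) -> None:
        out_list: List[Tuple[int, float, bool]] = []
        for child in node.child_nodes():
            if child.is_leaf():
                out_list.append((1, 0.0, False))
            elif child.node_id in calibrated:
                out_list.append((1, calibrated[child.node_id], True))
            else:
                out_list.extend((s + 1, d, c) for s, d, c in anchors[id(child)])
        anchors[id(node)] = out_list

    for node in out.postorder_internal_node_iter():
        collect_anchors(node)

    for node in out.preorder_internal_node_iter():
        if node.node_id in calibrated:
            node.age = calibrated[node.node_id]
            continue
        a = node.parent_node.age
        entries = anchors[id(node)]
        # nearest anchor by node-steps, ties broken by the older age
        s, d, _ = min(entries, key=lambda e: (e[0], -e[1]))
        age = a - (a - d) / (s + 1)
        # deeper calibrated anchors act as floors so branch lengths stay
        # strictly positive even when a shallow tip sits alongside an
        # older calibration
        for s2, d2, is_cal in entries:
            if is_cal:
                age = max(age, a - (a - d2) / (s2 + 1))
        node.age = age
    for node in out.leaf_node_iter():
        node.age = 0.0
    set_branch_lengths_from_ages(out)
    return out


# ---------------------------------------------------------------------------
# Dating a cloud of completions
# ---------------------------------------------------------------------------

def date_sample(
    completions,
    dated_trees: Sequence[InputTree],
    mode: str = "sample",
    seed: Optional[int] = None,
) -> List[dendropy.Tree]:
    """Date every tree of a completion cloud.

    Age evidence is aligned once against the shared phylogenetic core (the
    tree the completions were grafted from; grafted taxa never carry
    dates) and transferred to each completion through the core clusters.
    Each completion gets a fresh calibration draw from a derived sub-seed
    and is smoothed with bladj.
    """
    base = completions.base_tree
    if base is None:
        raise ChronoError("completion sample lacks a base tree for alignment")
    if not hasattr(base.seed_node, "node_id"):
        assign_node_ids(base)
    core_ages = collect_node_ages(base, dated_trees)
    core_clusters: Dict[str, FrozenSet[str]] = {
        n.node_id: leafset(n)
        for n in base.preorder_internal_node_iter()
        if n.node_id in core_ages.records
    }
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(completions.trees))
    dated: List[dendropy.Tree] = []
    for i, comp in enumerate(completions.trees):
        assign_node_ids(comp)  # grafted nodes have no ids yet
        comp_ages = NodeAgeSet(tree=comp)
        for node_id, cluster in core_clusters.items():
            target = mrca(comp, cluster)
            for rec in core_ages.records[node_id]:
                comp_ages.add(
                    AgeRecord(
                        synth_node=target.node_id,
                        age=rec.age,
                        source_tree=rec.source_tree,
                        source_node=rec.source_node,
                    )
                )
        cal = draw_calibrations(comp_ages, mode=mode, seed=int(sub_seeds[i]))
        dated.append(bladj_date(comp, cal))
    return dated
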