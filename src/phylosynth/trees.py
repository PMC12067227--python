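"""Rooted-tree I/O and core operations.

Every downstream stage (synthesis, conflict classification, grafting,
dating, summarising) works on *rooted* trees whose tips carry taxonomy
identifiers.  The unit of topological comparison throughout the package is
the **cluster**: the set of leaf labels descending from a rooted edge --
the rooted analogue of an unrooted bipartition.  Polytomies are treated as
soft (absence of resolution, not an assertion of simultaneous divergence).

dendropy supplies the tree container and the Newick parser/writer; the
operations here (cluster extraction, induced trees with origin tracking,
rooted Robinson-Foulds distance) are thin, rooted-semantics layers on top.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import yaml

__all__ = [
    "InputTree",
    "Ranking",
    "TreeError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tree_to_newick",
    "new_tree",
    "new_leaf",
    "new_internal",
    "rebind_taxa",
    "canonicalize",
    "leafset",
    "leaf_labels",
    "cluster_map",
    "clusters_of",
    "mrca",
    "induce_tree",
    "rf_distance",
    "collapse_duplicate_tips",
    "assign_node_ids",
    "node_ages_from_lengths",
    "set_branch_lengths_from_ages",
    "read_collection",
]


class TreeError(ValueError):
    """Raised for malformed trees, manifests, or incompatible leaf sets."""


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def new_tree(root: dendropy.Node) -> dendropy.Tree:
    """Wrap a node (with its subtree) as a rooted dendropy Tree."""
    tree = dendropy.Tree()
    tree.seed_node = root
    tree.is_rooted = True
    rebind_taxa(tree)
    return tree


def new_leaf(label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = dendropy.Taxon(label=label)
    return node


def new_internal(children: Sequence[dendropy.Node], label: Optional[str] = None) -> dendropy.Node:
    node = dendropy.Node()
    if label is not None:
        node.label = label
    for child in children:
        node.add_child(child)
    return node


def rebind_taxa(tree: dendropy.Tree) -> dendropy.Tree:
    """Give ``tree`` a fresh taxon namespace consistent with its leaf labels.

    Needed after grafting nodes across trees, which otherwise leaves taxa
    attached to foreign namespaces and confuses the Newick writer.
    """
    tns = dendropy.TaxonNamespace()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        leaf.taxon = tns.require_taxon(label=label)
    tree.taxon_namespace = tns
    return tree


def copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Structural deep copy preserving labels, branch lengths and ``age``."""

    def rec(node: dendropy.Node) -> dendropy.Node:
        if node.is_leaf():
            new = new_leaf(node.taxon.label)
        else:
            new = new_internal([rec(c) for c in node.child_nodes()], label=node.label)
        new.edge.length = node.edge.length
        if hasattr(node, "age"):
            new.age = node.age
        if hasattr(node, "node_id"):
            new.node_id = node.node_id
        return new

    return new_tree(rec(tree.seed_node))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick tree from a string.

    Trees are read with rooted semantics; an explicit ``[&U]`` rooting
    comment marks the tree unrooted and is rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a family of parse errors
        raise TreeError(f"unparseable newick: {exc}") from exc
    if tree.is_rooted is False:
        raise TreeError("tree is explicitly unrooted (no rooted interpretation)")
    tree.is_rooted = True
    return tree


def read_newick(path: str) -> dendropy.Tree:
    try:
        with open(path, "r", encoding="utf-8") as handle:
            text = handle.read()
    except OSError as exc:
        raise TreeError(f"cannot read tree file {path!r}: {exc}") from exc
    try:
        return parse_newick(text)
    except TreeError as exc:
        raise TreeError(f"{path}: {exc}") from exc


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children by their smallest descendant label (determinism)."""
    order: Dict[int, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            order[id(node)] = node.taxon.label
        else:
            kids = sorted(node.child_nodes(), key=lambda c: order[id(c)])
            node.set_child_nodes(kids)
            order[id(node)] = order[id(kids[0])]
    return tree


def tree_to_newick(tree: dendropy.Tree, *, lengths: bool = False) -> str:
    """Canonical single-line Newick serialization."""
    canonicalize(tree)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=not lengths,
        suppress_internal_node_labels=True,
    )
    return text.strip() + ("\n" if not text.endswith("\n") else "")


def write_newick(tree: dendropy.Tree, path: str, *, lengths: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(tree_to_newick(tree, lengths=lengths))


# ---------------------------------------------------------------------------
# Clusters and basic queries
# ---------------------------------------------------------------------------

def leafset(node: dendropy.Node) -> FrozenSet[str]:
    """Labels of the leaves descending from ``node`` (node itself if a leaf)."""
    return frozenset(l.taxon.label for l in node.leaf_iter())


def leaf_labels(tree: dendropy.Tree) -> FrozenSet[str]:
    return leafset(tree.seed_node)


def cluster_map(tree: dendropy.Tree) -> Dict[FrozenSet[str], dendropy.Node]:
    """Map cluster -> internal node, excluding the root cluster and tips.

    For a chain of unary nodes sharing a cluster the *lowest* node wins
    (unary chains should normally be suppressed upstream).
    """
    out: Dict[FrozenSet[str], dendropy.Node] = {}
    for node in tree.postorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        cl = leafset(node)
        out.setdefault(cl, node)
    return out


def clusters_of(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """The set of clusters of a rooted tree.

    One cluster per internal edge; the root cluster (full leaf set) and
    trivial one-leaf clusters are excluded, so a star tree has none.
    """
    return set(cluster_map(tree).keys())


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given tip labels."""
    want = frozenset(labels)
    if not want:
        raise TreeError("mrca of an empty label set")
    missing = want - leaf_labels(tree)
    if missing:
        raise TreeError(f"labels absent from tree: {sorted(missing)}")
    node = tree.seed_node
    while True:
        if node.is_leaf():
            return node
        containing = [c for c in node.child_nodes() if want & leafset(c)]
        if len(containing) == 1 and want <= leafset(containing[0]):
            node = containing[0]
        else:
            return node


# ---------------------------------------------------------------------------
# Induced trees
# ---------------------------------------------------------------------------

def induce_tree(tree: dendropy.Tree, leaves: Iterable[str]) -> dendropy.Tree:
    """Restrict ``tree`` to ``leaves``: prune, then suppress unary nodes.

    Every node of the induced tree remembers its originating node in
    ``node.orig`` (and its id, if assigned, in ``node.orig_id``) and carries
    ``node.parent_retained``: whether its original parent survived into the
    induced tree rather than being suppressed as unary.  The induced root is
    vacuously parent-retained.  Ages (``node.age``) are carried over.
    """
    keep = frozenset(leaves)
    present = keep & leaf_labels(tree)
    if not present:
        raise TreeError("induced leaf set has empty intersection with the tree")

    # count, per original node, the children with >=1 kept leaf
    kept_children: Dict[int, int] = {}
    has_kept: Dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_kept[id(node)] = node.taxon.label in present
        else:
            n = sum(1 for c in node.child_nodes() if has_kept[id(c)])
            kept_children[id(node)] = n
            has_kept[id(node)] = n > 0

    def retained(node: dendropy.Node) -> bool:
        return kept_children.get(id(node), 0) >= 2

    def rec(node: dendropy.Node) -> Optional[dendropy.Node]:
        if node.is_leaf():
            if node.taxon.label not in present:
                return None
            new = new_leaf(node.taxon.label)
        else:
            kids = [rec(c) for c in node.child_nodes()]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # suppress unary: child survives, this node does not
            new = new_internal(kids, label=node.label)
        new.orig = node
        if hasattr(node, "node_id"):
            new.orig_id = node.node_id
        if hasattr(node, "age"):
            new.age = node.age
        parent = node.parent_node
        new.parent_retained = parent is None or retained(parent)
        return new

    root = rec(tree.seed_node)
    induced = new_tree(root)
    # the induced root is vacuously parent-retained even if its original
    # parent chain was suppressed
    induced.seed_node.parent_retained = True
    return induced


# ---------------------------------------------------------------------------
# Robinson-Foulds (rooted-cluster symmetric difference)
# ---------------------------------------------------------------------------

def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric difference of the rooted cluster sets of two trees.

    Requires identical leaf sets; the rooted analogue of the classic
    Robinson-Foulds distance, counting clusters rather than bipartitions.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise TreeError(
            "leaf sets differ: only in first=%s, only in second=%s"
            % (sorted(l1 - l2), sorted(l2 - l1))
        )
    return len(clusters_of(t1) ^ clusters_of(t2))


# ---------------------------------------------------------------------------
# Tip collapsing (shared by exemplification and crosswalk lumping)
# ---------------------------------------------------------------------------

def collapse_duplicate_tips(
    tree: dendropy.Tree,
    label_map: Dict[str, Optional[str]],
) -> Tuple[dendropy.Tree, Dict[str, List[str]]]:
    """Relabel tips through ``label_map`` and collapse duplicates.

    Tips mapping to ``None`` (or absent from the map) are pruned.  When
    several tips map to the same new label, the exemplar kept is the one
    with the lexicographically smallest *original* label; the rest are
    pruned.  Unary nodes arising from pruning are suppressed.

    Returns the new tree and a report::

        {"pruned_unmapped": [...], "collapsed": [...orig labels dropped...]}
    """
    groups: Dict[str, List[str]] = {}
    unmapped: List[str] = []
    for leaf in tree.leaf_node_iter():
        orig = leaf.taxon.label
        new = label_map.get(orig)
        if new is None:
            unmapped.append(orig)
        else:
            groups.setdefault(new, []).append(orig)

    keep_orig: Dict[str, str] = {}  # original label -> new label, exemplars only
    collapsed: List[str] = []
    for new, origs in groups.items():
        origs.sort()
        keep_orig[origs[0]] = new
        collapsed.extend(origs[1:])

    def rec(node: dendropy.Node) -> Optional[dendropy.Node]:
        if node.is_leaf():
            orig = node.taxon.label
            if orig not in keep_orig:
                return None
            leaf = new_leaf(keep_orig[orig])
            if hasattr(node, "age"):
                leaf.age = node.age
            return leaf
        kids = [rec(c) for c in node.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = new_internal(kids, label=node.label)
        if hasattr(node, "age"):
            new.age = node.age
        if hasattr(node, "node_id"):
            new.node_id = node.node_id
        return new

    root = rec(tree.seed_node)
    if root is None:
        raise TreeError("no tips survive relabelling")
    return new_tree(root), {"pruned_unmapped": sorted(unmapped), "collapsed": sorted(collapsed)}


# ---------------------------------------------------------------------------
# Node ids and ages
# ---------------------------------------------------------------------------

def assign_node_ids(tree: dendropy.Tree, prefix: str = "n") -> dendropy.Tree:
    """Stable preorder ids: internal nodes get ``n<k>``; tips their label."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label
        else:
            node.node_id = f"{prefix}{i}"
            i += 1
    return tree


def node_ages_from_lengths(tree: dendropy.Tree) -> Dict[int, float]:
    """Node ages implied by branch lengths (age = max path length to a tip).

    Stores ``node.age`` and returns ``{id(node): age}``.
    """
    ages: Dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            ages[id(node)] = max(
                ages[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
        node.age = ages[id(node)]
    return ages


def set_branch_lengths_from_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Branch length = parent age - child age (tips have age 0)."""
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
            continue
        child_age = getattr(node, "age", 0.0) if not node.is_leaf() else 0.0
        node.edge.length = parent.age - child_age
    return tree


# ---------------------------------------------------------------------------
# Ranked collections
# ---------------------------------------------------------------------------

@dataclass
class InputTree:
    """A rooted input phylogeny with provenance metadata.

    ``node_ages`` maps internal-node ids to ages in Mya for dated trees.
    """

    tree_id: str
    study_id: str
    year: int
    tree: dendropy.Tree
    dated: bool = False
    demoted: bool = False
    node_ages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assign_node_ids(self.tree)
        if self.dated and not self.node_ages:
            node_ages_from_lengths(self.tree)
            self.node_ages = {
                n.node_id: n.age for n in self.tree.preorder_internal_node_iter()
            }
        elif self.node_ages:
            for n in self.tree.preorder_internal_node_iter():
                if n.node_id in self.node_ages:
                    n.age = self.node_ages[n.node_id]

    @property
    def leaves(self) -> FrozenSet[str]:
        return leaf_labels(self.tree)

    def clusters(self) -> Set[FrozenSet[str]]:
        return clusters_of(self.tree)


@dataclass
class Ranking:
    """Ordered tree ids, highest rank first; demoted ids after all others."""

    order: List[str]
    demoted: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise TreeError("ranking contains duplicate tree ids")
        seen_demoted = False
        for tid in self.order:
            if tid in self.demoted:
                seen_demoted = True
            elif seen_demoted:
                raise TreeError("demoted trees must come after all non-demoted trees")

    def rank_of(self, tree_id: str) -> int:
        return self.order.index(tree_id)

    def sort_trees(self, trees: Sequence[InputTree]) -> List[InputTree]:
        by_id = {t.tree_id: t for t in trees}
        return [by_id[tid] for tid in self.order if tid in by_id]


def default_ranking(entries: Sequence[Tuple[str, int, bool]]) -> Ranking:
    """Rank by descending year, manifest order breaking ties; demoted last."""
    indexed = list(enumerate(entries))
    normal = [(i, e) for i, e in indexed if not e[2]]
    demoted = [(i, e) for i, e in indexed if e[2]]
    key = lambda item: (-item[1][1], item[0])
    order = [e[0] for _, e in sorted(normal, key=key)] + [
        e[0] for _, e in sorted(demoted, key=key)
    ]
    return Ranking(order=order, demoted={e[0] for _, e in demoted})


def read_collection(manifest_path: str) -> Tuple[List[InputTree], Ranking]:
    """Read a ranked tree collection from a YAML manifest.

    The manifest lists one record per tree with fields ``file``, ``tree_id``,
    ``study_id``, ``year``, ``dated``, ``demoted``; paths are relative to the
    manifest.  The default ranking is descending publication year with
    manifest order breaking ties, demoted trees (e.g. sparse supermatrix
    supertrees) placed after all others.
    """
    with open(manifest_path, "r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "trees" not in doc:
        raise TreeError(f"{manifest_path}: manifest must have a top-level 'trees' list")
    base = os.path.dirname(os.path.abspath(manifest_path))
    trees: List[InputTree] = []
    entries: List[Tuple[str, int, bool]] = []
    for rec in doc["trees"]:
        for key in ("file", "tree_id", "year"):
            if key not in rec:
                raise TreeError(f"{manifest_path}: tree record missing '{key}': {rec}")
        path = rec["file"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        tree = read_newick(path)
        it = InputTree(
            tree_id=str(rec["tree_id"]),
            study_id=str(rec.get("study_id", rec["tree_id"])),
            year=int(rec["year"]),
            tree=tree,
            dated=bool(rec.get("dated", False)),
            demoted=bool(rec.get("demoted", False)),
        )
        trees.append(it)
        entries.append((it.tree_id, it.year, it.demoted))
    return trees, default_ranking(entries)
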