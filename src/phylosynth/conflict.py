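"""Tree-to-tree alignment and support/conflict classification.

The central notion: induce the synthetic tree down to the leaf set it
shares with a source tree, suppressing unary nodes.  A synthetic node X is
*aligned* to a source node Y when they are ancestors of exactly the same
species in that induced setting, and *supported* by Y when, additionally,
X's parent survived the induction (was not suppressed as unary).  The
induced root is treated as parent-retained vacuously, so published root
ages can map.  The same restriction logic classifies every synthetic edge
against a source tree as supporting / conflicting / compatible /
uninformative, and drives taxon monophyly reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import dendropy

from .taxa import Taxonomy
from .trees import InputTree, TreeError, induce_tree, leaf_labels, leafset, mrca

__all__ = [
    "AlignedPair",
    "NodeAlignment",
    "align_nodes",
    "classify_edges",
    "monophyly_report",
]

TreeLike = Union[dendropy.Tree, "object"]  # SynthTree quacks via .tree


def _tree_of(obj: TreeLike) -> dendropy.Tree:
    return obj.tree if hasattr(obj, "tree") else obj


@dataclass(frozen=True)
class AlignedPair:
    synth_node: str
    source_node: str
    relation: str  # "aligned" | "supported"


@dataclass
class NodeAlignment:
    pairs: List[AlignedPair]

    def supported(self) -> List[AlignedPair]:
        return [p for p in self.pairs if p.relation == "supported"]

    def by_synth_node(self) -> Dict[str, AlignedPair]:
        return {p.synth_node: p for p in self.pairs}


def _shared_leaves(synth: dendropy.Tree, source: dendropy.Tree) -> FrozenSet[str]:
    shared = leaf_labels(synth) & leaf_labels(source)
    if len(shared) < 2:
        raise TreeError(
            f"fewer than 2 shared leaves between synthesis and source ({len(shared)})"
        )
    return shared


def align_nodes(synth: TreeLike, source: InputTree) -> NodeAlignment:
    """Align synthetic-tree nodes to source-tree nodes by descendant sets.

    Both trees are restricted to their shared leaves.  A pair (X, Y) with
    identical descendant sets is ``aligned``; it is upgraded to
    ``supported`` when X's parent was retained in the induced synthetic
    tree.  Each synthetic node aligns to at most one source node.
    """
    synth_tree = _tree_of(synth)
    shared = _shared_leaves(synth_tree, source.tree)
    ind_synth = induce_tree(synth_tree, shared)
    ind_source = induce_tree(source.tree, shared)

    source_by_cluster: Dict[FrozenSet[str], dendropy.Node] = {}
    for node in ind_source.preorder_internal_node_iter():
        source_by_cluster[leafset(node)] = node
    # the restricted source root also aligns (full shared set)
    source_by_cluster.setdefault(leafset(ind_source.seed_node), ind_source.seed_node)

    pairs: List[AlignedPair] = []
    for node in ind_synth.preorder_internal_node_iter():
        cl = leafset(node)
        hit = source_by_cluster.get(cl)
        if hit is None:
            continue
        relation = "supported" if getattr(node, "parent_retained", False) else "aligned"
        pairs.append(
            AlignedPair(
                synth_node=getattr(node, "orig_id", "") or "",
                source_node=getattr(hit, "orig_id", "") or "",
                relation=relation,
            )
        )
    return NodeAlignment(pairs=pairs)


def classify_edges(synth: TreeLike, source: InputTree) -> Dict[str, str]:
    """Classify every internal synthetic edge against one source tree.

    Restricted to the shared leaves, an edge with cluster S is:

    - ``uninformative`` if fewer than 2 shared leaves fall below it or none
      fall outside it;
    - ``supports`` if some source cluster equals S exactly and the edge is
      the parent-retained representative of its restriction;
    - ``conflicts`` if some source cluster overlaps S with neither
      containing the other;
    - ``compatible`` otherwise (nested or disjoint with every source
      cluster, or an exact match without parent retention).
    """
    synth_tree = _tree_of(synth)
    shared = _shared_leaves(synth_tree, source.tree)
    ind_synth = induce_tree(synth_tree, shared)
    ind_source = induce_tree(source.tree, shared)
    source_leafset = leafset(ind_source.seed_node)

    source_clusters = set()
    for node in ind_source.preorder_internal_node_iter():
        if node is ind_source.seed_node:
            continue
        source_clusters.add(leafset(node))

    # synth nodes that are the retained representative of their restriction
    supports_rep: Dict[str, FrozenSet[str]] = {}
    for node in ind_synth.preorder_internal_node_iter():
        if getattr(node, "parent_retained", False) and node is not ind_synth.seed_node:
            supports_rep[getattr(node, "orig_id", "")] = leafset(node)

    out: Dict[str, str] = {}
    for node in synth_tree.preorder_internal_node_iter():
        if node is synth_tree.seed_node:
            continue
        nid = getattr(node, "node_id", "")
        restricted = leafset(node) & shared
        outside = source_leafset - restricted
        if len(restricted) < 2 or len(outside) < 1:
            out[nid] = "uninformative"
            continue
        if restricted in source_clusters and supports_rep.get(nid) == restricted:
            out[nid] = "supports"
            continue
        conflict = any(
            (restricted & t) and (restricted - t) and (t - restricted)
            for t in source_clusters
        )
        out[nid] = "conflicts" if conflict else "compatible"
    return out


def monophyly_report(
    synth: TreeLike,
    taxonomy: Taxonomy,
    rank: str = "genus",
) -> Tuple[float, Dict[str, bool]]:
    """Percent of taxa at a rank that are non-monophyletic in the synthesis.

    A taxon is monophyletic iff the MRCA of its sampled member species has
    exactly those species as leaf descendants.  Taxa with fewer than two
    sampled members are excluded from the denominator.  Returns
    ``(pct_non_monophyletic, {uid: is_monophyletic})``.
    """
    synth_tree = _tree_of(synth)
    tips = leaf_labels(synth_tree)
    verdicts: Dict[str, bool] = {}
    for uid in taxonomy.taxa_at_rank(rank):
        members = taxonomy.species_under(uid) & tips
        if len(members) < 2:
            continue
        node = mrca(synth_tree, members)
        verdicts[uid] = leafset(node) == members
    if not verdicts:
        return 0.0, verdicts
    broken = sum(1 for ok in verdicts.values() if not ok)
    return 100.0 * broken / len(verdicts), verdicts
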