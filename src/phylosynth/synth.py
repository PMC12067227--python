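"""Supertree synthesis: greedy ranked assembly over a taxonomic backbone.

The synthesis combines a ranked list of rooted input phylogenies with a
reference taxonomy.  Input tips are first *exemplified* to species-level
units.  Named taxa that are "uncontested" -- whose species set conflicts
with no cluster of any input tree -- decompose the problem into nested
subproblems.  Within each subproblem, clusters are considered tree by tree
in rank order (within a tree from root to tips) and greedily accepted when
they remain jointly satisfiable with everything accepted so far; joint
satisfiability is decided by rooted-triplet consistency using the Aho
BUILD algorithm over the accumulated cluster constraints.  Taxonomic
evidence is always ranked last, below every input phylogeny, so taxonomy
can never displace an input-tree cluster.  Each edge of the output carries
``supported_by`` / ``conflicts_with`` annotations pointing back at input
tree nodes, making the provenance of every branch traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

from .taxa import Taxonomy
from .trees import (
    InputTree,
    Ranking,
    TreeError,
    assign_node_ids,
    canonicalize,
    cluster_map,
    collapse_duplicate_tips,
    induce_tree,
    leaf_labels,
    leafset,
    new_internal,
    new_leaf,
    new_tree,
    tree_to_newick,
)

__all__ = [
    "SynthError",
    "Constraint",
    "EdgeAnnotation",
    "Subproblem",
    "SynthTree",
    "exemplify",
    "find_uncontested",
    "solve_subproblem",
    "synthesize",
    "build_from_constraints",
    "constraints_compatible",
]

TAXONOMY_SOURCE_PREFIX = "taxonomy:"


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Exemplification
# ---------------------------------------------------------------------------

def exemplify(itree: InputTree, taxonomy: Taxonomy) -> InputTree:
    """Map tips to species-level units and collapse duplicates.

    Tips below species rank are relabelled to their species-rank ancestor;
    several tips mapping to one species are reduced to a single exemplar
    (the lexicographically smallest original label).  Tips that cannot be
    mapped into the taxonomy are pruned.  A tree left with fewer than two
    tips is uninformative and rejected.
    """
    mapping: Dict[str, Optional[str]] = {}
    for label in sorted(itree.leaves):
        if label in taxonomy.records:
            mapping[label] = taxonomy.species_ancestor(label)
        else:
            mapping[label] = None
    try:
        new, report = collapse_duplicate_tips(itree.tree, mapping)
    except TreeError as exc:
        raise SynthError(
            f"tree {itree.tree_id!r} uninformative after exemplification: {exc}"
        ) from exc
    if len(leaf_labels(new)) < 2:
        raise SynthError(f"tree {itree.tree_id!r} uninformative after exemplification")
    out = InputTree(
        tree_id=itree.tree_id,
        study_id=itree.study_id,
        year=itree.year,
        tree=new,
        dated=False,  # ages re-attached below from carried-over node ages
        demoted=itree.demoted,
    )
    if itree.dated:
        node_ages = {}
        for node in out.tree.preorder_internal_node_iter():
            if getattr(node, "age", None) is not None:
                node_ages[node.node_id] = node.age
        out.dated = True
        out.node_ages = node_ages
    out.exemplify_report = report
    return out


# ---------------------------------------------------------------------------
# Cluster constraints and the BUILD algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    """A rooted cluster from a source tree, as a triplet-generating constraint.

    ``include`` must form a clade relative to ``exclude`` (the rest of the
    source tree's leaves): equivalently, the rooted triplets ab|c for all
    a, b in include and c in exclude.
    """

    include: FrozenSet[str]
    exclude: FrozenSet[str]
    tree_id: str
    node_id: str
    is_taxonomy: bool = False

    @property
    def context(self) -> FrozenSet[str]:
        return self.include | self.exclude

    @property
    def source(self) -> Tuple[str, str]:
        return (self.tree_id, self.node_id)


def _build(S: FrozenSet[str], constraints: Sequence[Constraint]) -> Optional[dendropy.Node]:
    """Aho BUILD over cluster constraints; ``None`` signals inconsistency."""
    if len(S) == 1:
        return new_leaf(next(iter(S)))
    relevant = [c for c in constraints if len(c.include & S) >= 2]
    active = [c for c in relevant if c.exclude & S]
    parent: Dict[str, str] = {x: x for x in S}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in active:
        members = sorted(c.include & S)
        head = members[0]
        for other in members[1:]:
            ra, rb = find(head), find(other)
            if ra != rb:
                parent[rb] = ra
    comps: Dict[str, Set[str]] = {}
    for x in S:
        comps.setdefault(find(x), set()).add(x)
    groups = sorted(comps.values(), key=min)
    if len(groups) == 1:
        if active:
            return None  # connected with live constraints: triplet conflict
        groups = [{x} for x in sorted(S)]  # no evidence: polytomy
    kids = []
    for group in groups:
        kid = _build(frozenset(group), relevant)
        if kid is None:
            return None
        kids.append(kid)
    if len(kids) == 1:
        return kids[0]
    return new_internal(kids)


def constraints_compatible(constraints: Sequence[Constraint], S: FrozenSet[str]) -> bool:
    """True iff some rooted tree on S displays every constraint."""
    if not S:
        return True
    return _build(S, constraints) is not None


def build_from_constraints(
    constraints: Sequence[Constraint], S: FrozenSet[str]
) -> dendropy.Tree:
    root = _build(S, constraints)
    if root is None:
        raise SynthError("constraint set is not jointly satisfiable")
    return new_tree(root)


# ---------------------------------------------------------------------------
# Uncontested decomposition
# ---------------------------------------------------------------------------

@dataclass
class Subproblem:
    """A self-contained synthesis unit rooted at an uncontested named taxon.

    ``leafset`` holds species ids; nested uncontested taxa are collapsed to
    a single representative species each (``child_subs`` maps the
    representative back to its subproblem).  ``restricted_trees`` are the
    ranked input trees induced onto the leafset; ``taxonomy_tree`` spans the
    leafset with internal nodes labelled by taxon uid.
    """

    root_taxon: Optional[str]  # None for the artificial root subproblem
    leafset: FrozenSet[str]
    restricted_trees: List[Tuple[str, dendropy.Tree]]
    taxonomy_tree: dendropy.Tree
    span: FrozenSet[str] = frozenset()
    child_subs: Dict[str, "Subproblem"] = field(default_factory=dict)


def _cluster_conflicts(a: FrozenSet[str], b: FrozenSet[str]) -> bool:
    """Overlap with neither containing the other."""
    return bool(a & b) and bool(a - b) and bool(b - a)


def _contested_taxa(
    taxonomy: Taxonomy, ex_trees: Sequence[InputTree]
) -> Dict[str, bool]:
    tree_info = []
    for t in ex_trees:
        tree_info.append((t.leaves, t.clusters()))
    contested: Dict[str, bool] = {}
    for uid in taxonomy.named_internal_taxa():
        span = taxonomy.species_under(uid)
        hit = False
        for leaves, clusters in tree_info:
            restricted = span & leaves
            if len(restricted) < 1:
                continue
            for cl in clusters:
                if _cluster_conflicts(restricted, cl):
                    hit = True
                    break
            if hit:
                break
        contested[uid] = hit
    return contested


def find_uncontested(
    taxonomy: Taxonomy, ex_trees: Sequence[InputTree]
) -> List[Subproblem]:
    """Decompose the synthesis problem at uncontested named taxa.

    Every uncontested named taxon with two or more species becomes a
    subproblem; inside a subproblem, nested uncontested taxa are collapsed
    to representative species.  Contested taxa are dissolved (their species
    flow into the enclosing subproblem, though their clusters remain as
    taxonomy evidence).  An artificial root subproblem covers the remaining
    top-level structure, so every species belongs to exactly one
    subproblem.  The returned list is in postorder (root subproblem last).
    """
    contested = _contested_taxa(taxonomy, ex_trees)
    subs: List[Subproblem] = []

    def rep_of(span: FrozenSet[str]) -> str:
        return min(span)

    def make(uid: str, root_taxon: Optional[str]) -> Subproblem:
        items: List[Tuple[str, FrozenSet[str], Optional[Subproblem]]] = []

        def collect(u: str) -> None:
            for child in taxonomy.children(u):
                rec = taxonomy.records[child]
                if rec.rank == "species":
                    items.append((child, frozenset([child]), None))
                    continue
                span = taxonomy.species_under(child)
                if not span:
                    continue
                if len(span) >= 2 and not contested[child]:
                    sub = make(child, child)
                    items.append((rep_of(span), span, sub))
                elif len(span) == 1:
                    sp = next(iter(span))
                    items.append((sp, span, None))
                else:
                    collect(child)

        collect(uid)
        reps = frozenset(rep for rep, _, _ in items)
        span_all = frozenset().union(*(s for _, s, _ in items)) if items else frozenset()
        rep_map: Dict[str, str] = {}
        for rep, span, _ in items:
            for sp in span:
                rep_map[sp] = rep

        restricted: List[Tuple[str, dendropy.Tree]] = []
        for t in ex_trees:
            labmap = {lv: rep_map.get(lv) for lv in t.leaves}
            mapped = {v for v in labmap.values() if v is not None}
            if len(mapped) < 2:
                continue
            rt, _ = collapse_duplicate_tips(t.tree, labmap)
            restricted.append((t.tree_id, rt))

        taxonomy_tree = _sub_taxonomy_tree(taxonomy, uid, {r: s for r, s, _ in
                                                           ((rep, span, cs) for rep, span, cs in items)})
        sub = Subproblem(
            root_taxon=root_taxon,
            leafset=reps,
            restricted_trees=restricted,
            taxonomy_tree=taxonomy_tree,
            span=span_all,
            child_subs={rep_of(s): cs for _, s, cs in items if cs is not None},
        )
        subs.append(sub)
        return sub

    make(taxonomy.root_uid, None)
    return subs


def _sub_taxonomy_tree(
    taxonomy: Taxonomy, root_uid: str, item_spans: Dict[str, FrozenSet[str]]
) -> dendropy.Tree:
    """Taxonomy induced on a subproblem: items are leaves, named taxa nodes.

    ``item_spans`` maps each item's representative to its species span;
    taxa fully inside one item are invisible, taxa spanning several items
    (including contested ones) appear as internal nodes labelled by uid.
    """
    rep_by_species: Dict[str, str] = {}
    for rep, span in item_spans.items():
        for sp in span:
            rep_by_species[sp] = rep

    def rec(uid: str) -> Optional[dendropy.Node]:
        rec_ = taxonomy.records[uid]
        span = taxonomy.species_under(uid)
        reps_here = {rep_by_species[sp] for sp in span if sp in rep_by_species}
        if not reps_here:
            return None
        if len(reps_here) == 1:
            rep = next(iter(reps_here))
            # taxon fully inside one item (or is the item): a single leaf,
            # but only emit it at the shallowest taxon covering it
            if span >= item_spans[rep]:
                return new_leaf(rep)
            return new_leaf(rep)
        kids = [rec(c) for c in taxonomy.children(uid)]
        kids = [k for k in kids if k is not None]
        # deduplicate leaves that surface through several children chains
        seen: Set[str] = set()
        uniq = []
        for k in kids:
            labels = leafset(k)
            if len(labels) == 1 and next(iter(labels)) in seen:
                continue
            seen |= labels
            uniq.append(k)
        if len(uniq) == 1:
            return uniq[0]
        node = new_internal(uniq, label=uid)
        node.node_id = uid
        return node

    root = rec(root_uid)
    if root is None:
        root = new_internal([new_leaf(r) for r in sorted(item_spans)], label=root_uid)
        root.node_id = root_uid
    tree = new_tree(root)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.node_id = node.taxon.label
        elif not hasattr(node, "node_id"):
            node.node_id = node.label or ""
    return tree


# ---------------------------------------------------------------------------
# Greedy subproblem solving
# ---------------------------------------------------------------------------

def _ranked_constraints(sub: Subproblem, taxonomy_version: str) -> List[Constraint]:
    out: List[Constraint] = []

    def tree_constraints(tree_id: str, tree: dendropy.Tree, is_tax: bool) -> None:
        L = leaf_labels(tree)
        entries = []
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node:
                continue
            cl = leafset(node)
            if 2 <= len(cl) < len(L):
                nid = getattr(node, "node_id", None) or node.label or ""
                entries.append((cl, nid))
        # root-to-tip: larger clusters first, lexicographic tie-break
        entries.sort(key=lambda e: (-len(e[0]), tuple(sorted(e[0]))))
        for cl, nid in entries:
            out.append(Constraint(cl, L - cl, tree_id, str(nid), is_tax))

    for tree_id, rt in sub.restricted_trees:
        tree_constraints(tree_id, rt, False)
    tree_constraints(TAXONOMY_SOURCE_PREFIX + taxonomy_version, sub.taxonomy_tree, True)
    return out


def solve_subproblem(sub: Subproblem, taxonomy_version: str = "") -> dendropy.Tree:
    """Greedy rank-order assembly of one subproblem.

    Clusters are taken tree by tree in rank order, root-to-tip within a
    tree, taxonomy last.  A cluster is accepted iff it stays jointly
    satisfiable (BUILD) with everything accepted before it.  The returned
    tree displays exactly the accepted set; each node carries
    ``supported_by`` (accepted sources whose cluster it realises) and
    ``conflicts_with`` (sources rejected with this edge as the blocking,
    highest-ranked incompatible acceptance).
    """
    S = sub.leafset
    ranked = _ranked_constraints(sub, taxonomy_version)
    accepted: List[Constraint] = []
    rejections: List[Tuple[Constraint, Optional[Constraint]]] = []
    for c in ranked:
        if constraints_compatible(accepted + [c], S):
            accepted.append(c)
        else:
            blocker: Optional[Constraint] = None
            for k in range(1, len(accepted) + 1):
                if not constraints_compatible(accepted[:k] + [c], S):
                    blocker = accepted[k - 1]
                    break
            rejections.append((c, blocker))

    tree = build_from_constraints(accepted, S)
    for node in tree.preorder_node_iter():
        node.supported_by = []
        node.conflicts_with = []

    # attach each accepted cluster to the smallest edge realising it
    node_of: Dict[int, dendropy.Node] = {}
    internal = [
        n for n in tree.preorder_internal_node_iter() if n is not tree.seed_node
    ]
    for idx, c in enumerate(accepted):
        candidates = [
            n for n in internal if (leafset(n) & c.context) == c.include
        ]
        if not candidates:
            continue
        best = min(candidates, key=lambda n: (len(leafset(n)), tuple(sorted(leafset(n)))))
        best.supported_by.append(c.source)
        node_of[idx] = best
    for c, blocker in rejections:
        if blocker is None:
            continue
        idx = accepted.index(blocker)
        if idx in node_of:
            node_of[idx].conflicts_with.append(c.source)
    return tree


# ---------------------------------------------------------------------------
# The annotated synthetic tree
# ---------------------------------------------------------------------------

@dataclass
class EdgeAnnotation:
    supported_by: List[Tuple[str, str]]
    conflicts_with: List[Tuple[str, str]]
    terminal: bool

    @property
    def input_supported(self) -> bool:
        return any(
            not tid.startswith(TAXONOMY_SOURCE_PREFIX) for tid, _ in self.supported_by
        )


class SynthTree:
    """The synthesized rooted tree with per-edge provenance annotations.

    Nodes carry ``node_id``, ``supported_by`` and ``conflicts_with``
    attributes; ``sampled_species`` records which tips appear in at least
    one input phylogeny (the rest are taxonomy-only placeholders on
    terminal edges).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        sampled_species: FrozenSet[str],
        taxonomy_version: str = "",
    ):
        canonicalize(tree)
        assign_node_ids(tree)
        for node in tree.preorder_node_iter():
            if not hasattr(node, "supported_by"):
                node.supported_by = []
            if not hasattr(node, "conflicts_with"):
                node.conflicts_with = []
        self.tree = tree
        self.sampled_species = sampled_species
        self.taxonomy_version = taxonomy_version

    @property
    def leaves(self) -> FrozenSet[str]:
        return leaf_labels(self.tree)

    def clusters(self) -> Set[FrozenSet[str]]:
        return set(cluster_map(self.tree).keys())

    def nodes_by_id(self) -> Dict[str, dendropy.Node]:
        return {n.node_id: n for n in self.tree.preorder_node_iter()}

    def annotation(self, node: dendropy.Node) -> EdgeAnnotation:
        if node.is_leaf():
            terminal = node.taxon.label not in self.sampled_species
        else:
            terminal = not any(
                not tid.startswith(TAXONOMY_SOURCE_PREFIX)
                for tid, _ in node.supported_by
            )
        return EdgeAnnotation(
            supported_by=list(node.supported_by),
            conflicts_with=list(node.conflicts_with),
            terminal=terminal,
        )

    def fingerprint(self, node: dendropy.Node) -> str:
        """Two-tip MRCA spec identifying the node: ``mrca:a+b`` (tips: label)."""
        if node.is_leaf():
            return node.taxon.label
        kids = node.child_nodes()
        mins = sorted(min(leafset(k)) for k in kids)
        return f"mrca:{mins[0]}+{mins[1]}"

    def phylo_only(self) -> "SynthTree":
        """The synthesis restricted to phylogenetically sampled species.

        Taxonomy-only tips are pruned and internal edges whose support is
        purely taxonomic are contracted, so every internal edge of the
        result is supported by at least one input phylogeny.
        """
        keep = self.sampled_species & self.leaves
        induced = induce_tree(self.tree, keep)
        # carry annotations over from the originating nodes
        for node in induced.preorder_node_iter():
            orig = getattr(node, "orig", None)
            node.supported_by = list(getattr(orig, "supported_by", []) or [])
            node.conflicts_with = list(getattr(orig, "conflicts_with", []) or [])
        # contract internal edges without input-tree support
        changed = True
        while changed:
            changed = False
            for node in list(induced.preorder_internal_node_iter()):
                if node is induced.seed_node or node.parent_node is None:
                    continue
                has_input = any(
                    not tid.startswith(TAXONOMY_SOURCE_PREFIX)
                    for tid, _ in node.supported_by
                )
                if not has_input:
                    parent = node.parent_node
                    for child in node.child_nodes():
                        parent.add_child(child)
                    parent.remove_child(node)
                    changed = True
        out = SynthTree(induced, self.sampled_species, self.taxonomy_version)
        for node in out.tree.preorder_internal_node_iter():
            if node is out.tree.seed_node:
                continue
            assert any(
                not tid.startswith(TAXONOMY_SOURCE_PREFIX)
                for tid, _ in node.supported_by
            ), "phylogeny-only tree contains an edge without input support"
        return out

    # -- serialization ------------------------------------------------------

    def newick(self) -> str:
        return tree_to_newick(self.tree)

    def annotation_table(self) -> str:
        """Tab-separated sidecar: edge_id, fingerprint, supports, conflicts, terminal."""
        lines = ["edge_id\tfingerprint\tsupported_by\tconflicts_with\tterminal"]

        def fmt(entries: List[Tuple[str, str]]) -> str:
            return ",".join(f"{tid}:{nid}" for tid, nid in entries) or "-"

        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            ann = self.annotation(node)
            lines.append(
                "\t".join(
                    [
                        node.node_id,
                        self.fingerprint(node),
                        fmt(ann.supported_by),
                        fmt(ann.conflicts_with),
                        "1" if ann.terminal else "0",
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def write(self, newick_path: str, annotations_path: Optional[str] = None) -> None:
        with open(newick_path, "w", encoding="utf-8") as handle:
            handle.write(self.newick())
        if annotations_path:
            with open(annotations_path, "w", encoding="utf-8") as handle:
                handle.write(self.annotation_table())


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def synthesize(
    trees: Sequence[InputTree],
    ranking: Ranking,
    taxonomy: Taxonomy,
    constraints: Sequence[dendropy.Tree] = (),
) -> SynthTree:
    """Synthesize an annotated supertree from ranked inputs and a taxonomy.

    Pipeline: exemplify each input; append constraint trees (ranked above
    the taxonomy but below all inputs, to reinforce monophyly); decompose
    at uncontested taxa; greedily solve each subproblem; graft fragments
    back together.  Species absent from every input attach according to the
    taxonomy, on terminal (taxonomy-only) edges; ``phylo_only()`` gives the
    variant restricted to sampled species.
    """
    ranked_inputs = ranking.sort_trees(trees)
    ex_trees: List[InputTree] = [exemplify(t, taxonomy) for t in ranked_inputs]
    for i, ctree in enumerate(constraints):
        ex_trees.append(
            InputTree(
                tree_id=f"constraint:{i}",
                study_id=f"constraint:{i}",
                year=0,
                tree=ctree,
            )
        )
    subs = find_uncontested(taxonomy, ex_trees)
    root_sub = subs[-1]  # postorder: artificial root subproblem last

    def assemble(sub: Subproblem) -> dendropy.Node:
        fragment = solve_subproblem(sub, taxonomy.version_tag)
        root = fragment.seed_node
        for rep, child_sub in sorted(sub.child_subs.items()):
            child_root = assemble(child_sub)
            child_root.sub_root_taxon = child_sub.root_taxon
            target = None
            for leaf in root.leaf_iter():
                if leaf.taxon.label == rep:
                    target = leaf
                    break
            if target is None:
                raise SynthError(f"representative {rep!r} missing from fragment")
            if target is root:
                root = child_root
                continue
            parent = target.parent_node
            kids = [child_root if k is target else k for k in parent.child_nodes()]
            parent.set_child_nodes(kids)
        return root

    full_root = assemble(root_sub)
    tree = new_tree(full_root)
    sampled = frozenset().union(*(t.leaves for t in ex_trees[: len(ranked_inputs)])) \
        if ranked_inputs else frozenset()
    synth = SynthTree(tree, sampled, taxonomy.version_tag)

    # subproblem-root edges: add taxonomy support and any input-tree support
    # their expanded cluster now realises
    input_clusters = [
        (t.tree_id, t.leaves, cluster_map(t.tree)) for t in ex_trees
    ]
    tax_src = TAXONOMY_SOURCE_PREFIX + taxonomy.version_tag
    for node in synth.tree.preorder_internal_node_iter():
        taxon = getattr(node, "sub_root_taxon", None)
        if taxon is None or node is synth.tree.seed_node:
            continue
        node.supported_by.append((tax_src, taxon))
        cl = leafset(node)
        for tid, tleaves, cmap in input_clusters:
            restricted = cl & tleaves
            if len(restricted) < 2 or not (tleaves - restricted):
                continue
            hit = cmap.get(frozenset(restricted))
            if hit is not None:
                src = (tid, getattr(hit, "node_id", "") or "")
                if src not in node.supported_by:
                    node.supported_by.append(src)
    return synth
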