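"""Synthetic fixtures: true trees, taxonomies, input-tree sets, statements.

Every pipeline stage is testable without downloads: a Yule (pure-birth)
simulation provides a dated "true" tree; its clades, cut at two depths,
define genera and families of a matching taxonomy (so named groups are
true clades and monophyly holds by construction); input trees are induced
subtrees, optionally perturbed by one rooted NNI (the smallest topological
change that guarantees conflict with the truth); held-out species yield
addition statements anchored at their true genus or family with sibling
genera excluded, guaranteeing the true placement stays legal; and
assemblages are drawn uniformly or clade-clustered to mimic
phylogenetically clustered versus overdispersed communities.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .diversity import Assemblage
from .graft import AdditionStatement, CladeSpec, GraftError
from .taxa import TaxonRecord, Taxonomy
from .trees import (
    InputTree,
    assign_node_ids,
    canonicalize,
    induce_tree,
    leaf_labels,
    leafset,
    new_internal,
    new_leaf,
    new_tree,
    node_ages_from_lengths,
    set_branch_lengths_from_ages,
)

__all__ = [
    "simulate_true_tree",
    "sample_input_trees",
    "make_addition_statements",
    "make_assemblages",
]

DEFAULT_ROOT_AGE = 100.0  # Mya; same order as the avian crown age
GENUS_CUT_FRACTION = 0.25  # clades younger than this fraction of the root age
FAMILY_CUT_FRACTION = 0.60


def simulate_true_tree(
    n_species: int,
    seed: int,
    root_age: float = DEFAULT_ROOT_AGE,
    genus_cut: Optional[float] = None,
    family_cut: Optional[float] = None,
) -> Tuple[dendropy.Tree, Taxonomy]:
    """A dated Yule tree plus a taxonomy whose named groups are true clades.

    Pure-birth forward simulation: a uniformly chosen extant lineage splits
    after an exponential wait, until ``n_species`` tips exist; node ages
    are rescaled so the root sits at ``root_age``.  Tip labels are then
    assigned in random order, which makes every labelled topology equally
    likely at small n.  Genera (families) are the maximal clades entirely
    younger than the genus (family) age cut-off.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = np.random.default_rng(seed)
    genus_cut = root_age * GENUS_CUT_FRACTION if genus_cut is None else genus_cut
    family_cut = root_age * FAMILY_CUT_FRACTION if family_cut is None else family_cut

    # forward Yule: (node, birth_time) of each open lineage
    t = 0.0
    root = new_internal([])
    root.split_time = 0.0
    open_nodes: List[dendropy.Node] = []
    for _ in range(2):
        child = new_internal([])
        root.add_child(child)
        open_nodes.append(child)
    while len(open_nodes) < n_species:
        t += float(rng.exponential(1.0 / len(open_nodes)))
        idx = int(rng.integers(len(open_nodes)))
        node = open_nodes.pop(idx)
        node.split_time = t
        for _ in range(2):
            child = new_internal([])
            node.add_child(child)
            open_nodes.append(child)
    t_end = t + float(rng.exponential(1.0 / len(open_nodes)))

    # open lineages become tips; shuffle labels for exchangeability
    width = len(str(n_species))
    labels = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    rng.shuffle(labels)
    for node, label in zip(open_nodes, labels):
        node.taxon = dendropy.Taxon(label=label)

    tree = new_tree(root)
    scale = root_age / t_end
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
        else:
            node.age = (t_end - node.split_time) * scale
    set_branch_lengths_from_ages(tree)
    canonicalize(tree)
    assign_node_ids(tree)

    taxonomy = _taxonomy_from_tree(tree, genus_cut, family_cut)
    return tree, taxonomy


def _taxonomy_from_tree(
    tree: dendropy.Tree, genus_cut: float, family_cut: float
) -> Taxonomy:
    """Cut a dated tree at two depths into genera and families."""
    records: List[TaxonRecord] = [
        TaxonRecord(uid="aves", parent_uid=None, name="aves", rank="class")
    ]

    def maximal_clades(node: dendropy.Node, cut: float) -> List[dendropy.Node]:
        if node.is_leaf() or node.age <= cut:
            return [node]
        out: List[dendropy.Node] = []
        for child in node.child_nodes():
            out.extend(maximal_clades(child, cut))
        return out

    families = maximal_clades(tree.seed_node, family_cut)
    fam_counter = gen_counter = 0
    for fam in families:
        fam_counter += 1
        fam_uid = f"fam{fam_counter}"
        records.append(
            TaxonRecord(uid=fam_uid, parent_uid="aves", name=fam_uid, rank="family")
        )
        for gen in maximal_clades(fam, genus_cut):
            gen_counter += 1
            gen_uid = f"gen{gen_counter}"
            records.append(
                TaxonRecord(uid=gen_uid, parent_uid=fam_uid, name=gen_uid, rank="genus")
            )
            for label in sorted(leafset(gen)):
                records.append(
                    TaxonRecord(
                        uid=label, parent_uid=gen_uid, name=label, rank="species"
                    )
                )
    return Taxonomy(records, version_tag="sim")


def _rnni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """One rooted NNI: swap a child of an internal node with its sibling.

    Guarantees a changed (conflicting) cluster.  Returns False when the
    tree has no eligible internal edge (e.g. a 2-leaf or star tree).
    """
    eligible = [
        n
        for n in tree.preorder_internal_node_iter()
        if n is not tree.seed_node and n.parent_node is not None
        and len(n.parent_node.child_nodes()) >= 2
    ]
    if not eligible:
        return False
    node = eligible[int(rng.integers(len(eligible)))]
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    sib = siblings[int(rng.integers(len(siblings)))]
    kids = node.child_nodes()
    moved = kids[int(rng.integers(len(kids)))]
    node.remove_child(moved)
    parent.remove_child(sib)
    node.add_child(sib)
    parent.add_child(moved)
    return True


def sample_input_trees(
    true_tree: dendropy.Tree,
    n_trees: int,
    leaves_per_tree: int,
    conflict_rate: float,
    seed: int,
    dated: bool = False,
    age_noise: float = 0.0,
) -> List[InputTree]:
    """Input trees induced from the truth, with controllable conflict.

    Each tree restricts the true tree to a random leaf subset; with
    probability ``conflict_rate`` one internal edge is then perturbed by a
    rooted NNI.  Dated variants carry the true node ages, optionally with
    symmetric multiplicative noise truncated to preserve parent > child
    monotonicity.  Publication years place unperturbed trees above
    perturbed ones in the default ranking.
    """
    if leaves_per_tree < 3:
        raise ValueError("leaves_per_tree must be >= 3")
    rng = np.random.default_rng(seed)
    all_leaves = sorted(leaf_labels(true_tree))
    leaves_per_tree = min(leaves_per_tree, len(all_leaves))
    out: List[InputTree] = []
    for i in range(n_trees):
        subset = rng.choice(all_leaves, size=leaves_per_tree, replace=False)
        sub = induce_tree(true_tree, set(map(str, subset)))
        perturbed = bool(rng.random() < conflict_rate)
        if perturbed:
            perturbed = _rnni(sub, rng)
            if perturbed and dated:
                _repair_monotonicity(sub)
        if dated and age_noise > 0.0:
            _jitter_ages(sub, age_noise, rng)
        if dated:
            set_branch_lengths_from_ages(_with_tip_ages(sub))
        canonicalize(sub)
        year = (2000 if perturbed else 2020) + i
        out.append(
            InputTree(
                tree_id=f"sim{i}",
                study_id=f"study{i}",
                year=year,
                tree=sub,
                dated=dated,
            )
        )
    return out


def _with_tip_ages(tree: dendropy.Tree) -> dendropy.Tree:
    for leaf in tree.leaf_node_iter():
        leaf.age = 0.0
    return tree


def _repair_monotonicity(tree: dendropy.Tree) -> None:
    """Lift ages broken by topology surgery so parents stay older."""
    for node in tree.postorder_internal_node_iter():
        floor = max(
            (c.age for c in node.child_nodes() if not c.is_leaf()), default=0.0
        )
        if node.age <= floor:
            node.age = floor * (1.0 + 1e-6) + 1e-9


def _jitter_ages(tree: dendropy.Tree, noise: float, rng: np.random.Generator) -> None:
    """Symmetric multiplicative age noise, truncated to keep monotonicity."""
    for node in tree.preorder_internal_node_iter():
        parent = node.parent_node
        ceiling = parent.age if parent is not None else float("inf")
        floor = max(
            (c.age for c in node.child_nodes() if not c.is_leaf()), default=0.0
        )
        lo = max(node.age * (1.0 - noise), floor + 1e-9)
        hi = min(node.age * (1.0 + noise), ceiling - 1e-9) if ceiling < float("inf") \
            else node.age * (1.0 + noise)
        if lo < hi:
            node.age = float(rng.uniform(lo, hi))


def choose_holdout(taxonomy: Taxonomy, species: Sequence[str], k: int) -> List[str]:
    """Pick up to ``k`` species to hold out, leaving every family represented.

    Greedy over the given order; a species is skipped when holding it out
    would empty its family (which addition statements cannot recover from).
    """
    held: List[str] = []
    held_set: Set[str] = set()
    for sp in species:
        genus = taxonomy.parent(sp)
        family = taxonomy.parent(genus) if genus is not None else None
        if family is None:
            continue
        if taxonomy.species_under(family) - held_set - {sp}:
            held.append(sp)
            held_set.add(sp)
        if len(held) == k:
            break
    return held


def make_addition_statements(
    true_tree: dendropy.Tree,
    holdout: Iterable[str],
    taxonomy: Taxonomy,
) -> Tuple[List[AdditionStatement], dendropy.Tree]:
    """Statements for held-out species, plus the reduced tree without them.

    Each held-out species is anchored to its true genus with the family as
    a fallback anchor; sibling genera of the family are excluded, so the
    true placement is always among the candidates.  Species whose genus is
    entirely held out depend on a congener being added first (the genus
    anchor resolves only then), matching the sister-to-the-first pattern.
    """
    holdout_set = set(holdout)
    all_species = leaf_labels(true_tree)
    if not holdout_set or holdout_set >= all_species:
        raise GraftError("holdout must be a non-empty proper subset of species")
    unknown = holdout_set - all_species
    if unknown:
        raise GraftError(f"holdout species absent from tree: {sorted(unknown)}")
    remaining = all_species - holdout_set

    statements: List[AdditionStatement] = []
    for sp in sorted(holdout_set):
        genus = taxonomy.parent(sp)
        family = taxonomy.parent(genus) if genus is not None else None
        if genus is None or family is None:
            raise GraftError(f"species {sp!r} lacks genus/family in the taxonomy")
        if not (taxonomy.species_under(family) - holdout_set):
            raise GraftError(f"holdout exhausts family {family!r}")
        # exclude every sibling genus: one-member exclusions have no
        # interior yet, but start protecting the genus the moment a
        # held-out congener is grafted into it
        exclusions = [
            CladeSpec(taxon=g)
            for g in taxonomy.children(family)
            if g != genus and taxonomy.species_under(g)
        ]
        statements.append(
            AdditionStatement(
                taxon=sp,
                anchors=[CladeSpec(taxon=family), CladeSpec(taxon=genus)],
                exclusions=exclusions,
                note="sim",
            )
        )
    reduced = induce_tree(true_tree, remaining)
    canonicalize(reduced)
    assign_node_ids(reduced)
    return statements, reduced


def make_assemblages(
    tree: dendropy.Tree,
    n_cells: int,
    richness_range: Tuple[int, int],
    seed: int,
    mode: str = "uniform",
) -> List[Assemblage]:
    """Random assemblages, uniform or phylogenetically clustered.

    ``clustered`` cells draw their species from within one random clade of
    sufficient size, giving systematically lower MPD than uniform cells of
    the same richness.
    """
    if mode not in ("uniform", "clustered"):
        raise ValueError(f"unknown assemblage mode {mode!r}")
    lo, hi = richness_range
    if lo < 1 or hi < lo:
        raise ValueError("richness_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    leaves = sorted(leaf_labels(tree))
    clades = [
        sorted(leafset(n))
        for n in tree.preorder_internal_node_iter()
        if n is not tree.seed_node
    ]
    out: List[Assemblage] = []
    for i in range(n_cells):
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(leaves))
        if mode == "uniform":
            pool = leaves
        else:
            eligible = [c for c in clades if len(c) >= k] or [leaves]
            pool = eligible[int(rng.integers(len(eligible)))]
        picks = rng.choice(pool, size=min(k, len(pool)), replace=False)
        out.append(
            Assemblage(cell_id=f"cell{i:04d}", species=frozenset(map(str, picks)))
        )
    return out
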