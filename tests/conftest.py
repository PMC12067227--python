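"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pytest

from phylosynth.taxa import TaxonRecord, Taxonomy


# ---------------------------------------------------------------------------
# Independent tree enumeration / generation (oracles never reuse the
# package's assembly code paths)
# ---------------------------------------------------------------------------

def all_rooted_binary_newicks(labels: Sequence[str]) -> List[str]:
    """Every rooted binary labelled topology on ``labels`` as newick."""

    def rec(group: Tuple[str, ...]) -> List[str]:
        if len(group) == 1:
            return [group[0]]
        out = []
        rest = group[1:]
        # first label stays on the left side to avoid mirror duplicates
        for r in range(0, len(rest)):
            for combo in itertools.combinations(rest, r):
                left = (group[0],) + combo
                right = tuple(x for x in rest if x not in combo)
                if not right:
                    continue
                for lt in rec(left):
                    for rt in rec(right):
                        out.append(f"({lt},{rt})")
        return out

    return [s + ";" for s in rec(tuple(labels))]


def random_binary_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """A uniform random-join rooted binary topology, as newick text."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Small taxonomies
# ---------------------------------------------------------------------------

def make_taxonomy(
    families: Dict[str, Dict[str, List[str]]], version: str = "v1"
) -> Taxonomy:
    """Taxonomy from ``{family: {genus: [species...]}}``."""
    records = [TaxonRecord(uid="root", parent_uid=None, name="root", rank="class")]
    for fam, genera in families.items():
        records.append(TaxonRecord(uid=fam, parent_uid="root", name=fam, rank="family"))
        for gen, species in genera.items():
            records.append(
                TaxonRecord(uid=gen, parent_uid=fam, name=gen, rank="genus")
            )
            for sp in species:
                records.append(
                    TaxonRecord(uid=sp, parent_uid=gen, name=sp, rank="species")
                )
    return Taxonomy(records, version_tag=version)


@pytest.fixture
def taxonomy_two_genera() -> Taxonomy:
    """((A,B)g1,(C,D)g2) under one family."""
    return make_taxonomy({"f1": {"g1": ["A", "B"], "g2": ["C", "D"]}})


# ---------------------------------------------------------------------------
# Oracle: descendant-set alignment by exhaustive pair comparison
# ---------------------------------------------------------------------------

def oracle_align(synth_tree, source_tree) -> Set[Tuple[str, str, str]]:
    """Brute-force (synth_node, source_node, relation) triples.

    Pure set algebra on descendant sets: a node is visible in the induced
    tree iff at least two of its children retain shared leaves; pairs with
    equal restricted descendant sets align; the relation is ``supported``
    when the synth node's original parent is visible too, or when the
    synth node is the induced root (no visible proper ancestor).
    """

    def leafset(node) -> FrozenSet[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    shared = leafset(synth_tree.seed_node) & leafset(source_tree.seed_node)

    def visible(node) -> bool:
        kids = [c for c in node.child_nodes() if leafset(c) & shared]
        return len(kids) >= 2

    def internal_nodes(tree):
        return [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    out: Set[Tuple[str, str, str]] = set()
    for x in internal_nodes(synth_tree):
        rx = leafset(x) & shared
        if len(rx) < 2 or not visible(x):
            continue
        for y in internal_nodes(source_tree):
            ry = leafset(y) & shared
            if len(ry) < 2 or not visible(y):
                continue
            if rx != ry:
                continue
            anc, has_visible_anc = x.parent_node, False
            while anc is not None:
                if visible(anc):
                    has_visible_anc = True
                    break
                anc = anc.parent_node
            if not has_visible_anc:
                retained = True  # induced root: vacuously parent-retained
            else:
                retained = visible(x.parent_node)
            out.add(
                (x.node_id, y.node_id, "supported" if retained else "aligned")
            )
    return out


def oracle_classify(synth_tree, source_tree) -> Dict[str, str]:
    """Brute-force per-edge verdicts against one source tree."""

    def leafset(node) -> FrozenSet[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    shared = leafset(synth_tree.seed_node) & leafset(source_tree.seed_node)

    def visible(node) -> bool:
        kids = [c for c in node.child_nodes() if leafset(c) & shared]
        return len(kids) >= 2

    source_clusters = set()
    for y in source_tree.preorder_node_iter():
        if y.is_leaf() or y is source_tree.seed_node:
            continue
        ry = leafset(y) & shared
        if 2 <= len(ry) < len(shared) and visible(y):
            source_clusters.add(ry)

    out: Dict[str, str] = {}
    for x in synth_tree.preorder_node_iter():
        if x.is_leaf() or x is synth_tree.seed_node:
            continue
        rx = leafset(x) & shared
        if len(rx) < 2 or len(shared - rx) < 1:
            out[x.node_id] = "uninformative"
            continue
        exact = rx in source_clusters and visible(x) and (
            x.parent_node is None or visible(x.parent_node)
        )
        if exact:
            out[x.node_id] = "supports"
        elif any((rx & t) and (rx - t) and (t - rx) for t in source_clusters):
            out[x.node_id] = "conflicts"
        else:
            out[x.node_id] = "compatible"
    return out
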