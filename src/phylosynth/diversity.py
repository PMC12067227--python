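"""Patristic distances and assemblage mean pairwise phylogenetic distance.

Given a dated (branch-length-bearing) tree and presence/absence species
lists per assemblage (e.g. grid cells of occurrence records), computes the
unweighted mean pairwise patristic distance (MPD) among the species of
each assemblage.  Phylogenetically clustered assemblages (close relatives
co-occurring) show low MPD; overdispersed ones high MPD.  Abundance
weighting and spatial gridding of raw records are upstream of this module.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set

import dendropy

from .trees import TreeError, leaf_labels

__all__ = [
    "Assemblage",
    "patristic_distance",
    "assemblage_mpd",
    "read_assemblages",
    "write_mpd_table",
]


@dataclass(frozen=True)
class Assemblage:
    cell_id: str
    species: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"assemblage {self.cell_id!r} has no species")


def _depths(tree: dendropy.Tree) -> Dict[str, List]:
    """Per-leaf (depth, ancestor-path) bookkeeping for path-sum distances."""
    depth: Dict[int, float] = {id(tree.seed_node): 0.0}
    order: Dict[int, int] = {id(tree.seed_node): 0}
    parent: Dict[int, dendropy.Node] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        order[id(node)] = i
        for child in node.child_nodes():
            parent[id(child)] = node
            depth[id(child)] = depth[id(node)] + (child.edge.length or 0.0)
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    return {"depth": depth, "parent": parent, "leaves": leaves, "order": order}


def _pairwise(tree: dendropy.Tree, a: str, b: str, book) -> float:
    if a == b:
        return 0.0
    leaves = book["leaves"]
    missing = [x for x in (a, b) if x not in leaves]
    if missing:
        raise TreeError(f"tips missing from tree: {missing}")
    depth, parent, order = book["depth"], book["parent"], book["order"]
    na, nb = leaves[a], leaves[b]
    # walk the deeper-ordered node up until the paths meet
    pa, pb = na, nb
    seen: Set[int] = {id(pa)}
    while id(pa) in parent:
        pa = parent[id(pa)]
        seen.add(id(pa))
    path_a = seen
    anc = nb
    while id(anc) not in path_a:
        anc = parent[id(anc)]
    return depth[id(na)] + depth[id(nb)] - 2.0 * depth[id(anc)]


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two tips (symmetric)."""
    return _pairwise(tree, a, b, _depths(tree))


def assemblage_mpd(
    tree: dendropy.Tree, assemblages: Sequence[Assemblage]
) -> Dict[str, float]:
    """Unweighted mean pairwise patristic distance per assemblage.

    Every species must be a tip of the tree (translate labels first);
    singleton assemblages get ``nan`` -- an undefined MPD is not a zero.
    """
    tips = leaf_labels(tree)
    missing = sorted(
        {sp for asm in assemblages for sp in asm.species if sp not in tips}
    )
    if missing:
        raise TreeError(f"assemblage species absent from tree: {missing}")
    book = _depths(tree)
    out: Dict[str, float] = {}
    for asm in assemblages:
        species = sorted(asm.species)
        if len(species) < 2:
            out[asm.cell_id] = math.nan
            continue
        total, pairs = 0.0, 0
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                total += _pairwise(tree, a, b, book)
                pairs += 1
        out[asm.cell_id] = total / pairs
    return out


def read_assemblages(path: str) -> List[Assemblage]:
    """Two-column occurrence CSV (cell_id, species_id) -> assemblages."""
    cells: Dict[str, Set[str]] = {}
    with open(path, "r", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {"cell_id", "species_id"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: need columns cell_id, species_id")
        for row in reader:
            cells.setdefault(row["cell_id"].strip(), set()).add(
                row["species_id"].strip()
            )
    return [
        Assemblage(cell_id=cid, species=frozenset(sps))
        for cid, sps in sorted(cells.items())
    ]


def write_mpd_table(mpd: Dict[str, float], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("cell_id\tmpd\n")
        for cell_id in sorted(mpd):
            value = mpd[cell_id]
            handle.write(f"{cell_id}\t{'NA' if math.isnan(value) else value}\n")
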