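"""Reference taxonomy, name resolution and cross-version translation.

A single reference taxonomy (an OTT-style parent-pointer table) provides
the backbone for synthesis and the placeholder source for species without
phylogenetic data.  Tip labels on input trees are resolved to taxonomy ids
by exact matching on canonical names and stored synonyms; hard cases are
carried as ``hand`` rows in a crosswalk table, which also links taxon
concepts across taxonomy versions so trees can be translated between them.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

from . import trees as _trees
from .trees import InputTree, TreeError, collapse_duplicate_tips, leaf_labels

__all__ = [
    "RANK_LEVEL",
    "TaxonRecord",
    "Taxonomy",
    "TaxonomyError",
    "CrosswalkRow",
    "CoverageReport",
    "load_taxonomy",
    "resolve_names",
    "load_crosswalk",
    "translate_labels",
    "coverage_report",
]

# ordered rank scale, most inclusive first; unknown ranks map to "other"
RANK_LEVEL = {"class": 0, "order": 1, "family": 2, "genus": 3, "species": 4}


class TaxonomyError(ValueError):
    """Malformed taxonomy table: cycles, orphans, duplicate ids."""


@dataclass
class TaxonRecord:
    uid: str
    parent_uid: Optional[str]
    name: str
    rank: str  # one of RANK_LEVEL keys, or "other"
    synonyms: Set[str] = field(default_factory=set)
    source_ids: Dict[str, str] = field(default_factory=dict)


class Taxonomy:
    """A validated rooted hierarchy of taxon records.

    Invariants checked at construction: unique uids, exactly one root,
    acyclic parent chains terminating at the root, every non-root parent
    present, and child ranks never above their parent's on the rank scale.
    """

    def __init__(self, records: Iterable[TaxonRecord], version_tag: str = ""):
        self.version_tag = version_tag
        self.records: Dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.uid in self.records:
                raise TaxonomyError(f"duplicate uid {rec.uid!r}")
            self.records[rec.uid] = rec
        roots = [r.uid for r in self.records.values() if r.parent_uid is None]
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root_uid = roots[0]
        self._children: Dict[str, List[str]] = {uid: [] for uid in self.records}
        for rec in self.records.values():
            if rec.parent_uid is None:
                continue
            if rec.parent_uid not in self.records:
                raise TaxonomyError(
                    f"orphan parent_uid {rec.parent_uid!r} referenced by {rec.uid!r}"
                )
            self._children[rec.parent_uid].append(rec.uid)
        for kids in self._children.values():
            kids.sort()
        self._check_acyclic()
        self._check_ranks()
        self._species_under: Dict[str, FrozenSet[str]] = {}
        self._compute_species_sets()

    # -- validation ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        state: Dict[str, int] = {}  # 0 visiting, 1 done
        for start in self.records:
            if start in state:
                continue
            chain = []
            uid: Optional[str] = start
            while uid is not None and uid not in state:
                state[uid] = 0
                chain.append(uid)
                uid = self.records[uid].parent_uid
            if uid is not None and state.get(uid) == 0:
                raise TaxonomyError(f"cycle detected through uid {uid!r}")
            for c in chain:
                state[c] = 1

    def _check_ranks(self) -> None:
        for rec in self.records.values():
            if rec.parent_uid is None:
                continue
            child_level = RANK_LEVEL.get(rec.rank)
            parent_level = RANK_LEVEL.get(self.records[rec.parent_uid].rank)
            if child_level is not None and parent_level is not None:
                if child_level < parent_level:
                    raise TaxonomyError(
                        f"rank inversion: {rec.uid!r} ({rec.rank}) under "
                        f"{rec.parent_uid!r} ({self.records[rec.parent_uid].rank})"
                    )

    def _compute_species_sets(self) -> None:
        def rec(uid: str) -> FrozenSet[str]:
            record = self.records[uid]
            out: Set[str] = set()
            if record.rank == "species":
                out.add(uid)
            for child in self._children[uid]:
                out |= rec(child)
            fs = frozenset(out)
            self._species_under[uid] = fs
            return fs

        rec(self.root_uid)

    # -- queries ------------------------------------------------------------

    def children(self, uid: str) -> List[str]:
        return self._children[uid]

    def parent(self, uid: str) -> Optional[str]:
        return self.records[uid].parent_uid

    def species_ids(self) -> FrozenSet[str]:
        return self._species_under[self.root_uid]

    def species_under(self, uid: str) -> FrozenSet[str]:
        return self._species_under[uid]

    def ancestors(self, uid: str) -> List[str]:
        """Ancestor uids from parent up to and including the root."""
        out = []
        cur = self.records[uid].parent_uid
        while cur is not None:
            out.append(cur)
            cur = self.records[cur].parent_uid
        return out

    def species_ancestor(self, uid: str) -> Optional[str]:
        """The species-rank taxon containing ``uid`` (itself if species)."""
        cur: Optional[str] = uid
        while cur is not None:
            if self.records[cur].rank == "species":
                return cur
            cur = self.records[cur].parent_uid
        return None

    def taxa_at_rank(self, rank: str) -> List[str]:
        return sorted(u for u, r in self.records.items() if r.rank == rank)

    def named_internal_taxa(self) -> List[str]:
        """Non-root, non-species taxa, ordered top-down (parents first)."""
        out: List[str] = []

        def walk(uid: str) -> None:
            for child in self._children[uid]:
                if self.records[child].rank != "species":
                    out.append(child)
                walk(child)

        walk(self.root_uid)
        return out

    def to_tree(self, restrict: Optional[Iterable[str]] = None) -> dendropy.Tree:
        """The taxonomy as a rooted tree over species tips.

        Internal nodes carry the taxon uid as both label and ``node_id``;
        unary taxa (e.g. monotypic genera) are suppressed.  ``restrict``
        limits the tips to a subset of species ids.
        """
        keep = frozenset(restrict) if restrict is not None else self.species_ids()

        def rec(uid: str) -> Optional[dendropy.Node]:
            record = self.records[uid]
            if record.rank == "species":
                return _trees.new_leaf(uid) if uid in keep else None
            kids = [rec(c) for c in self._children[uid]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = _trees.new_internal(kids, label=uid)
            node.node_id = uid
            return node

        root = rec(self.root_uid)
        if root is None:
            raise TaxonomyError("taxonomy tree has no species tips under restriction")
        tree = _trees.new_tree(root)
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.node_id = node.taxon.label
            elif not hasattr(node, "node_id"):
                node.node_id = node.label or ""
        return tree


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_taxonomy(path: str, version_tag: Optional[str] = None) -> Taxonomy:
    """Load a tab-separated parent-pointer taxonomy table.

    Columns: ``uid  parent_uid  name  rank  synonyms  source_ids`` with
    synonyms pipe-separated and source ids as comma-separated
    ``source:id`` pairs.  Errors (duplicate uid, orphan parent, cycle) are
    reported with the offending row numbers.
    """
    records: List[TaxonRecord] = []
    rows_by_uid: Dict[str, List[int]] = {}
    with open(path, "r", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"uid", "parent_uid", "name", "rank"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TaxonomyError(
                f"{path}: header must contain columns {sorted(required)}"
            )
        for rownum, row in enumerate(reader, start=2):  # 1 = header
            uid = row["uid"].strip()
            parent = row["parent_uid"].strip() or None
            rows_by_uid.setdefault(uid, []).append(rownum)
            synonyms = {
                s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()
            }
            source_ids: Dict[str, str] = {}
            for pair in (row.get("source_ids") or "").split(","):
                pair = pair.strip()
                if pair:
                    src, _, sid = pair.partition(":")
                    source_ids[src] = sid
            rank = row["rank"].strip().lower()
            if rank not in RANK_LEVEL:
                rank = "other"
            if parent == uid:
                raise TaxonomyError(f"{path}: row {rownum}: uid {uid!r} is its own parent (cycle)")
            records.append(
                TaxonRecord(
                    uid=uid,
                    parent_uid=parent,
                    name=row["name"].strip(),
                    rank=rank,
                    synonyms=synonyms,
                    source_ids=source_ids,
                )
            )
    dups = {u: rows for u, rows in rows_by_uid.items() if len(rows) > 1}
    if dups:
        detail = "; ".join(f"uid {u!r} at rows {rows}" for u, rows in sorted(dups.items()))
        raise TaxonomyError(f"{path}: duplicate uid(s): {detail}")
    try:
        return Taxonomy(records, version_tag=version_tag or "")
    except TaxonomyError as exc:
        raise TaxonomyError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Name resolution
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm(label: str) -> str:
    return _WS.sub(" ", label.strip()).casefold()


def resolve_names(
    labels: Sequence[str], taxonomy: Taxonomy
) -> Dict[str, Tuple[Optional[str], str]]:
    """Resolve tip labels to taxon uids.

    Matching is exact-string after whitespace normalisation and case
    folding, first on canonical names, then on stored synonyms; canonical
    matches always win over synonym matches.  A name carried by several
    taxa in the same tier resolves to ``(None, "ambiguous")`` rather than
    silently picking one; unmatched labels give ``(None, "unmatched")``.
    Hand-curated matches are expressed as crosswalk rows, not here.
    """
    canonical: Dict[str, List[str]] = {}
    synonym: Dict[str, List[str]] = {}
    for rec in taxonomy.records.values():
        canonical.setdefault(_norm(rec.name), []).append(rec.uid)
        for syn in rec.synonyms:
            synonym.setdefault(_norm(syn), []).append(rec.uid)

    out: Dict[str, Tuple[Optional[str], str]] = {}
    for label in labels:
        key = _norm(label)
        hits = canonical.get(key, [])
        if len(hits) == 1:
            out[label] = (hits[0], "canonical")
            continue
        if len(hits) > 1:
            out[label] = (None, "ambiguous")
            continue
        hits = sorted(set(synonym.get(key, [])))
        if len(hits) == 1:
            out[label] = (hits[0], "synonym")
        elif len(hits) > 1:
            out[label] = (None, "ambiguous")
        else:
            out[label] = (None, "unmatched")
    return out


# ---------------------------------------------------------------------------
# Crosswalk translation
# ---------------------------------------------------------------------------

@dataclass
class CrosswalkRow:
    """One taxon concept linked across taxonomy versions."""

    concept_key: str
    ids: Dict[str, Optional[str]]  # version_tag -> uid (or None)
    match_method: str  # canonical | synonym | hand

    def __post_init__(self) -> None:
        if not any(v for v in self.ids.values()):
            raise TaxonomyError(
                f"crosswalk concept {self.concept_key!r} maps to no version id"
            )


def load_crosswalk(path: str) -> List[CrosswalkRow]:
    """Read a crosswalk CSV: concept_key, one column per version, match_method."""
    rows: List[CrosswalkRow] = []
    with open(path, "r", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "concept_key" not in reader.fieldnames:
            raise TaxonomyError(f"{path}: crosswalk must have a concept_key column")
        version_cols = [
            c for c in reader.fieldnames if c not in ("concept_key", "match_method")
        ]
        for row in reader:
            ids = {v: (row[v].strip() or None) for v in version_cols}
            rows.append(
                CrosswalkRow(
                    concept_key=row["concept_key"].strip(),
                    ids=ids,
                    match_method=(row.get("match_method") or "canonical").strip(),
                )
            )
    return rows


def translate_labels(
    tree: dendropy.Tree,
    crosswalk: Sequence[CrosswalkRow],
    from_version: str,
    to_version: str,
) -> Tuple[dendropy.Tree, Dict[str, List[str]]]:
    """Relabel tips from one taxonomy version to another via the crosswalk.

    Tips whose concept has no id in the target version are pruned and
    reported.  When two source ids lump into one target id the duplicate
    tips are collapsed to a single exemplar (smallest original label), the
    same rule used by exemplification.  A tip absent from the crosswalk
    under ``from_version`` is an error.
    """
    mapping: Dict[str, Optional[str]] = {}
    for row in crosswalk:
        src = row.ids.get(from_version)
        if src is not None and src not in mapping:
            # first row wins when a lumped concept reverses to several ids
            mapping[src] = row.ids.get(to_version)
    tips = sorted(leaf_labels(tree))
    absent = [t for t in tips if t not in mapping]
    if absent:
        raise TaxonomyError(
            f"tips absent from crosswalk under version {from_version!r}: {absent}"
        )
    new_tree, report = collapse_duplicate_tips(tree, {t: mapping[t] for t in tips})
    return new_tree, report


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _pct(numer: int, denom: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if denom == 0:
        return 0
    return int(math.floor(100.0 * numer / denom + 0.5))


@dataclass
class CoverageReport:
    """Species counts and integer-rounded coverage percentages.

    ``pct_in_taxonomy`` = share of the checklist total present in the
    reference taxonomy; ``pct_with_phylo`` = share appearing in at least
    one input phylogeny.
    """

    version_tag: str
    total_species: int
    species_in_taxonomy: int
    species_with_phylo: int

    def __post_init__(self) -> None:
        if not (0 <= self.species_with_phylo <= self.species_in_taxonomy <= self.total_species):
            raise ValueError(
                "coverage counts must satisfy 0 <= with_phylo <= in_taxonomy <= total"
            )

    @property
    def pct_in_taxonomy(self) -> int:
        return _pct(self.species_in_taxonomy, self.total_species)

    @property
    def pct_with_phylo(self) -> int:
        return _pct(self.species_with_phylo, self.total_species)

    @classmethod
    def from_counts(
        cls, version_tag: str, total: int, in_taxonomy: int, with_phylo: int
    ) -> "CoverageReport":
        return cls(version_tag, total, in_taxonomy, with_phylo)


def coverage_report(
    taxonomy: Taxonomy,
    input_trees: Sequence[InputTree],
    total_species: Optional[int] = None,
) -> CoverageReport:
    """Phylogenetic coverage of the taxonomy by a set of input trees.

    A species counts as having phylogenetic information when it appears as
    a tip of at least one input tree, either directly or as the mapped
    species-rank ancestor of a below-species tip.  ``total_species``
    defaults to the number of species in the taxonomy; pass the full
    checklist count when the taxonomy covers only part of it.
    """
    species = taxonomy.species_ids()
    seen: Set[str] = set()
    for itree in input_trees:
        for label in itree.leaves:
            if label in species:
                seen.add(label)
            elif label in taxonomy.records:
                anc = taxonomy.species_ancestor(label)
                if anc is not None:
                    seen.add(anc)
    n_species = len(species)
    return CoverageReport(
        version_tag=taxonomy.version_tag,
        total_species=total_species if total_species is not None else n_species,
        species_in_taxonomy=n_species,
        species_with_phylo=len(seen),
    )
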