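"""Constrained stochastic addition of phylogenetically unsampled species.

Species present in the taxonomy but absent from every input phylogeny are
grafted into the synthesis tree using curated *addition statements*.  A
statement names the missing taxon, an ordered list of anchor clades (a
named taxon, or the MRCA of two or more listed species; most specific
last) and exclusion clades whose monophyly must not be broken.  The
algorithm searches for the most specific anchor resolvable in the current
tree, enumerates the candidate edges strictly within it (minus the
interiors of exclusion clades -- their stem stays legal, so sister-to
placements remain possible), and attaches the taxon by subdividing a
uniformly drawn candidate edge.  Randomising the statement order and
repeating yields a cloud of taxonomically complete trees.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .taxa import Taxonomy
from .trees import (
    canonicalize,
    copy_tree,
    leaf_labels,
    leafset,
    mrca,
    new_internal,
    new_leaf,
    new_tree,
)

__all__ = [
    "GraftError",
    "CladeSpec",
    "AdditionStatement",
    "CompletionSample",
    "parse_statements",
    "write_statements",
    "candidate_edges",
    "add_missing",
    "sample_completions",
]


class GraftError(ValueError):
    pass


@dataclass(frozen=True)
class CladeSpec:
    """A clade reference: a named taxon, or the MRCA of listed species."""

    taxon: Optional[str] = None
    members: Tuple[str, ...] = ()

    def species_set(self, taxonomy: Taxonomy) -> FrozenSet[str]:
        if self.taxon is not None:
            return taxonomy.species_under(self.taxon)
        return frozenset(self.members)

    def as_text(self) -> str:
        if self.taxon is not None:
            return self.taxon
        return "mrca:" + "+".join(self.members)


@dataclass
class AdditionStatement:
    """One missing taxon plus placement anchors and exclusions."""

    taxon: str
    anchors: List[CladeSpec]  # most specific last
    exclusions: List[CladeSpec] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not self.anchors:
            raise GraftError(f"statement for {self.taxon!r} has no anchors")

    def referents(self, missing: Set[str]) -> Set[str]:
        """Other missing taxa this statement's anchors refer to."""
        out: Set[str] = set()
        for spec in self.anchors:
            for m in spec.members:
                if m in missing and m != self.taxon:
                    out.add(m)
        return out


# ---------------------------------------------------------------------------
# Statement files
# ---------------------------------------------------------------------------

def _parse_spec_item(item: str, taxonomy: Taxonomy, rownum: int) -> CladeSpec:
    item = item.strip()
    if item.startswith("mrca:"):
        members = tuple(m.strip() for m in item[5:].split("+") if m.strip())
        if len(members) < 2:
            raise GraftError(f"row {rownum}: mrca spec needs >=2 species: {item!r}")
        for m in members:
            if m not in taxonomy.records:
                raise GraftError(f"row {rownum}: unknown taxon {m!r} in {item!r}")
        return CladeSpec(members=members)
    if item not in taxonomy.records:
        # allow matching by canonical name as a convenience
        by_name = [u for u, r in taxonomy.records.items() if r.name == item]
        if len(by_name) == 1:
            return CladeSpec(taxon=by_name[0])
        raise GraftError(f"row {rownum}: unknown anchor taxon {item!r}")
    return CladeSpec(taxon=item)


def parse_statements(path: str, taxonomy: Taxonomy) -> List[AdditionStatement]:
    """Read addition statements from CSV and resolve them against the taxonomy.

    Columns: ``taxon_id, anchor_spec, exclusion_spec, note``; specs are
    semicolon-separated, most specific last, with MRCA specs written
    ``mrca:idA+idB``.  Statements whose anchors reference other missing
    taxa (sister-to-another-missing-species cases) are ordered after their
    referents; circular references are an error.
    """
    statements: List[AdditionStatement] = []
    with open(path, "r", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "taxon_id" not in reader.fieldnames:
            raise GraftError(f"{path}: statement file needs a taxon_id column")
        for rownum, row in enumerate(reader, start=2):
            taxon = row["taxon_id"].strip()
            if taxon not in taxonomy.records:
                raise GraftError(f"{path}: row {rownum}: unknown taxon {taxon!r}")
            anchors = [
                _parse_spec_item(a, taxonomy, rownum)
                for a in (row.get("anchor_spec") or "").split(";")
                if a.strip()
            ]
            exclusions = [
                _parse_spec_item(e, taxonomy, rownum)
                for e in (row.get("exclusion_spec") or "").split(";")
                if e.strip()
            ]
            statements.append(
                AdditionStatement(
                    taxon=taxon,
                    anchors=anchors,
                    exclusions=exclusions,
                    note=(row.get("note") or "").strip(),
                )
            )
    return _order_by_referents(statements)


def _order_by_referents(statements: Sequence[AdditionStatement]) -> List[AdditionStatement]:
    """Stable topological order placing referents before dependents."""
    missing = {s.taxon for s in statements}
    pending = list(statements)
    done: Set[str] = set()
    out: List[AdditionStatement] = []
    while pending:
        progressed = False
        rest = []
        for s in pending:
            if s.referents(missing) <= done:
                out.append(s)
                done.add(s.taxon)
                progressed = True
            else:
                rest.append(s)
        if not progressed:
            cyc = sorted(s.taxon for s in rest)
            raise GraftError(f"circular sister references among statements: {cyc}")
        pending = rest
    return out


def write_statements(statements: Sequence[AdditionStatement], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["taxon_id", "anchor_spec", "exclusion_spec", "note"])
        for s in statements:
            writer.writerow(
                [
                    s.taxon,
                    ";".join(a.as_text() for a in s.anchors),
                    ";".join(e.as_text() for e in s.exclusions),
                    s.note,
                ]
            )


# ---------------------------------------------------------------------------
# Candidate edges
# ---------------------------------------------------------------------------

def _resolve_clade(
    tree: dendropy.Tree, spec: CladeSpec, taxonomy: Taxonomy
) -> Optional[dendropy.Node]:
    present = spec.species_set(taxonomy) & leaf_labels(tree)
    if not present:
        return None
    return mrca(tree, present)


def candidate_edges(
    tree: dendropy.Tree, statement: AdditionStatement, taxonomy: Taxonomy
) -> List[dendropy.Node]:
    """Edges (identified by their child node) legal for attaching the taxon.

    The most specific resolvable anchor wins.  Candidates are the edges
    strictly within the anchor clade (every edge below the anchor MRCA;
    the anchor's own stem is excluded -- placing sister to the whole
    anchor is not "within" it), minus edges strictly inside any exclusion
    clade, whose stem edge remains allowed so sister-to placement stays
    legal.  When the anchor resolves to a single tip, its stem edge is the
    one candidate (the sister-to-that-tip placement).
    """
    anchor_node: Optional[dendropy.Node] = None
    anchor_spec: Optional[CladeSpec] = None
    for spec in reversed(statement.anchors):  # most specific last
        anchor_node = _resolve_clade(tree, spec, taxonomy)
        if anchor_node is not None:
            anchor_spec = spec
            break
    if anchor_node is None:
        raise GraftError(
            f"statement for {statement.taxon!r}: no anchor resolvable in the tree"
        )
    if anchor_node.is_leaf():
        candidates = {id(anchor_node): anchor_node}
    else:
        candidates = {
            id(n): n for n in anchor_node.preorder_iter() if n is not anchor_node
        }
    for spec in statement.exclusions:
        excl = _resolve_clade(tree, spec, taxonomy)
        if excl is None or excl.is_leaf():
            continue
        for n in excl.preorder_iter():
            if n is not excl:  # the exclusion's stem stays allowed
                candidates.pop(id(n), None)
    if not candidates:
        # when the anchor clade is undersampled (its MRCA spans fewer
        # species than the taxonomy assigns to it) the anchor's own stem
        # is still "within" the true clade: sister to everything sampled
        full = anchor_spec.species_set(taxonomy)
        present = full & leaf_labels(tree)
        if full - present and anchor_node.parent_node is not None:
            candidates = {id(anchor_node): anchor_node}
        else:
            raise GraftError(f"over-constrained statement for {statement.taxon!r}")
    out = list(candidates.values())
    out.sort(key=lambda n: (min(leafset(n)), len(leafset(n))))
    return out


# ---------------------------------------------------------------------------
# Stochastic addition
# ---------------------------------------------------------------------------

def _shuffled_dependency_order(
    statements: Sequence[AdditionStatement], rng: np.random.Generator
) -> List[AdditionStatement]:
    perm = rng.permutation(len(statements))
    shuffled = [statements[i] for i in perm]
    return _order_by_referents(shuffled)


def add_missing(
    tree: dendropy.Tree,
    statements: Sequence[AdditionStatement],
    seed: int,
    taxonomy: Taxonomy,
) -> dendropy.Tree:
    """Attach every statement's taxon to a copy of ``tree``.

    Statements are shuffled with the seeded generator (PCG64, pinned for
    cross-platform determinism), dependency order preserved, and applied
    sequentially; each taxon subdivides a uniformly drawn candidate edge
    with a new bifurcation, so the tree stays binary at every attachment.
    """
    rng = np.random.default_rng(seed)
    work = copy_tree(tree)
    for statement in _shuffled_dependency_order(statements, rng):
        if statement.taxon in leaf_labels(work):
            raise GraftError(f"taxon {statement.taxon!r} already present in the tree")
        candidates = candidate_edges(work, statement, taxonomy)
        choice = candidates[int(rng.integers(len(candidates)))]
        parent = choice.parent_node
        if parent is None:
            raise GraftError(
                f"statement for {statement.taxon!r} selected the root edge"
            )
        new_leaf_node = new_leaf(statement.taxon)
        joint = new_internal([choice, new_leaf_node])
        kids = [joint if k is choice else k for k in parent.child_nodes()]
        parent.set_child_nodes(kids)
    work = new_tree(work.seed_node)
    canonicalize(work)
    return work


@dataclass
class CompletionSample:
    """A reproducible cloud of taxonomically complete trees."""

    trees: List[dendropy.Tree]
    seed: int
    statements_version: str = ""
    base_tree: Optional[dendropy.Tree] = None


def _clean_in_base(
    base: dendropy.Tree, spec: CladeSpec, taxonomy: Taxonomy
) -> Optional[FrozenSet[str]]:
    """The spec's members present in the base tree, if they form a clade.

    ``None`` when the clade was already non-monophyletic in the base (the
    grafting step cannot repair pre-existing conflict, so the post-hoc
    check would misfire) or has fewer than two base members.
    """
    members = spec.species_set(taxonomy) & leaf_labels(base)
    if len(members) < 2:
        return members if members else None
    return members if leafset(mrca(base, members)) == members else None


def _verify_statement(
    completion: dendropy.Tree,
    statement: AdditionStatement,
    taxonomy: Taxonomy,
    base: dendropy.Tree,
) -> Optional[str]:
    """Return a failure description, or None if the statement is satisfied.

    Checks are made against clades that were intact in the base tree;
    anchors or exclusions whose clade was already broken there are not
    re-litigated (candidate filtering enforced them at placement time).
    """
    tips = leaf_labels(completion)
    if statement.taxon not in tips:
        return f"taxon {statement.taxon!r} missing from completion"
    # most specific anchor with members beyond the focal taxon
    for spec in reversed(statement.anchors):
        others = (spec.species_set(taxonomy) & tips) - {statement.taxon}
        if not others:
            continue
        if spec.taxon is not None:
            if _clean_in_base(base, spec, taxonomy) is None:
                break
            # named clade: the group spanned by its members plus the focal
            # taxon must contain only the taxon's species
            node = mrca(completion, others | {statement.taxon})
            if not leafset(node) <= spec.species_set(taxonomy):
                return (
                    f"taxon {statement.taxon!r} placed outside anchor "
                    f"{spec.as_text()!r}"
                )
        elif len(others) >= 2:
            # MRCA clade: the focal taxon must fall inside the clade the
            # listed members span
            node = mrca(completion, others)
            if statement.taxon not in leafset(node):
                return (
                    f"taxon {statement.taxon!r} placed outside anchor "
                    f"{spec.as_text()!r}"
                )
        break
    for spec in statement.exclusions:
        base_members = _clean_in_base(base, spec, taxonomy)
        if base_members is None or len(base_members) < 2:
            continue
        node = mrca(completion, base_members)
        # only members of the excluded taxon itself may have been grafted
        # inside its clade
        if not leafset(node) <= spec.species_set(taxonomy):
            return (
                f"exclusion {spec.as_text()!r} broken by placement of "
                f"{statement.taxon!r}"
            )
    return None


def sample_completions(
    tree: dendropy.Tree,
    statements: Sequence[AdditionStatement],
    n: int,
    seed: int,
    taxonomy: Taxonomy,
    statements_version: str = "",
) -> CompletionSample:
    """Draw ``n`` independent complete trees and verify every statement.

    Sub-seeds are derived from ``seed``; every statement (anchors and
    exclusions) is re-checked post hoc on every sampled tree, and any
    violation aborts with the offending tree index and statement.
    """
    if n < 1:
        raise GraftError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    completions: List[dendropy.Tree] = []
    for i in range(n):
        comp = add_missing(tree, statements, int(sub_seeds[i]), taxonomy)
        for statement in statements:
            failure = _verify_statement(comp, statement, taxonomy, tree)
            if failure is not None:
                raise GraftError(f"completion {i}: {failure}")
        completions.append(comp)
    return CompletionSample(
        trees=completions,
        seed=seed,
        statements_version=statements_version,
        base_tree=tree,
    )
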