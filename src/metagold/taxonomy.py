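"""Minimal NCBI-taxdump-dialect taxonomy with lineage, LCA and rank queries.

Only the first three fields of ``nodes.dmp`` (taxid, parent taxid, rank) and
the "scientific name" entries of ``names.dmp`` are consumed.  That is enough
to support the rollup and partitioning logic of read classification: walking
lineages, finding lowest common ancestors, and deciding whether a taxon is
bacterial and whether it sits at or below species rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: NCBI taxid of the superkingdom Bacteria.
BACTERIA_TAXID = 2

#: NCBI taxid of the taxonomy root.
ROOT_TAXID = 1


class TaxonomyError(ValueError):
    """Malformed taxonomy input or a structurally invalid tree."""


class UnknownTaxidError(KeyError):
    """A queried taxid is not present in the tree."""

    def __init__(self, taxid: int):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"taxid {self.taxid} not present in taxonomy"


def _norm_rank(rank: str) -> str:
    return rank.strip().lower()


@dataclass
class TaxonomyTree:
    """Rank-labelled parent-pointer taxonomy.

    Attributes
    ----------
    nodes:
        Map of taxid to ``(parent_taxid, rank)``.  The root's parent is
        itself.
    names:
        Map of taxid to scientific name.  Nodes without a name entry carry a
        ``"taxid:<id>"`` placeholder.
    root_taxid:
        Taxid of the root node (1 in NCBI dumps).
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str] = field(default_factory=dict)
    root_taxid: int = ROOT_TAXID

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        try:
            return self.nodes[taxid][0]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def rank(self, taxid: int) -> str:
        try:
            return self.nodes[taxid][1]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def name(self, taxid: int) -> str:
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        return self.names.get(taxid, f"taxid:{taxid}")

    def children(self) -> dict[int, list[int]]:
        """Child lists per taxid (root is not its own child)."""
        out: dict[int, list[int]] = {t: [] for t in self.nodes}
        for taxid, (parent, _rank) in self.nodes.items():
            if taxid != parent:
                out[parent].append(taxid)
        return out

    def depth(self, taxid: int) -> int:
        """Number of edges from *taxid* up to the root."""
        return len(lineage(self, taxid)) - 1


def _parse_dmp_fields(line: str) -> list[str]:
    # taxdump lines look like "562\t|\t561\t|\tspecies\t|\t...\t|\n".
    return [f.strip("\t ") for f in line.rstrip("\n").rstrip("|").split("|")]


def load_taxonomy(
    nodes_source: Iterable[str], names_source: Iterable[str] | None = None
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes.dmp / names.dmp style streams.

    Parameters
    ----------
    nodes_source:
        Lines in nodes.dmp dialect; fields 1-3 are taxid, parent taxid, rank.
    names_source:
        Lines in names.dmp dialect; only "scientific name" entries are kept.
        May be ``None`` or empty, in which case every node gets a
        ``"taxid:<id>"`` placeholder name.

    Raises
    ------
    TaxonomyError
        On malformed lines (naming the line number), a missing parent, or a
        parent cycle that never reaches the root.
    """
    nodes: dict[int, tuple[int, str]] = {}
    for lineno, line in enumerate(nodes_source, start=1):
        if not line.strip():
            continue
        fields = _parse_dmp_fields(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes line {lineno}: expected >= 3 fields, got {len(fields)}")
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError:
            raise TaxonomyError(f"nodes line {lineno}: non-integer taxid/parent") from None
        nodes[taxid] = (parent, fields[2])

    names: dict[int, str] = {}
    if names_source is not None:
        for lineno, line in enumerate(names_source, start=1):
            if not line.strip():
                continue
            fields = _parse_dmp_fields(line)
            if len(fields) < 4:
                raise TaxonomyError(f"names line {lineno}: expected >= 4 fields, got {len(fields)}")
            if fields[3] == "scientific name":
                try:
                    names[int(fields[0])] = fields[1]
                except ValueError:
                    raise TaxonomyError(f"names line {lineno}: non-integer taxid") from None

    tree = TaxonomyTree(nodes=nodes, names=names)
    _validate_structure(tree)
    return tree


def _validate_structure(tree: TaxonomyTree) -> None:
    """Every node must reach the root by parent pointers, with no cycles."""
    ok: set[int] = set()
    for start in tree.nodes:
        path: list[int] = []
        seen: set[int] = set()
        node = start
        while node not in ok:
            if node in seen:
                raise TaxonomyError(f"cycle detected at taxid {node}")
            seen.add(node)
            path.append(node)
            parent, _rank = tree.nodes[node]
            if parent == node:  # root
                break
            if parent not in tree.nodes:
                raise TaxonomyError(f"taxid {node} has unknown parent {parent}")
            node = parent
        ok.update(path)


def lineage(tree: TaxonomyTree, taxid: int) -> list[tuple[int, str]]:
    """Ordered ``(taxid, rank)`` pairs from *taxid* up to and including root."""
    if taxid not in tree:
        raise UnknownTaxidError(taxid)
    out: list[tuple[int, str]] = []
    node = taxid
    while True:
        parent, rank = tree.nodes[node]
        out.append((node, rank))
        if parent == node:
            return out
        node = parent


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty set of taxids."""
    taxids = list(taxids)
    if not taxids:
        raise ValueError("lca of an empty taxid set is undefined")
    first = [t for t, _ in lineage(tree, taxids[0])]
    common = set(first)
    for t in taxids[1:]:
        common &= {x for x, _ in lineage(tree, t)}
    for t in first:  # first lineage is deepest-first, so the first hit is the LCA
        if t in common:
            return t
    raise TaxonomyError("taxa share no common ancestor (disconnected tree)")


def is_bacterial(tree: TaxonomyTree, taxid: int, bacteria_root: int = BACTERIA_TAXID) -> bool:
    """True iff *bacteria_root* lies on the lineage of *taxid* (inclusive)."""
    return any(t == bacteria_root for t, _ in lineage(tree, taxid))


def at_or_below_species(tree: TaxonomyTree, taxid: int) -> bool:
    """True iff the node is ranked species, or descends from a species node.

    Strain and "no rank" nodes that hang below a species node count as
    species-level; genus and higher do not.
    """
    return any(_norm_rank(rank) == "species" for _t, rank in lineage(tree, taxid))


def species_ancestor(tree: TaxonomyTree, taxid: int) -> int | None:
    """Taxid of the species-ranked node on the lineage, or None."""
    for t, rank in lineage(tree, taxid):
        if _norm_rank(rank) == "species":
            return t
    return None
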