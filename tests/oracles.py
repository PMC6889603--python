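"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity by the most direct method
available (exhaustive walks, set intersections, cumulative sums) and share
no code with the package internals they check.
"""

from __future__ import annotations

from metagold.taxonomy import TaxonomyTree


def parent_walk(tree: TaxonomyTree, taxid: int) -> list[int]:
    """Lineage by repeated single parent lookups."""
    out = [taxid]
    while True:
        parent = tree.nodes[out[-1]][0]
        if parent == out[-1]:
            return out
        out.append(parent)


def lca_by_exhaustion(tree: TaxonomyTree, taxids: set[int]) -> int:
    """Deepest node that is an ancestor-or-self of every query, found by
    checking every node of the tree."""
    best, best_depth = None, -1
    for candidate in tree.nodes:
        if all(candidate in parent_walk(tree, t) for t in taxids):
            depth = len(parent_walk(tree, candidate))
            if depth > best_depth:
                best, best_depth = candidate, depth
    assert best is not None
    return best


def clade_count(tree: TaxonomyTree, assignments: list[int], taxid: int) -> int:
    """Reads whose full lineage contains *taxid* (taxid 0 = unclassified)."""
    return sum(1 for a in assignments if a != 0 and taxid in parent_walk(tree, a))


def mimag_tier_name(
    completeness: float,
    contamination: float,
    has_all_rrnas: bool,
    trna_count: int,
) -> str:
    """Direct transcription of the draft-genome tier table."""
    if completeness > 90 and contamination < 5 and has_all_rrnas and trna_count >= 18:
        return "HIGH"
    if completeness >= 50 and contamination < 10:
        return "MEDIUM"
    if completeness < 50 and contamination < 10:
        return "LOW"
    return "FAILED"


def phylotype_by_rank_walk(
    markers: list[dict[str, tuple[str, float]]],
    threshold: float = 0.8,
    rank_order: tuple[str, ...] = (
        "superkingdom", "phylum", "class", "order", "family", "genus", "species",
    ),
):
    """Exhaustive rank walk over plain-dict markers.

    Each marker is {rank: (taxon, confidence)}.  Returns (rank, taxon) or None.
    """
    surviving = [
        {r: t for r, (t, c) in m.items() if c > threshold} for m in markers
    ]
    domains = {m["superkingdom"] for m in surviving if "superkingdom" in m}
    if "Bacteria" in domains and "Archaea" in domains:
        return None
    for rank in rank_order[::-1]:
        taxa = [m.get(rank) for m in surviving]
        if None not in taxa and len(set(taxa)) == 1:
            return rank, taxa[0]
    return None


def n50_by_cumsum(lengths: list[int], min_length: int) -> int:
    kept = sorted((l for l in lengths if l >= min_length), reverse=True)
    if not kept:
        return 0
    half = sum(kept) / 2
    acc = 0
    for l in kept:
        acc += l
        if acc >= half:
            return l
    return kept[-1]
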