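import numpy as np
import pytest

from metagold.taxonomy import TaxonomyTree

RANK_POOL = [
    "no rank", "superkingdom", "phylum", "class", "order",
    "family", "genus", "species", "strain",
]


def make_tree(nodes: dict[int, tuple[int, str]], names: dict[int, str] | None = None) -> TaxonomyTree:
    return TaxonomyTree(nodes=dict(nodes), names=dict(names or {}))


@pytest.fixture
def tiny_tree() -> TaxonomyTree:
    """root -> {Bacteria -> genus -> 2 species (one with a strain), Eukaryota -> host}."""
    return make_tree(
        {
            1: (1, "no rank"),
            2: (1, "superkingdom"),
            561: (2, "genus"),
            562: (561, "species"),
            5620: (562, "no rank"),  # strain below species
            620: (561, "species"),
            2759: (1, "superkingdom"),
            9606: (2759, "species"),
        },
        {1: "root", 2: "Bacteria", 561: "Escherichia", 562: "Escherichia coli",
         5620: "E. coli K-12", 620: "Shigella", 2759: "Eukaryota", 9606: "Homo sapiens"},
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rank-labelled tree: node i attaches to a uniformly chosen earlier node."""
    nodes: dict[int, tuple[int, str]] = {1: (1, "no rank")}
    taxids = [1]
    for i in range(2, n_nodes + 1):
        parent = int(taxids[rng.integers(0, len(taxids))])
        rank = RANK_POOL[rng.integers(0, len(RANK_POOL))]
        nodes[i] = (parent, rank)
        taxids.append(i)
    return make_tree(nodes)
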