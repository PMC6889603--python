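"""Match species/strain-level classified read counts to a reference-genome
catalog and emit the exact-count simulation recipe with coverage statistics.

Reads that cannot be matched to any catalog genome are *dropped*, never
redistributed; the drop counts are first-class outputs because they describe
how faithfully a gold standard can represent its source sample.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

from . import taxonomy as tax
from .classification import ReadPartition
from .taxonomy import TaxonomyTree


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogEntry:
    accession: str
    taxid: int
    species_taxid: int
    genome_length: int
    fasta_path: str
    representative: bool = False


@dataclass
class GenomeCatalog:
    """Reference genomes indexed by exact taxid and by species taxid."""

    entries: list[CatalogEntry]
    by_taxid: dict[int, CatalogEntry] = field(default_factory=dict)
    by_species: dict[int, list[CatalogEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_taxid:
            for e in self.entries:
                self.by_taxid.setdefault(e.taxid, e)
                self.by_species.setdefault(e.species_taxid, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)


def load_catalog(stream: Iterable[str]) -> GenomeCatalog:
    """Load a 5(+1)-column TSV catalog (header required).

    Columns: accession, taxid, species_taxid, genome_length, fasta_path and an
    optional boolean ``representative`` column used to break ties when several
    strains share a species taxid.
    """
    reader = csv.DictReader(stream, delimiter="\t")
    required = {"accession", "taxid", "species_taxid", "genome_length", "fasta_path"}
    if reader.fieldnames is None:
        raise CatalogError("catalog is empty (no header)")
    missing = required - set(reader.fieldnames)
    if missing:
        raise CatalogError(f"catalog header missing columns: {sorted(missing)}")

    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    for row in reader:
        acc = row["accession"].strip()
        if acc in seen:
            raise CatalogError(f"duplicate accession {acc!r}")
        seen.add(acc)
        length = int(row["genome_length"])
        if length <= 0:
            raise CatalogError(f"accession {acc!r}: non-positive genome_length {length}")
        rep = str(row.get("representative", "")).strip().lower() in {"1", "true", "yes", "y"}
        entries.append(
            CatalogEntry(acc, int(row["taxid"]), int(row["species_taxid"]), length, row["fasta_path"], rep)
        )
    return GenomeCatalog(entries)


@dataclass(frozen=True)
class RecipeItem:
    accession: str
    taxid_classified: int
    n_reads: int
    n_pairs: int


@dataclass
class Recipe:
    """Exact per-genome read(-pair) counts plus drop bookkeeping."""

    items: list[RecipeItem]
    dropped_no_reference: int
    dropped_above_species: int
    read_length: int

    def total_assigned_reads(self) -> int:
        return sum(i.n_reads for i in self.items)


def _pick_entry(candidates: list[CatalogEntry]) -> CatalogEntry:
    """Deterministic strain pick: representative flag wins, then smallest accession."""
    reps = [e for e in candidates if e.representative]
    pool = reps or candidates
    return min(pool, key=lambda e: e.accession)


def resolve_reference(
    taxid: int, catalog: GenomeCatalog, tree: TaxonomyTree
) -> CatalogEntry | None:
    """Reference genome for a species-or-below classified taxid, or None.

    Lookup order: exact taxid match; any strain whose species taxid equals the
    query; then the same two lookups keyed by the query's species ancestor.
    """
    if taxid in catalog.by_taxid:
        return catalog.by_taxid[taxid]
    if taxid in catalog.by_species:
        return _pick_entry(catalog.by_species[taxid])
    species = tax.species_ancestor(tree, taxid)
    if species is not None and species != taxid:
        if species in catalog.by_taxid:
            return catalog.by_taxid[species]
        if species in catalog.by_species:
            return _pick_entry(catalog.by_species[species])
    return None


def build_recipe(
    partition: ReadPartition,
    catalog: GenomeCatalog,
    tree: TaxonomyTree,
    read_length: int,
    reads_per_fragment: int = 2,
) -> Recipe:
    """Turn the species-level read partition into an exact-count recipe.

    Each classified taxid with a resolvable reference genome becomes one item
    carrying the exact read count observed for it; taxa without a reference
    contribute to ``dropped_no_reference``.  ``reads_per_fragment`` converts
    the fragment-level partition into read counts (2 for paired-end input,
    1 for single-end).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    items: list[RecipeItem] = []
    dropped_no_ref = 0
    for taxid in sorted(partition.bacterial_species_level):
        n_fragments = len(partition.bacterial_species_level[taxid])
        n_reads = n_fragments * reads_per_fragment
        entry = resolve_reference(taxid, catalog, tree)
        if entry is None:
            dropped_no_ref += n_reads
        else:
            items.append(RecipeItem(entry.accession, taxid, n_reads, math.ceil(n_reads / 2)))
    return Recipe(
        items=items,
        dropped_no_reference=dropped_no_ref,
        dropped_above_species=len(partition.bacterial_above_species) * reads_per_fragment,
        read_length=read_length,
    )


@dataclass
class RecipeStats:
    """Assignment fraction and expected per-genome coverage of a recipe."""

    assigned_fraction: float  # of all classified bacterial reads, in [0, 1]
    coverage: dict[str, float]  # accession -> expected mean depth (x)
    max_coverage: float
    n_genomes_cov_ge_1: int
    n_genomes: int
    no_bacterial_reads: bool = False  # warning flag for empty input


def recipe_stats(recipe: Recipe, catalog: GenomeCatalog) -> RecipeStats:
    """Expected coverage (reads x read length / genome length) and the
    fraction of classified bacterial reads that reached a reference genome."""
    coverage: dict[str, float] = {}
    for item in recipe.items:
        entry = next(e for e in catalog.entries if e.accession == item.accession)
        coverage[item.accession] = (
            coverage.get(item.accession, 0.0)
            + item.n_reads * recipe.read_length / entry.genome_length
        )
    assigned = recipe.total_assigned_reads()
    denom = assigned + recipe.dropped_no_reference + recipe.dropped_above_species
    return RecipeStats(
        assigned_fraction=(assigned / denom) if denom else 0.0,
        coverage=coverage,
        max_coverage=max(coverage.values(), default=0.0),
        n_genomes_cov_ge_1=sum(1 for c in coverage.values() if c >= 1.0),
        n_genomes=len(coverage),
        no_bacterial_reads=denom == 0,
    )


def write_recipe(recipe: Recipe, handle: IO[str]) -> None:
    handle.write("#read_length\t%d\n" % recipe.read_length)
    handle.write("#dropped_no_reference\t%d\n" % recipe.dropped_no_reference)
    handle.write("#dropped_above_species\t%d\n" % recipe.dropped_above_species)
    handle.write("accession\ttaxid_classified\tn_reads\tn_pairs\n")
    for item in recipe.items:
        handle.write(f"{item.accession}\t{item.taxid_classified}\t{item.n_reads}\t{item.n_pairs}\n")


def read_recipe(stream: Iterable[str]) -> Recipe:
    meta: dict[str, int] = {}
    items: list[RecipeItem] = []
    header_seen = False
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            key, value = line[1:].split("\t")
            meta[key] = int(value)
        elif not header_seen:
            header_seen = True
        else:
            acc, taxid, n_reads, n_pairs = line.split("\t")
            items.append(RecipeItem(acc, int(taxid), int(n_reads), int(n_pairs)))
    return Recipe(
        items=items,
        dropped_no_reference=meta.get("dropped_no_reference", 0),
        dropped_above_species=meta.get("dropped_above_species", 0),
        read_length=meta.get("read_length", 0),
    )


def stats_to_json(stats: RecipeStats) -> str:
    return json.dumps(
        {
            "assigned_fraction": stats.assigned_fraction,
            "max_coverage": stats.max_coverage,
            "n_genomes": stats.n_genomes,
            "n_genomes_cov_ge_1": stats.n_genomes_cov_ge_1,
            "no_bacterial_reads": stats.no_bacterial_reads,
            "coverage": stats.coverage,
        },
        indent=2,
        sort_keys=True,
    )
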