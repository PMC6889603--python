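"""Per-read classifier output: parsing, multi-hit collapse, Kraken-style
reports, and the four-way read partition used to build gold standards.

The classification unit is the sequenced fragment: for paired-end data a
classifier such as Centrifuge scores both mates jointly and emits one (or,
with multi-matches, several) rows per fragment.  Read ids are therefore
handled with any ``/1``/``/2`` mate suffix stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

from . import taxonomy as tax
from .taxonomy import TaxonomyTree, UnknownTaxidError


@dataclass(frozen=True)
class ReadHit:
    """One classifier match line: a (read, matched taxon) pair."""

    read_id: str
    taxid: int  # 0 = unclassified
    score: float = 0.0
    num_matches: int = 1


@dataclass(frozen=True)
class ReadClassification:
    """Final single assignment per read after multi-hit collapse."""

    read_id: str
    taxid: int


@dataclass(frozen=True)
class KreportRow:
    percent: float  # of total reads, 0-100
    clade_reads: int
    direct_reads: int
    rank_code: str  # single character
    taxid: int
    name: str  # two spaces of indentation per tree level


@dataclass
class ReadPartition:
    """Disjoint 4-way split of a sample's reads.

    ``bacterial_species_level`` holds reads classified to a bacterial taxon at
    or below species rank, keyed by that taxid.  ``bacterial_above_species``
    holds bacterial reads classified only to genus or higher.  Everything
    classified but non-bacterial goes to ``nonbacterial_classified``;
    taxid 0 goes to ``unclassified``.
    """

    bacterial_species_level: dict[int, list[str]] = field(default_factory=dict)
    bacterial_above_species: set[str] = field(default_factory=set)
    nonbacterial_classified: set[str] = field(default_factory=set)
    unclassified: set[str] = field(default_factory=set)

    def all_read_ids(self) -> set[str]:
        ids: set[str] = set()
        for reads in self.bacterial_species_level.values():
            ids.update(reads)
        return ids | self.bacterial_above_species | self.nonbacterial_classified | self.unclassified

    def bacterial_read_ids(self) -> set[str]:
        """Ids of every bacterial-classified read (species level or above)."""
        ids = set(self.bacterial_above_species)
        for reads in self.bacterial_species_level.values():
            ids.update(reads)
        return ids

    def n_bacterial_species_reads(self) -> int:
        return sum(len(v) for v in self.bacterial_species_level.values())


class ClassificationParseError(ValueError):
    pass


def parse_centrifuge(stream: Iterable[str]) -> list[ReadHit]:
    """Parse Centrifuge per-read tabular output into :class:`ReadHit` rows.

    Accepts the stream with or without its ``readID\\tseqID\\ttaxID...``
    header.  Rows whose seqID is ``unclassified`` carry taxid 0.
    """
    hits: list[ReadHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if lineno == 1 and fields and fields[0] == "readID":
            continue
        if len(fields) < 3:
            raise ClassificationParseError(
                f"line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
            )
        try:
            taxid = int(fields[2])
        except ValueError:
            raise ClassificationParseError(f"line {lineno}: non-integer taxid {fields[2]!r}") from None
        score = 0.0
        if len(fields) > 3:
            try:
                score = float(fields[3])
            except ValueError:
                score = 0.0
        num_matches = 1
        if len(fields) > 7:
            try:
                num_matches = int(fields[7])
            except ValueError:
                num_matches = 1
        if fields[1] == "unclassified":
            taxid = 0
        hits.append(ReadHit(fields[0], taxid, score, max(1, num_matches)))
    return hits


def collapse_multihits(hits: Iterable[ReadHit], tree: TaxonomyTree) -> list[ReadClassification]:
    """Collapse multi-match reads to their LCA; one record per read.

    Unclassified (taxid 0) hits are ignored whenever the read also has a
    classified hit; a read with only taxid-0 hits stays unclassified.
    Output preserves first-seen read order.
    """
    order: list[str] = []
    by_read: dict[str, set[int]] = {}
    for hit in hits:
        if hit.read_id not in by_read:
            by_read[hit.read_id] = set()
            order.append(hit.read_id)
        by_read[hit.read_id].add(hit.taxid)

    unknown = sorted(
        {t for taxids in by_read.values() for t in taxids if t != 0 and t not in tree}
    )
    if unknown:
        raise UnknownTaxidError(unknown[0]) if len(unknown) == 1 else TaxidLookupError(unknown)

    out: list[ReadClassification] = []
    for read_id in order:
        taxids = by_read[read_id] - {0}
        if not taxids:
            assigned = 0
        elif len(taxids) == 1:
            assigned = next(iter(taxids))
        else:
            assigned = tax.lca(tree, taxids)
        out.append(ReadClassification(read_id, assigned))
    return out


class TaxidLookupError(KeyError):
    """Several classification taxids are absent from the taxonomy."""

    def __init__(self, taxids: list[int]):
        super().__init__(tuple(taxids))
        self.taxids = taxids

    def __str__(self) -> str:
        return f"taxids not present in taxonomy: {self.taxids}"


# Kraken rank codes; ranks not listed print "-" (indentation still shows depth).
_RANK_CODES = {
    "superkingdom": "D",
    "domain": "D",
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


def _rank_code(tree: TaxonomyTree, taxid: int) -> str:
    if taxid == tree.root_taxid:
        return "R"
    return _RANK_CODES.get(tree.rank(taxid).strip().lower(), "-")


def to_kreport(
    classifications: Iterable[ReadClassification], tree: TaxonomyTree
) -> list[KreportRow]:
    """Roll per-read assignments up into a Kraken-style hierarchical report.

    The first row is the unclassified ("U") row; classified rows follow in
    depth-first taxonomy order, children sorted by descending clade count and
    then ascending taxid.  Only taxa with a non-zero clade count appear.
    """
    classifications = list(classifications)
    total = len(classifications)
    direct: dict[int, int] = {}
    n_unclassified = 0
    for rec in classifications:
        if rec.taxid == 0:
            n_unclassified += 1
        else:
            if rec.taxid not in tree:
                raise UnknownTaxidError(rec.taxid)
            direct[rec.taxid] = direct.get(rec.taxid, 0) + 1

    clade: dict[int, int] = {}
    for taxid, n in direct.items():
        for anc, _rank in tax.lineage(tree, taxid):
            clade[anc] = clade.get(anc, 0) + n

    def pct(n: int) -> float:
        return round(100.0 * n / total, 2) if total else 0.0

    rows: list[KreportRow] = [
        KreportRow(pct(n_unclassified), n_unclassified, n_unclassified, "U", 0, "unclassified")
    ]
    if not clade:
        return rows

    children = tree.children()

    def walk(taxid: int, depth: int) -> None:
        rows.append(
            KreportRow(
                pct(clade[taxid]),
                clade[taxid],
                direct.get(taxid, 0),
                _rank_code(tree, taxid),
                taxid,
                "  " * depth + tree.name(taxid),
            )
        )
        kids = [c for c in children.get(taxid, []) if c in clade]
        kids.sort(key=lambda c: (-clade[c], c))
        for kid in kids:
            walk(kid, depth + 1)

    walk(tree.root_taxid, 0)
    return rows


def write_kreport(rows: Iterable[KreportRow], handle: IO[str]) -> None:
    for row in rows:
        handle.write(
            f"{row.percent:.2f}\t{row.clade_reads}\t{row.direct_reads}\t"
            f"{row.rank_code}\t{row.taxid}\t{row.name}\n"
        )


def parse_kreport(stream: Iterable[str]) -> list[KreportRow]:
    rows: list[KreportRow] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ClassificationParseError(f"kreport line {lineno}: expected 6 columns")
        rows.append(
            KreportRow(
                float(fields[0]), int(fields[1]), int(fields[2]), fields[3], int(fields[4]), fields[5]
            )
        )
    return rows


def partition_reads(
    classifications: Iterable[ReadClassification],
    tree: TaxonomyTree,
    bacteria_root: int = tax.BACTERIA_TAXID,
) -> ReadPartition:
    """Split reads into the four groups the gold-standard build consumes."""
    part = ReadPartition()
    for rec in classifications:
        if rec.taxid == 0:
            part.unclassified.add(rec.read_id)
        elif tax.is_bacterial(tree, rec.taxid, bacteria_root):
            if tax.at_or_below_species(tree, rec.taxid):
                part.bacterial_species_level.setdefault(rec.taxid, []).append(rec.read_id)
            else:
                part.bacterial_above_species.add(rec.read_id)
        else:
            part.nonbacterial_classified.add(rec.read_id)
    return part
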