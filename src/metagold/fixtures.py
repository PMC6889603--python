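"""Fully synthetic, truth-annotated inputs for the gold-standard pipeline.

The generator emulates a quality-controlled urban shotgun sample: a
bacterial fraction drawn error-free from known synthetic genomes, a host
(human-like) fraction, and an "unknown" fraction of random DNA that no
classifier could place.  It writes every format the real pipeline consumes
— paired FASTQ, genome FASTA files, a reference catalog, a taxdump-dialect
taxonomy, and a Centrifuge-format per-read classification table — all
mutually consistent and reproducible from a single seed.

Two knobs exercise the drop paths of the recipe builder: a configurable
fraction of bacterial fragments is classified to the parent genus instead
of the species (the above-species drop), and taxa can be flagged as absent
from the catalog (the no-reference drop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._io import atomic_write

HOST_TAXID = 9606
EUKARYOTA_TAXID = 2759
_GENUS_OFFSET = 100000  # fixture genus taxid = species taxid + offset


@dataclass(frozen=True)
class TaxonSpec:
    taxid: int
    genome_length: int
    read_pairs: int
    gc: float = 0.5
    in_catalog: bool = True


@dataclass
class CommunitySpec:
    """Study conditions of one synthetic sample."""

    taxa: list[TaxonSpec]
    host_pairs: int = 0
    unknown_pairs: int = 0
    read_length: int = 101
    seed: int = 0
    # fraction of bacterial fragments classified only to the parent genus
    misclassify_to_genus_fraction: float = 0.0
    # fraction of fragments shortened as if quality-trimmed (70 bp minimum)
    trimmed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(t.read_pairs < 0 for t in self.taxa) or self.host_pairs < 0 or self.unknown_pairs < 0:
            raise ValueError("read counts must be >= 0")
        total = sum(t.read_pairs for t in self.taxa) + self.host_pairs + self.unknown_pairs
        if total == 0:
            raise ValueError("at least one read category must be non-zero")
        taxids = [t.taxid for t in self.taxa]
        if len(set(taxids)) != len(taxids):
            raise ValueError("taxon taxids must be unique")


def make_genome(length: int, gc: float, seed: int) -> SeqRecord:
    """Deterministic random genome with the requested GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return SeqRecord(Seq(seq.tobytes().decode("ascii")), id=f"synth{seed}", description="")


@dataclass
class MockSample:
    """Paths plus ground truth of a generated sample."""

    spec: CommunitySpec
    r1_path: Path
    r2_path: Path
    classification_path: Path
    nodes_path: Path
    names_path: Path
    catalog_path: Path
    genome_paths: dict[str, Path]  # accession -> FASTA (incl. host)
    # fragment-level truth, all counts in pairs
    species_pairs: dict[int, int] = field(default_factory=dict)  # classified at species
    above_species_pairs: int = 0
    no_reference_pairs: int = 0
    host_pairs: int = 0
    unknown_pairs: int = 0

    def accession_for(self, taxid: int) -> str:
        return f"ACC{taxid:07d}.1"


def _write_fasta(record: SeqRecord, path: Path) -> None:
    with atomic_write(path) as handle:
        handle.write(f">{record.id}\n")
        seq = str(record.seq)
        for i in range(0, len(seq), 80):
            handle.write(seq[i : i + 80] + "\n")


def _draw_pair(
    genome: np.ndarray, read_length: int, rng: np.random.Generator
) -> tuple[str, str]:
    """One error-free pair from a linear genome (R1 forward, R2 revcomp)."""
    frag_mean = min(350.0, len(genome) / 2)
    frag_len = int(round(rng.normal(frag_mean, frag_mean / 10)))
    frag_len = max(read_length, min(frag_len, len(genome)))
    start = int(rng.integers(0, len(genome) - frag_len + 1))
    fragment = genome[start : start + frag_len]
    r1 = fragment[:read_length].tobytes().decode("ascii")
    r2 = fragment[frag_len - read_length :].tobytes().decode("ascii")
    comp = str.maketrans("ACGT", "TGCA")
    return r1, r2.translate(comp)[::-1]


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode("ascii")


def make_mock_sample(spec: CommunitySpec, out_dir: str | Path) -> MockSample:
    """Generate all pipeline inputs for *spec* under *out_dir*."""
    out_dir = Path(out_dir)
    genomes_dir = out_dir / "genomes"
    genomes_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    sample = MockSample(
        spec=spec,
        r1_path=out_dir / "sample_R1.fastq",
        r2_path=out_dir / "sample_R2.fastq",
        classification_path=out_dir / "classification.tsv",
        nodes_path=out_dir / "nodes.dmp",
        names_path=out_dir / "names.dmp",
        catalog_path=out_dir / "catalog.tsv",
        genome_paths={},
        host_pairs=spec.host_pairs,
        unknown_pairs=spec.unknown_pairs,
    )

    # --- taxonomy dump -----------------------------------------------------
    nodes = [(1, 1, "no rank"), (2, 1, "superkingdom"), (EUKARYOTA_TAXID, 1, "superkingdom")]
    names = {1: "root", 2: "Bacteria", EUKARYOTA_TAXID: "Eukaryota", HOST_TAXID: "Homo sapiens"}
    nodes.append((HOST_TAXID, EUKARYOTA_TAXID, "species"))
    for taxon in spec.taxa:
        genus = taxon.taxid + _GENUS_OFFSET
        nodes.append((genus, 2, "genus"))
        nodes.append((taxon.taxid, genus, "species"))
        names[genus] = f"Synthogenus g{taxon.taxid}"
        names[taxon.taxid] = f"Synthobacter sp. {taxon.taxid}"
    with atomic_write(sample.nodes_path) as handle:
        for taxid, parent, rank in nodes:
            handle.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with atomic_write(sample.names_path) as handle:
        for taxid, name in sorted(names.items()):
            handle.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")

    # --- genomes and catalog ----------------------------------------------
    genomes: dict[int, np.ndarray] = {}
    catalog_rows: list[str] = []
    for taxon in spec.taxa:
        acc = sample.accession_for(taxon.taxid)
        record = make_genome(taxon.genome_length, taxon.gc, seed=int(rng.integers(2**31)))
        record.id = acc
        path = genomes_dir / f"{acc}.fasta"
        _write_fasta(record, path)
        genomes[taxon.taxid] = np.frombuffer(str(record.seq).encode(), dtype=np.uint8)
        sample.genome_paths[acc] = path
        if taxon.in_catalog:
            catalog_rows.append(f"{acc}\t{taxon.taxid}\t{taxon.taxid}\t{taxon.genome_length}\t{path}")
    with atomic_write(sample.catalog_path) as handle:
        handle.write("accession\ttaxid\tspecies_taxid\tgenome_length\tfasta_path\n")
        for row in catalog_rows:
            handle.write(row + "\n")

    host_genome: np.ndarray | None = None
    if spec.host_pairs:
        host_record = make_genome(
            max(50_000, 4 * spec.read_length), 0.41, seed=int(rng.integers(2**31))
        )
        host_record.id = "HOST0000001.1"
        host_path = genomes_dir / "HOST0000001.1.fasta"
        _write_fasta(host_record, host_path)
        sample.genome_paths["HOST0000001.1"] = host_path
        host_genome = np.frombuffer(str(host_record.seq).encode(), dtype=np.uint8)

    # --- reads and classification ------------------------------------------
    # fragments: (category, taxid_for_classification, r1, r2)
    fragments: list[tuple[str, int, str, str]] = []
    for taxon in spec.taxa:
        genome = genomes[taxon.taxid]
        for _ in range(taxon.read_pairs):
            r1, r2 = _draw_pair(genome, spec.read_length, rng)
            if rng.random() < spec.misclassify_to_genus_fraction:
                fragments.append(("above_species", taxon.taxid + _GENUS_OFFSET, r1, r2))
                sample.above_species_pairs += 1
            else:
                fragments.append(("species", taxon.taxid, r1, r2))
                sample.species_pairs[taxon.taxid] = sample.species_pairs.get(taxon.taxid, 0) + 1
                if not taxon.in_catalog:
                    sample.no_reference_pairs += 1
    for _ in range(spec.host_pairs):
        r1, r2 = _draw_pair(host_genome, spec.read_length, rng)
        fragments.append(("host", HOST_TAXID, r1, r2))
    for _ in range(spec.unknown_pairs):
        fragments.append(
            ("unknown", 0, _random_seq(spec.read_length, rng), _random_seq(spec.read_length, rng))
        )

    order = rng.permutation(len(fragments))
    with atomic_write(sample.r1_path) as r1_out, atomic_write(sample.r2_path) as r2_out, \
            atomic_write(sample.classification_path) as cls_out:
        cls_out.write(
            "readID\tseqID\ttaxID\tscore\t2ndBestScore\thitLength\tqueryLength\tnumMatches\n"
        )
        for serial, idx in enumerate(order):
            category, taxid, r1, r2 = fragments[idx]
            frag_id = f"sample.{serial}"
            if spec.trimmed_fraction and rng.random() < spec.trimmed_fraction:
                keep1 = int(rng.integers(70, spec.read_length + 1))
                keep2 = int(rng.integers(70, spec.read_length + 1))
                r1, r2 = r1[:keep1], r2[:keep2]
            r1_out.write(f"@{frag_id}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            r2_out.write(f"@{frag_id}/2\n{r2}\n+\n{'I' * len(r2)}\n")
            if category == "unknown":
                cls_out.write(
                    f"{frag_id}\tunclassified\t0\t0\t0\t0\t{len(r1) + len(r2)}\t1\n"
                )
            else:
                seq_id = f"tax{taxid}" if category != "host" else "HOST0000001.1"
                cls_out.write(
                    f"{frag_id}\t{seq_id}\t{taxid}\t900\t0\t{len(r1)}\t{len(r1) + len(r2)}\t1\n"
                )
    return sample


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """A small urban-sample-like community: ~74% bacterial, ~24% unknown and
    ~2% host fragments, with a log-spread of species abundances."""
    pair_counts = [600, 350, 200, 120, 80, 50, 40, 25, 15, 3]
    rng = np.random.default_rng(seed)
    taxa = [
        TaxonSpec(
            taxid=561000 + i,
            genome_length=int(rng.integers(15_000, 40_000)),
            read_pairs=n,
            gc=float(rng.uniform(0.35, 0.65)),
        )
        for i, n in enumerate(pair_counts)
    ]
    return CommunitySpec(taxa=taxa, host_pairs=40, unknown_pairs=480, read_length=101, seed=seed)
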