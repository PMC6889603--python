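"""Splice simulated bacterial reads into a real sample.

The targeted gold standard keeps every unclassified and non-bacterial read
of the original sample byte-identically (preserving its real error
structure and complexity), removes every bacterial-classified read, and
appends the simulated replacement reads.  The result is a benchmark sample
whose bacterial fraction has a fully known truth while the hard, unknown
background is real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import fragment_id
from .classification import ReadPartition
from .recipe import Recipe


class GoldStandardError(ValueError):
    pass


@dataclass(frozen=True)
class ManifestRow:
    read_id: str  # fragment-level id
    origin: str  # retained_unclassified | retained_nonbacterial | simulated
    accession: str = "-"
    start: int | None = None
    end: int | None = None


@dataclass
class TruthManifest:
    rows: list[ManifestRow]

    def counts(self) -> dict[str, int]:
        out = {"retained_unclassified": 0, "retained_nonbacterial": 0, "simulated": 0}
        for row in self.rows:
            out[row.origin] += 1
        return out


@dataclass
class CompositionSummary:
    """Tally of where every output fragment came from and what happened to
    the bacterial fraction of the input."""

    retained_unclassified: int
    retained_nonbacterial: int
    simulated: int
    dropped_no_reference: int  # fragments of the input, not in the output
    dropped_above_species: int
    total_in: int
    total_out: int
    bp_in: int
    bp_out: int

    def output_fractions(self) -> dict[str, float]:
        total = self.total_out or 1
        return {
            "retained_unclassified": self.retained_unclassified / total,
            "retained_nonbacterial": self.retained_nonbacterial / total,
            "simulated": self.simulated / total,
        }


def build_gold_standard(
    orig_r1: Iterable[str],
    orig_r2: Iterable[str],
    partition: ReadPartition,
    sim_r1: Iterable[str],
    sim_r2: Iterable[str],
    gs_r1_out: IO[str],
    gs_r2_out: IO[str],
    recipe: Recipe | None = None,
    manifest_out: IO[str] | None = None,
) -> tuple[TruthManifest, CompositionSummary]:
    """Build the gold-standard FASTQ pair, truth manifest and composition.

    Original pairs whose fragment id is bacterial-classified (species level
    or above) are removed; all others are copied through unchanged.  The
    simulated pairs are appended afterwards.  Drop counts are taken from
    *recipe* when given (fragments = reads / 2 for paired input), else from
    the partition alone (no-reference drops unknown without a recipe).
    """
    bacterial = {fragment_id(r) for r in partition.bacterial_read_ids()}
    unclassified = {fragment_id(r) for r in partition.unclassified}
    nonbacterial = {fragment_id(r) for r in partition.nonbacterial_classified}

    rows: list[ManifestRow] = []
    seen: set[str] = set()
    total_in = 0
    bp_in = 0
    bp_out = 0
    n_removed = 0
    for (id1, seq1, qual1), (id2, seq2, qual2) in zip(
        FastqGeneralIterator(orig_r1), FastqGeneralIterator(orig_r2), strict=True
    ):
        frag = fragment_id(id1)
        if frag != fragment_id(id2):
            raise GoldStandardError(f"desynchronized original pair: {id1!r} vs {id2!r}")
        total_in += 1
        bp_in += len(seq1) + len(seq2)
        seen.add(frag)
        if frag in bacterial:
            n_removed += 1
            continue
        gs_r1_out.write(f"@{id1}\n{seq1}\n+\n{qual1}\n")
        gs_r2_out.write(f"@{id2}\n{seq2}\n+\n{qual2}\n")
        bp_out += len(seq1) + len(seq2)
        if frag in unclassified:
            rows.append(ManifestRow(frag, "retained_unclassified"))
        elif frag in nonbacterial:
            rows.append(ManifestRow(frag, "retained_nonbacterial"))
        else:
            raise GoldStandardError(
                f"original read {frag!r} is in no partition group; "
                "partition does not cover the input sample"
            )

    missing = (bacterial | unclassified | nonbacterial) - seen
    if missing:
        examples = sorted(missing)[:5]
        raise GoldStandardError(
            f"{len(missing)} partition read id(s) absent from the original sample, e.g. {examples}"
        )

    n_simulated = 0
    for (id1, seq1, qual1), (id2, seq2, qual2) in zip(
        FastqGeneralIterator(sim_r1), FastqGeneralIterator(sim_r2), strict=True
    ):
        frag = fragment_id(id1)
        if frag != fragment_id(id2):
            raise GoldStandardError(f"desynchronized simulated pair: {id1!r} vs {id2!r}")
        gs_r1_out.write(f"@{id1}\n{seq1}\n+\n{qual1}\n")
        gs_r2_out.write(f"@{id2}\n{seq2}\n+\n{qual2}\n")
        bp_out += len(seq1) + len(seq2)
        n_simulated += 1
        parts = frag.split("|")
        if len(parts) == 6 and parts[0] == "gs":
            rows.append(ManifestRow(frag, "simulated", parts[1], int(parts[3]), int(parts[4])))
        else:
            rows.append(ManifestRow(frag, "simulated", "?"))

    manifest = TruthManifest(rows)
    if manifest_out is not None:
        write_manifest(manifest, manifest_out)

    if recipe is not None:
        dropped_no_ref = recipe.dropped_no_reference // 2
        dropped_above = recipe.dropped_above_species // 2
    else:
        dropped_no_ref = 0
        dropped_above = len({fragment_id(r) for r in partition.bacterial_above_species})
    summary = CompositionSummary(
        retained_unclassified=sum(1 for r in rows if r.origin == "retained_unclassified"),
        retained_nonbacterial=sum(1 for r in rows if r.origin == "retained_nonbacterial"),
        simulated=n_simulated,
        dropped_no_reference=dropped_no_ref,
        dropped_above_species=dropped_above,
        total_in=total_in,
        total_out=total_in - n_removed + n_simulated,
        bp_in=bp_in,
        bp_out=bp_out,
    )
    return manifest, summary


def write_manifest(manifest: TruthManifest, handle: IO[str]) -> None:
    handle.write("read_id\torigin\taccession\tstart\tend\n")
    for row in manifest.rows:
        start = "-" if row.start is None else str(row.start)
        end = "-" if row.end is None else str(row.end)
        handle.write(f"{row.read_id}\t{row.origin}\t{row.accession}\t{start}\t{end}\n")


def summarize_composition(
    manifest: TruthManifest,
    recipe: Recipe | None,
    read_lengths: dict[str, int],
    total_in: int,
    bp_in: int,
) -> CompositionSummary:
    """Recompute a :class:`CompositionSummary` from a manifest.

    *read_lengths* maps fragment id to the total bp of the output fragment
    (both mates).  Simulated fragments run at the full profile read length,
    which is why a gold standard can carry more bp than its source even
    after dropping unassignable bacterial reads.
    """
    counts = manifest.counts()
    bp_out = sum(read_lengths[row.read_id] for row in manifest.rows)
    dropped_no_ref = (recipe.dropped_no_reference // 2) if recipe else 0
    dropped_above = (recipe.dropped_above_species // 2) if recipe else 0
    return CompositionSummary(
        retained_unclassified=counts["retained_unclassified"],
        retained_nonbacterial=counts["retained_nonbacterial"],
        simulated=counts["simulated"],
        dropped_no_reference=dropped_no_ref,
        dropped_above_species=dropped_above,
        total_in=total_in,
        total_out=len(manifest.rows),
        bp_in=bp_in,
        bp_out=bp_out,
    )


def summary_to_dict(summary: CompositionSummary) -> dict:
    return {
        "counts": {
            "retained_unclassified": summary.retained_unclassified,
            "retained_nonbacterial": summary.retained_nonbacterial,
            "simulated": summary.simulated,
            "dropped_no_reference": summary.dropped_no_reference,
            "dropped_above_species": summary.dropped_above_species,
        },
        "fractions_of_output": summary.output_fractions(),
        "total_in": summary.total_in,
        "total_out": summary.total_out,
        "bp_in": summary.bp_in,
        "bp_out": summary.bp_out,
    }
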