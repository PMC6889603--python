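"""Sample-matched paired-end read simulation.

The simulator learns an empirical profile from the original sample — read
lengths, per-cycle Phred score distributions and a fragment-length model —
and then draws the *exact* requested number of read pairs from each
reference genome.  Errors are substitution-only at the Phred-implied rate
(P(error) = 10^(-Q/10)); truth coordinates are encoded in the read name
(``gs|<accession>|<contig>|<start>|<end>|<serial>``, 0-based half-open), so
every simulated base can be traced back to its source position.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import fragment_id, open_text
from .recipe import GenomeCatalog, Recipe

MAX_PHRED = 41
DEFAULT_FRAGMENT_MEAN = 350.0
DEFAULT_FRAGMENT_SD = 35.0
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_TABLE[_a] = _b


class SimulationError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ErrorProfile:
    """Empirical read-length / quality / fragment model of a sample.

    ``qual_counts_r1[i, q]`` counts how often Phred score *q* was observed at
    cycle *i* of mate 1; sampling a simulated quality string draws each cycle
    independently from these histograms.
    """

    read_length_r1: int
    read_length_r2: int
    qual_counts_r1: np.ndarray  # (read_length_r1, MAX_PHRED+1) int64
    qual_counts_r2: np.ndarray
    fragment_mean: float = DEFAULT_FRAGMENT_MEAN
    fragment_sd: float = DEFAULT_FRAGMENT_SD
    error_free: bool = False

    def __post_init__(self) -> None:
        if self.read_length_r1 <= 0 or self.read_length_r2 <= 0:
            raise SimulationError("read lengths must be positive")
        if self.fragment_mean < max(self.read_length_r1, self.read_length_r2):
            raise SimulationError("fragment_mean must be >= the read length")
        self._cdf_r1 = _normalized_cdf(self.qual_counts_r1)
        self._cdf_r2 = _normalized_cdf(self.qual_counts_r2)

    @classmethod
    def uniform(
        cls,
        read_length: int,
        phred: int = 30,
        fragment_mean: float = DEFAULT_FRAGMENT_MEAN,
        fragment_sd: float = DEFAULT_FRAGMENT_SD,
        error_free: bool = False,
    ) -> "ErrorProfile":
        """Point-mass profile: every cycle of both mates at one Phred score."""
        counts = np.zeros((read_length, MAX_PHRED + 1), dtype=np.int64)
        counts[:, min(phred, MAX_PHRED)] = 1
        return cls(read_length, read_length, counts, counts.copy(),
                   fragment_mean, fragment_sd, error_free)


def _normalized_cdf(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise SimulationError("every cycle quality distribution must have observations")
    return np.cumsum(counts / totals, axis=1)


def _sample_quals(cdf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(cdf.shape[0])
    return (cdf < u[:, None]).sum(axis=1).astype(np.int64)


def learn_error_profile(
    r1: Iterable[str] | str,
    r2: Iterable[str] | str,
    fragment_mean: float | None = None,
    fragment_sd: float | None = None,
) -> ErrorProfile:
    """Learn read lengths and per-cycle quality histograms from a FASTQ pair.

    The target read length per mate is the modal *full* length observed in
    the sample (quality trimming leaves a tail of shorter reads which are not
    representative of the machine output); quality histograms accumulate over
    the first ``read_length`` cycles of every read at least that long.
    Fragment parameters default to a typical Illumina library unless given
    or estimated separately (:func:`estimate_fragment_length`).
    """
    lengths: list[tuple[int, int]] = []
    quals: list[tuple[str, str]] = []
    stream1 = open_text(r1) if isinstance(r1, str) else r1
    stream2 = open_text(r2) if isinstance(r2, str) else r2
    for (id1, _s1, q1), (id2, _s2, q2) in zip(
        FastqGeneralIterator(stream1), FastqGeneralIterator(stream2), strict=True
    ):
        if fragment_id(id1) != fragment_id(id2):
            raise SimulationError(f"desynchronized FASTQ pair: {id1!r} vs {id2!r}")
        lengths.append((len(q1), len(q2)))
        quals.append((q1, q2))
    if not lengths:
        raise SimulationError("empty FASTQ input")

    def modal(values: list[int]) -> int:
        counts: dict[int, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        # ties broken toward the longer length (the untrimmed machine length)
        return max(counts, key=lambda v: (counts[v], v))

    len1 = modal([a for a, _ in lengths])
    len2 = modal([b for _, b in lengths])
    counts1 = np.zeros((len1, MAX_PHRED + 1), dtype=np.int64)
    counts2 = np.zeros((len2, MAX_PHRED + 1), dtype=np.int64)
    for q1, q2 in quals:
        if len(q1) >= len1:
            _accumulate(counts1, q1, len1)
        if len(q2) >= len2:
            _accumulate(counts2, q2, len2)
    return ErrorProfile(
        len1,
        len2,
        counts1,
        counts2,
        DEFAULT_FRAGMENT_MEAN if fragment_mean is None else fragment_mean,
        DEFAULT_FRAGMENT_SD if fragment_sd is None else fragment_sd,
    )


def _accumulate(counts: np.ndarray, qual: str, length: int) -> None:
    phred = np.frombuffer(qual[:length].encode(), dtype=np.uint8).astype(np.int64) - 33
    np.clip(phred, 0, MAX_PHRED, out=phred)
    np.add.at(counts, (np.arange(length), phred), 1)


def estimate_fragment_length(alignments) -> tuple[float, float]:
    """Mean/SD of absolute template lengths of proper pairs in a SAM stream.

    Template lengths are trimmed at the 1st/99th percentile before computing
    moments so that chimeric pairs do not distort the estimate.  Accepts an
    iterable of :class:`pysam.AlignedSegment` or a SAM path.
    """
    if isinstance(alignments, str):
        import pysam

        with pysam.AlignmentFile(alignments, "r") as handle:
            return estimate_fragment_length(list(handle))
    tlens = [
        abs(rec.template_length)
        for rec in alignments
        if rec.is_proper_pair and rec.template_length > 0
    ]
    if not tlens:
        raise SimulationError("no proper pairs with positive template length")
    arr = np.asarray(tlens, dtype=np.float64)
    lo, hi = np.percentile(arr, [1, 99])
    arr = arr[(arr >= lo) & (arr <= hi)]
    return float(arr.mean()), float(arr.std())


@dataclass(frozen=True)
class SimulatedPair:
    pair_id: str  # gs|<accession>|<contig>|<start>|<end>|<serial>
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str


def _contig_arrays(contigs: Sequence[tuple[str, str]], min_len: int):
    """Uppercase byte arrays plus length-proportional sampling weights."""
    arrays = [(name, np.frombuffer(seq.upper().encode(), dtype=np.uint8)) for name, seq in contigs]
    usable = [(name, arr) for name, arr in arrays if len(arr) >= min_len]
    if not usable:
        raise SimulationError(f"no contig reaches the read length ({min_len} bp)")
    weights = np.array([len(arr) for _n, arr in usable], dtype=np.float64)
    return usable, weights / weights.sum()


def simulate_read_pairs(
    genome: str | Sequence[tuple[str, str]],
    accession: str,
    n_pairs: int,
    profile: ErrorProfile,
    seed: int,
) -> Iterator[SimulatedPair]:
    """Draw exactly *n_pairs* pairs from a (possibly multi-contig) genome.

    Fragment starts are uniform over valid linear positions; fragment lengths
    are Normal(fragment_mean, fragment_sd) rounded and clamped to
    [read length, contig length].  R1 is the forward 5' prefix of the
    fragment, R2 the reverse complement of its 3' suffix.  Fragments with
    more than 10% N are rejected and redrawn (at most 100 attempts); retained
    N bases pass through with quality 2 and are never substituted.
    """
    if n_pairs < 0:
        raise SimulationError("n_pairs must be >= 0")
    if isinstance(genome, str):
        genome = [(accession, genome)]
    min_len = max(profile.read_length_r1, profile.read_length_r2)
    contigs, weights = _contig_arrays(genome, min_len)
    rng = np.random.default_rng(seed)

    for serial in range(n_pairs):
        for _attempt in range(100):
            ci = int(rng.choice(len(contigs), p=weights))
            name, arr = contigs[ci]
            frag_len = int(round(rng.normal(profile.fragment_mean, profile.fragment_sd)))
            frag_len = max(min_len, min(frag_len, len(arr)))
            start = int(rng.integers(0, len(arr) - frag_len + 1))
            fragment = arr[start : start + frag_len]
            if (fragment == ord("N")).mean() <= 0.10:
                break
        else:
            raise SimulationError(
                f"{accession}/{name}: could not draw a fragment with <= 10% N in 100 attempts"
            )
        r1_template = fragment[: profile.read_length_r1]
        # R2 is sequenced from the fragment 3' end: reverse-complement first so
        # cycle 0 of the read aligns with cycle 0 of the learned profile.
        r2_template = _COMP_TABLE[fragment[frag_len - profile.read_length_r2 :]][::-1]
        r1_seq, r1_qual = _apply_errors(r1_template, profile._cdf_r1, profile.error_free, rng)
        r2_seq, r2_qual = _apply_errors(r2_template, profile._cdf_r2, profile.error_free, rng)
        yield SimulatedPair(
            pair_id=f"gs|{accession}|{name}|{start}|{start + frag_len}|{serial}",
            r1_seq=r1_seq,
            r2_seq=r2_seq,
            r1_qual=r1_qual,
            r2_qual=r2_qual,
        )


def _apply_errors(
    template: np.ndarray, cdf: np.ndarray, error_free: bool, rng: np.random.Generator
) -> tuple[str, str]:
    seq = template.copy()
    n_mask = seq == ord("N")
    quals = _sample_quals(cdf, rng)
    quals[n_mask] = 2
    if not error_free:
        p_err = np.power(10.0, -quals / 10.0)
        hit = (rng.random(len(seq)) < p_err) & ~n_mask
        if hit.any():
            idx = np.nonzero(hit)[0]
            # substitute with a uniformly chosen different base
            current = seq[idx]
            offsets = rng.integers(1, 4, size=len(idx))
            base_idx = np.searchsorted(_BASES, current)
            seq[idx] = _BASES[(base_idx + offsets) % 4]
    qual_str = (quals + 33).astype(np.uint8).tobytes().decode("ascii")
    return seq.tobytes().decode("ascii"), qual_str


def profile_to_json(profile: ErrorProfile) -> str:
    import json

    return json.dumps(
        {
            "read_length_r1": profile.read_length_r1,
            "read_length_r2": profile.read_length_r2,
            "qual_counts_r1": profile.qual_counts_r1.tolist(),
            "qual_counts_r2": profile.qual_counts_r2.tolist(),
            "fragment_mean": profile.fragment_mean,
            "fragment_sd": profile.fragment_sd,
            "error_free": profile.error_free,
        }
    )


def profile_from_json(text: str) -> ErrorProfile:
    import json

    data = json.loads(text)
    return ErrorProfile(
        read_length_r1=data["read_length_r1"],
        read_length_r2=data["read_length_r2"],
        qual_counts_r1=np.asarray(data["qual_counts_r1"], dtype=np.int64),
        qual_counts_r2=np.asarray(data["qual_counts_r2"], dtype=np.int64),
        fragment_mean=data["fragment_mean"],
        fragment_sd=data["fragment_sd"],
        error_free=data["error_free"],
    )


def item_seed(seed: int, accession: str, taxid: int) -> int:
    """Stable per-recipe-item seed below 2^31 derived from the run seed."""
    digest = hashlib.blake2b(f"{seed}|{accession}|{taxid}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    accession: str
    contig: str
    start: int
    end: int
    strand: str  # "+" for R1, "-" for R2


def load_fasta_contigs(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with open_text(path) as handle:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def execute_recipe(
    recipe: Recipe,
    catalog: GenomeCatalog,
    profile: ErrorProfile,
    seed: int,
    r1_out: IO[str],
    r2_out: IO[str],
    truth_out: IO[str] | None = None,
) -> list[TruthRow]:
    """Simulate every recipe item, writing a synchronized FASTQ pair.

    Items are processed in recipe order; each gets an independent RNG seeded
    from ``(seed, accession, taxid)`` so the output is reproducible and
    insensitive to how other items change.  One truth row is written per
    read.  All FASTA paths are checked before any output is produced.
    """
    paths: dict[str, str] = {}
    for item in recipe.items:
        entry = next((e for e in catalog.entries if e.accession == item.accession), None)
        if entry is None:
            raise SimulationError(f"recipe accession {item.accession!r} not in catalog")
        paths[item.accession] = entry.fasta_path
    import os

    missing = [p for p in paths.values() if not os.path.exists(p)]
    if missing:
        raise SimulationError(f"missing reference FASTA file(s): {missing}")

    if truth_out is not None:
        truth_out.write("read_id\taccession\tcontig\tstart\tend\tstrand\n")
    rows: list[TruthRow] = []
    for item in recipe.items:
        contigs = load_fasta_contigs(paths[item.accession])
        pairs = simulate_read_pairs(
            contigs, item.accession, item.n_pairs, profile,
            item_seed(seed, item.accession, item.taxid_classified),
        )
        for pair in pairs:
            r1_out.write(f"@{pair.pair_id}/1\n{pair.r1_seq}\n+\n{pair.r1_qual}\n")
            r2_out.write(f"@{pair.pair_id}/2\n{pair.r2_seq}\n+\n{pair.r2_qual}\n")
            _acc, contig, start, end, _serial = pair.pair_id.split("|")[1:]
            for mate, strand in (("1", "+"), ("2", "-")):
                row = TruthRow(f"{pair.pair_id}/{mate}", item.accession, contig, int(start), int(end), strand)
                rows.append(row)
                if truth_out is not None:
                    truth_out.write(
                        f"{row.read_id}\t{row.accession}\t{row.contig}\t{row.start}\t{row.end}\t{row.strand}\n"
                    )
    return rows
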