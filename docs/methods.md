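# Methods

## The targeted gold-standard construction

Benchmarking assembly and binning tools on environmental shotgun samples is
hard because the true composition of such samples is unknown, and fully
synthetic communities discard the property that makes these samples hard:
a large fraction of reads (often a quarter to a half in urban metagenomes)
matches nothing in any reference database. `metagold` builds *targeted*
in silico gold standards that keep that unknown background real. Given a
quality-controlled paired-end sample and a per-read taxonomic classification
of it, the construction:

1. collapses multi-match classifications to the lowest common ancestor
   (LCA) of their taxa and rolls the result up into a Kraken-style report;
2. partitions the sample's fragments four ways: bacterial at species or
   strain level, bacterial above species level, classified non-bacterial,
   and unclassified;
3. matches each species/strain-level taxon to a reference genome in a
   catalog and records the *exact* classified read count for it (the
   recipe). Bacterial reads classified only above species level, and reads
   of taxa with no catalog genome, are dropped and counted;
4. simulates exactly the recipe's read-pair counts from the reference
   genomes, using an error/length profile learned from the original sample;
5. splices: every unclassified and non-bacterial fragment of the original
   sample is copied through byte-identically, every bacterial-classified
   fragment is removed, and the simulated pairs are appended. A per-read
   truth manifest and a composition summary accompany the output.

The result is a sample whose bacterial fraction has known truth (source
genome and coordinates encoded in each read name) while retaining the
original sample's unclassified complexity. Expected per-genome coverage is
`n_reads x read_length / genome_length`; the fraction of classified
bacterial reads that reach a reference genome is the main fidelity
statistic of a build.

## Classification semantics

The classification unit is the sequenced fragment: paired-end classifiers
score both mates jointly, so read ids are matched with `/1`/`/2` suffixes
stripped and each fragment contributes `reads_per_fragment` (default 2)
reads to recipe counts. Multi-match reads collapse to the LCA of their
distinct classified taxa; unclassified (taxid 0) matches are ignored when
any classified match exists. "Species or strain level" means the node
itself is ranked `species` or has a species-ranked ancestor, so `no rank`
strain nodes below a species count as species-level. Reference lookup
order: exact taxid, then any catalog strain of that species, then the same
two lookups keyed by the species ancestor; ties among strains go to a
`representative`-flagged entry, else the lexicographically smallest
accession (determinism is required for reproducible benchmarks).

## The read simulator

The simulator is substitution-only: each base errs with the Phred-implied
probability 10^(−Q/10), with Q drawn per cycle from the quality histograms
learned from the original sample. Indels, chimeras and PCR duplicates are
not modelled — substitutions dominate Illumina error, and keeping reads
colinear with their source makes the truth coordinates exact. Read length
is the modal full length per mate, on the reasoning that quality trimming
leaves a tail of shortened reads that do not represent machine output; all
simulated reads run at full length. Fragment lengths are
Normal(mean, sd) rounded and clamped to [read length, contig length], with
defaults 350 ± 35 bp (a typical Illumina library) when no estimate is
available; an optional SAM-based estimator takes the trimmed (1st–99th
percentile) mean/SD of proper-pair template lengths. Multi-contig
references are sampled per contig proportional to length; contigs shorter
than the read length are excluded. Fragments with more than 10% N are
redrawn (at most 100 times); retained Ns pass through at quality 2 and are
never substituted. Qualities are Phred+33, capped at 41.

Each recipe item gets an independent RNG seeded from a hash of
`(run seed, accession, taxid)`, so outputs are byte-reproducible and one
item's count change does not perturb another item's reads.

## Bin evaluation

MIMAG tiers follow the printed gates exactly: HIGH needs completeness
strictly above 90%, contamination strictly below 5%, at least one each of
5S/16S/23S rRNA and at least 18 tRNAs (distinct isotypes, pseudo-tRNAs
excluded); MEDIUM needs completeness ≥ 50% and contamination < 10%; LOW
covers completeness < 50% with contamination < 10%. Contamination at or
above 10% fits no tier row and is graded FAILED. Consensus phylotyping
discards marker assignments with confidence ≤ 0.8 (strict), assigns None
when surviving superkingdom calls mix Bacteria and Archaea, and otherwise
returns the deepest rank at which every marker has a surviving assignment
and all agree; a marker lacking any surviving assignment at a rank vetoes
that rank but not others. iRep eligibility is coverage ≥ 5x, < 175
fragments/Mbp, contamination < 2% and completeness > 75%; an iRep value v
is read as a replicating fraction v − 1. Assembly statistics filter
contigs below 500 bp; N50 is the smallest length L such that contigs ≥ L
cover half the filtered total.

## The synthetic-data generator

`metagold.fixtures` emulates a quality-controlled urban sample: bacterial
fragments drawn error-free from generated genomes (specified GC, length),
host fragments from a human-stand-in genome, and an unknown fraction of
uniform random DNA. The classification table assigns bacterial fragments
their true taxid — except a configurable fraction sent to the parent genus
(exercising the above-species drop) — host fragments to the host taxid and
unknown fragments to taxid 0; taxa can be flagged absent from the catalog
(exercising the no-reference drop). The default community mirrors a
high-bacterial urban sample: ~74% bacterial, ~24% unknown, ~2% host
fragments, read length 101 bp, with a log-spread of species abundances.
All outputs derive from one seed and are byte-reproducible.

What the generator does *not* emulate: real per-cycle quality decay
(fixture reads are Q40 flat; the learned-profile machinery is exercised
separately with constructed profiles), sequence homology between the
unknown fraction and the bacterial genomes, strain mixtures within one
species, and classifier errors other than the genus perturbation.
Passing tests therefore demonstrate the bookkeeping, determinism and
statistical contracts of the construction, not classifier accuracy on
real data.

## Numerical and design choices

- Percentages in reports print with two decimals; kreport children sort by
  descending clade count then ascending taxid, making output byte-stable.
- `n_pairs = ceil(n_reads / 2)`, so an odd classified read count overshoots
  by at most one read per taxon — matching the slight bp increase a full
  build shows over its source.
- Problem sizes in the test-suite and acceptance script are chosen so a
  full run takes well under a minute on one CPU: fixture samples of
  ~0.5–2k fragments, 100 random community specs for the conservation
  suite, 100,000 simulated bases for the error-rate check and 1,000 pairs
  on a 200 kb genome for the coverage identity. These sizes leave the
  binomial and chi-square checks well-powered at the stated tolerances.
- Degenerate inputs are first-class: empty catalogs drop everything (not
  an error), a sample with zero bacterial reads reports assigned fraction
  0 with a warning flag, and an assembly with no contig above the filter
  reports zeros with a warning flag.

## Known limitations

- The taxonomy loader reads only the minimal nodes/names dialect; merged
  or deleted taxids are not resolved, so the dump must match the
  classification output's taxid space.
- The simulator's per-cycle histograms are learned marginally; covariance
  between cycles (error bursts) is not modelled.
- Only one classification table drives a build; workflows that combine
  indexes (e.g. one for extraction, one for unknown-content estimation)
  must choose which table defines the bacterial fraction.
- The splice step appends simulated reads after retained reads rather than
  interleaving; downstream assemblers are order-insensitive, and the read
  order can be shuffled externally when order sensitivity matters.
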