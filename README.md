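# metagold

Targeted in silico gold standards for shotgun metagenomes, plus a
genome-draft bin evaluation layer.

## The problem

Urban and other environmental metagenomes carry a large fraction of reads
that match nothing in reference databases, so the true composition of a
sample is unknowable and fully synthetic benchmark communities are too
easy: they lack the unknown background that makes real assembly and
binning hard. `metagold` builds *sample-specific* benchmarks instead. It
takes a real paired-end sample together with a per-read taxonomic
classification of it, removes every read classified as bacterial, and
replaces them with reads simulated from reference genomes at the **exact
classified counts** — with read lengths, per-cycle quality profiles and
fragment lengths matched to the original sample. Unclassified and
non-bacterial reads pass through byte-identically. The result is a sample
whose bacterial fraction has fully known truth (source genome and
coordinates are encoded in every simulated read name) while the hard,
unknown fraction stays real.

Per reference genome the expected depth is

    coverage = n_reads · read_length / genome_length

and the headline fidelity statistic of a build is the fraction of
classified bacterial reads that could be assigned to a catalog genome;
reads classified only above species level, or belonging to taxa without a
reference genome, are dropped and counted.

The bin-evaluation layer grades metagenome-assembled genomes into MIMAG
tiers (high: completeness > 90%, contamination < 5%, 5S/16S/23S rRNA
present, ≥ 18 tRNAs), computes lowest-rank consensus phylotypes from
marker-gene assignments (confidence strictly above 0.8; mixed
Bacteria/Archaea → None), applies the iRep replication-rate eligibility
gates (coverage ≥ 5×, < 175 fragments/Mbp, contamination < 2%,
completeness > 75%), and computes assembly statistics (N50, 500 bp
minimum contig length).

## Worked example

Everything is testable without downloads: the `fixtures` subcommand
generates a complete synthetic sample — genomes, catalog, taxonomy dump,
paired FASTQ and a Centrifuge-format classification table — with known
truth, and `splice` runs the whole construction:

```sh
metagold fixtures wex/sample --seed 1 --misclassify-to-genus 0.04
metagold splice \
    --r1 wex/sample/sample_R1.fastq --r2 wex/sample/sample_R2.fastq \
    --classification wex/sample/classification.tsv \
    --nodes wex/sample/nodes.dmp --names wex/sample/names.dmp \
    --catalog wex/sample/catalog.tsv \
    --out-dir wex/gs --seed 7
```

which prints the composition summary of the build:

```json
{
  "bp_in": 404606,
  "bp_out": 391678,
  "counts": {
    "dropped_above_species": 64,
    "dropped_no_reference": 0,
    "retained_nonbacterial": 40,
    "retained_unclassified": 480,
    "simulated": 1419
  },
  "fractions_of_output": {
    "retained_nonbacterial": 0.020629190304280558,
    "retained_unclassified": 0.2475502836513667,
    "simulated": 0.7318205260443528
  },
  "total_in": 2003,
  "total_out": 1939
}
```

Reading this: the synthetic sample held 2,003 fragments, of which 1,483
were classified bacterial. 64 fragments were classified only to genus
level and dropped; the remaining 1,419 were replaced by simulated pairs
(2,003 − 1,483 + 1,419 = 1,939 output fragments). The 480 unclassified and
40 host fragments passed through unchanged. `wex/gs/` now holds the
gold-standard FASTQ pair, a per-read truth manifest
(`manifest.tsv`: origin, source accession and coordinates per fragment)
and the same summary as `composition.json`.

The library surface mirrors the subcommands (`metagold.partition_reads`,
`build_recipe`, `learn_error_profile`, `execute_recipe`,
`build_gold_standard`, `classify_mimag`, `phylotype_consensus`, ...); see
`docs/methods.md` for the model and its assumptions.

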