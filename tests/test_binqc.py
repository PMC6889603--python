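import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metagold import binqc
from metagold.binqc import (
    BinMetrics,
    BinQCError,
    MarkerAssignment,
    MimagTier,
    RankAssignment,
    classify_mimag,
    phylotype_consensus,
)

from .oracles import mimag_tier_name, n50_by_cumsum, phylotype_by_rank_walk


def metrics(completeness, contamination, rrnas=(1, 1, 1), trnas=18, **kw):
    return BinMetrics(
        bin_id="bin",
        completeness=completeness,
        contamination=contamination,
        rrna_counts=dict(zip(("5S", "16S", "23S"), rrnas)),
        trna_count=trnas,
        **kw,
    )


class TestClassifyMimag:
    def test_complete_clean_bin_is_high(self):
        assert classify_mimag(metrics(100, 0.11)) is MimagTier.HIGH

    def test_missing_16s_blocks_high(self):
        assert classify_mimag(metrics(99.56, 0, rrnas=(1, 0, 1), trnas=20)) is MimagTier.MEDIUM

    def test_low_completeness_clean_bin_is_low(self):
        assert classify_mimag(metrics(40, 2)) is MimagTier.LOW

    def test_high_contamination_fails(self):
        assert classify_mimag(metrics(95, 12)) is MimagTier.FAILED

    def test_too_few_trnas_blocks_high(self):
        assert classify_mimag(metrics(95, 1, trnas=17)) is MimagTier.MEDIUM

    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [
            (90.0, 1.0, MimagTier.MEDIUM),  # completeness gate is strict >90
            (50.0, 1.0, MimagTier.MEDIUM),  # medium gate is inclusive >=50
            (95.0, 5.0, MimagTier.MEDIUM),  # contamination gate is strict <5
            (95.0, 10.0, MimagTier.FAILED),  # no tier allows contamination >=10
            (49.99, 9.99, MimagTier.LOW),
        ],
    )
    def test_printed_boundaries(self, completeness, contamination, expected):
        assert classify_mimag(metrics(completeness, contamination)) is expected

    def test_out_of_range_completeness_rejected(self):
        with pytest.raises(BinQCError):
            classify_mimag(metrics(101, 0))
        with pytest.raises(BinQCError):
            classify_mimag(metrics(50, -1))

    def test_grid_against_rule_oracle(self):
        completeness_grid = [0, 25, 49.99, 50, 50.01, 75, 89.99, 90, 90.01, 95, 100]
        contamination_grid = [0, 1.99, 2, 4.99, 5, 5.01, 9.99, 10, 10.01, 30]
        rrna_grid = [(1, 1, 1), (1, 0, 1), (0, 0, 0), (2, 1, 3)]
        trna_grid = [0, 17, 18, 25]
        for comp, cont, rrnas, trnas in itertools.product(
            completeness_grid, contamination_grid, rrna_grid, trna_grid
        ):
            got = classify_mimag(metrics(comp, cont, rrnas=rrnas, trnas=trnas))
            expected = mimag_tier_name(comp, cont, all(r >= 1 for r in rrnas), trnas)
            assert got.name == expected, (comp, cont, rrnas, trnas)

    @settings(max_examples=200, derandomize=True)
    @given(
        comp=st.floats(0, 100),
        cont=st.floats(0, 40),
        delta_comp=st.floats(0, 10),
        delta_cont=st.floats(0, 5),
    )
    def test_monotone_in_completeness_and_contamination(self, comp, cont, delta_comp, delta_cont):
        base = classify_mimag(metrics(comp, cont))
        better_comp = classify_mimag(metrics(min(100, comp + delta_comp), cont))
        better_cont = classify_mimag(metrics(comp, max(0, cont - delta_cont)))
        assert better_comp >= base
        assert better_cont >= base


class TestReferenceBinTable:
    def test_all_27_reference_bins_pass_high_gates(self):
        bins = binqc.load_reference_bin_table()
        assert len(bins) == 27
        for b in bins:
            assert classify_mimag(b) is MimagTier.HIGH, b.bin_id


def marker(marker_id, **rank_conf_taxon):
    """marker('m1', species=('X', 0.95), genus=('G', 0.9))"""
    return MarkerAssignment(
        marker_id,
        [RankAssignment(rank, taxon, conf) for rank, (taxon, conf) in rank_conf_taxon.items()],
    )


class TestPhylotypeConsensus:
    def test_full_agreement_at_species(self):
        markers = [marker(f"m{i}", species=("X", 0.95), genus=("G", 0.99)) for i in range(2)]
        assert phylotype_consensus(markers) == ("species", "X")

    def test_species_disagreement_falls_back_to_genus(self):
        markers = [
            marker("a", species=("X", 0.9), genus=("G", 0.95)),
            marker("b", species=("Y", 0.9), genus=("G", 0.95)),
        ]
        assert phylotype_consensus(markers) == ("genus", "G")

    def test_mixed_domains_give_none(self):
        markers = [
            marker("a", superkingdom=("Bacteria", 0.99)),
            marker("b", superkingdom=("Archaea", 0.9)),
        ]
        assert phylotype_consensus(markers) is None

    def test_threshold_is_strict(self):
        markers = [marker("a", species=("X", 0.8)), marker("b", species=("X", 0.8))]
        assert phylotype_consensus(markers) is None

    def test_marker_without_assignment_at_rank_vetoes_it(self):
        markers = [
            marker("a", species=("X", 0.9), genus=("G", 0.9)),
            marker("b", genus=("G", 0.9)),
        ]
        assert phylotype_consensus(markers) == ("genus", "G")

    def test_empty_marker_list_rejected(self):
        with pytest.raises(BinQCError):
            phylotype_consensus([])

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_inputs_match_rank_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ranks = binqc.RANK_ORDER
        for _ in range(40):
            n_markers = int(rng.integers(1, 5))
            plain, markers = [], []
            for m in range(n_markers):
                assignments = {}
                for rank in ranks:
                    if rng.random() < 0.7:
                        taxon = f"{rank[:2]}{int(rng.integers(0, 2))}"
                        conf = float(rng.choice([0.5, 0.8, 0.85, 0.95]))
                        assignments[rank] = (taxon, conf)
                plain.append(assignments)
                markers.append(
                    MarkerAssignment(
                        f"m{m}",
                        [RankAssignment(r, t, c) for r, (t, c) in assignments.items()],
                    )
                )
            assert phylotype_consensus(markers) == phylotype_by_rank_walk(plain)


class TestIrep:
    @pytest.mark.parametrize(
        "coverage,frags,cont,comp,expected",
        [
            (5.0, 100, 1.0, 80, True),  # coverage boundary is inclusive
            (4.99, 100, 1.0, 80, False),
            (10, 175, 1.0, 80, False),  # fragments/Mbp gate is strict
            (10, 174.9, 1.0, 80, True),
            (10, 100, 2.0, 80, False),  # contamination gate is strict
            (10, 100, 1.0, 75, False),  # completeness gate is strict
            (10, 100, 1.0, 75.01, True),
        ],
    )
    def test_eligibility_gates(self, coverage, frags, cont, comp, expected):
        assert binqc.irep_eligible(coverage, frags, cont, comp) is expected

    def test_interpretation(self):
        assert binqc.interpret_irep(2.0) == 1.0
        assert binqc.interpret_irep(1.0) == 0.0
        assert binqc.interpret_irep(1.34) == pytest.approx(0.34)

    def test_subunit_irep_rejected(self):
        with pytest.raises(BinQCError):
            binqc.interpret_irep(0.9)


class TestAssemblyStats:
    def test_equal_contigs(self):
        stats = binqc.assembly_stats([1000, 1000, 1000])
        assert (stats.n_contigs, stats.total_length, stats.n50) == (3, 3000, 1000)

    def test_skewed_lengths(self):
        stats = binqc.assembly_stats([3000, 1000, 700, 500])
        assert stats.total_length == 5200
        assert stats.n50 == 3000

    def test_filter_removes_short_contigs(self):
        stats = binqc.assembly_stats([499], min_length=500)
        assert stats.empty_after_filter
        assert stats.n_contigs == 0 and stats.n50 == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_n50_matches_cumsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lengths = [int(l) for l in rng.integers(100, 50_000, size=int(rng.integers(1, 60)))]
        stats = binqc.assembly_stats(lengths, min_length=500)
        assert stats.n50 == n50_by_cumsum(lengths, 500)

    def test_accepts_sequences_and_tuples(self):
        assert binqc.assembly_stats(["A" * 600, ("c2", "G" * 900)]).total_length == 1500


CHECKM = (
    "Bin Id\tMarker lineage\tCompleteness\tContamination\tStrain heterogeneity\n"
    "bin1\tk__Bacteria\t99.34\t0.55\t0.0\n"
    "bin2\tk__Bacteria\t45.2\t3.1\t12.5\n"
)

BARRNAP = (
    "##gff-version 3\n"
    "ctg1\tbarrnap:0.9\trRNA\t100\t1600\t0\t+\t.\tName=16S_rRNA;product=16S ribosomal RNA\n"
)

TRNASCAN_HEADER = (
    "Sequence\t\ttRNA\tBounds\tIsotype\tIsotype\tInf\n"
    "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tScore\n"
    "--------\t------\t-----\t----\t----\t-----\t-----\n"
)


class TestParsers:
    def test_checkm_row_values(self):
        table = binqc.parse_checkm_table(io.StringIO(CHECKM))
        assert table["bin1"] == (99.34, 0.55)
        assert table["bin2"] == (45.2, 3.1)

    def test_checkm_missing_column(self):
        with pytest.raises(BinQCError, match="Contamination"):
            binqc.parse_checkm_table(io.StringIO("Bin Id\tCompleteness\nb\t90\n"))

    def test_barrnap_single_16s(self):
        assert binqc.parse_barrnap_gff(io.StringIO(BARRNAP)) == {"5S": 0, "16S": 1, "23S": 0}

    def test_trnascan_distinct_isotypes(self):
        # 20 hits over 18 isotypes -> 18
        isotypes = [f"Iso{i:02d}" for i in range(18)] + ["Iso00", "Iso01"]
        body = "".join(
            f"ctg1\t{i}\t{i * 100}\t{i * 100 + 70}\t{iso}\tAAA\t55.0\n"
            for i, iso in enumerate(isotypes)
        )
        assert binqc.parse_trnascan(io.StringIO(TRNASCAN_HEADER + body)) == 18

    def test_trnascan_pseudo_excluded(self):
        body = (
            "ctg1\t1\t100\t170\tAla\tAAA\t55.0\t\t\tpseudo\n"
            "ctg1\t2\t300\t370\tGly\tGGG\t60.0\n"
        )
        assert binqc.parse_trnascan(io.StringIO(TRNASCAN_HEADER + body)) == 1

    def test_marker_table_round_trip(self):
        text = (
            "marker_id\trank\ttaxon\tconfidence\n"
            "m1\tspecies\tX\t0.95\n"
            "m1\tgenus\tG\t0.99\n"
            "m2\tgenus\tG\t0.9\n"
        )
        markers = binqc.parse_marker_table(io.StringIO(text))
        assert len(markers) == 2
        assert phylotype_consensus(markers) == ("genus", "G")

    def test_merge_bin_metrics(self):
        table = binqc.parse_checkm_table(io.StringIO(CHECKM))
        m = binqc.merge_bin_metrics("bin1", table, {"5S": 1, "16S": 1, "23S": 1}, 19)
        assert classify_mimag(m) is MimagTier.HIGH
        with pytest.raises(BinQCError):
            binqc.merge_bin_metrics("nope", table)
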