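"""Identification pipeline: filters, screens, clustering, accounting."""

import math

import numpy as np
import pytest
from scipy import integrate

from linckit import identify as idn
from linckit.io_formats import AnnotationRecord, TranscriptAlignment

RNG = np.random.default_rng(20240901)

STOPS = {"TAA", "TAG", "TGA"}


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_longest_orf(seq):
    """Independent oracle: scan every codon start in all six frames."""
    best = 0
    for s in (seq, idn.revcomp(seq)):
        for off in range(3):
            codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
            for i in range(len(codons)):
                run = 0
                for j in range(i, len(codons)):
                    if codons[j] in STOPS:
                        break
                    run += 1
                best = max(best, run)
    return best * 3


def make_tu(tu_id, seq, chrom="c1", start=0, blocks=None):
    blocks = blocks or [(start, start + len(seq))]
    aln = TranscriptAlignment(tu_id, chrom, "+", blocks, matched=len(seq), mismatches=0)
    return idn.TranscriptUnit(tu_id, seq, loci=[aln])


class TestMapFilter:
    def test_perfect_full_length_kept_partial_removed(self):
        seqs = {"a": "A" * 300, "b": "C" * 300}
        alns = [
            TranscriptAlignment("a", "c1", "+", [(0, 300)], matched=300, mismatches=0),
            TranscriptAlignment("b", "c1", "+", [(0, 299)], matched=299, mismatches=0),
        ]
        tus = idn.map_filter(alns, seqs, ["c1"])
        assert [t.tu_id for t in tus] == ["a"]

    def test_two_perfect_placements_become_one_tu_with_two_loci(self):
        seqs = {"a": "A" * 250}
        alns = [
            TranscriptAlignment("a", "c1", "+", [(0, 250)], matched=250, mismatches=0),
            TranscriptAlignment("a", "c2", "+", [(50, 300)], matched=250, mismatches=0),
        ]
        (tu,) = idn.map_filter(alns, seqs, ["c1", "c2"])
        assert len(tu.loci) == 2

    def test_unknown_chromosome_is_an_error(self):
        aln = TranscriptAlignment("a", "cX", "+", [(0, 10)], matched=10, mismatches=0)
        with pytest.raises(ValueError, match="unknown chromosome"):
            idn.map_filter([aln], {"a": "A" * 10}, ["c1"])


class TestIntervalOverlap:
    GENE = AnnotationRecord("c1", 200, 400, "+", "gene", "g1")

    def test_one_bp_overlap_removes(self):
        tu = make_tu("a", random_seq(200), start=100)
        assert idn.interval_overlap_filter([tu], [self.GENE], "gene_nat") == []

    @pytest.mark.parametrize(
        "start,end,kept",
        [(950, 1150, False), (900, 990, True)],  # gaps of 350 and 510
    )
    def test_flank500_boundary_arithmetic(self, start, end, kept):
        gene = AnnotationRecord("c1", 1500, 2000, "+", "gene", "g1")
        tu = make_tu("a", random_seq(end - start), start=start)
        out = idn.interval_overlap_filter([tu], [gene], "flank500")
        assert (len(out) == 1) is kept

    def test_mode_selects_feature_class(self):
        rep = AnnotationRecord("c1", 200, 400, "+", "repeat", "r1")
        tu = make_tu("a", random_seq(200), start=300)
        assert idn.interval_overlap_filter([tu], [rep], "gene_nat") == [tu]
        assert idn.interval_overlap_filter([tu], [rep], "repeat") == []

    def test_any_locus_overlap_removes_multi_locus_tu(self):
        seq = random_seq(150)
        tu = make_tu("a", seq, start=5000)
        tu.loci.append(
            TranscriptAlignment("a", "c1", "+", [(250, 400)], matched=150, mismatches=0)
        )
        assert idn.interval_overlap_filter([tu], [self.GENE], "gene_nat") == []


class TestOrfScan:
    def test_poly_a_has_no_stops_and_fails(self):
        longest, ok = idn.orf_scan("A" * 999)
        assert longest >= 300 and not ok

    def test_short_sequence_always_passes(self):
        longest, ok = idn.orf_scan(random_seq(250))
        assert ok or longest < 300  # 250 nt cannot host a 300 nt ORF
        assert idn.orf_scan("A" * 250)[1]

    def test_constructed_stop_dense_sequence_passes(self):
        # stops roughly every 60 nt in the forward frame; verified six-frame
        block = random_seq(57) + "TAA"
        seq = block * 12
        oracle = brute_force_longest_orf(seq)
        longest, ok = idn.orf_scan(seq)
        assert longest == oracle
        assert ok is (oracle < 300)

    def test_n_codons_never_count_as_stops(self):
        # TNA could be TAA/TGA but N-containing codons are not stops
        seq = ("ACG" * 40 + "TNA" + "ACG" * 70)
        longest, _ = idn.orf_scan(seq)
        assert longest >= 333

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            seq = random_seq(int(rng.integers(30, 1000)), rng)
            assert idn.orf_scan(seq)[0] == brute_force_longest_orf(seq)

    def test_require_init_restricts_to_atg_runs(self):
        seq = "CCC" * 30 + "TAA"  # 90 nt stop-free run without ATG
        assert idn.orf_scan(seq, min_len=60, require_init=True)[0] == 0
        with_atg = "ATG" + "CCC" * 30 + "TAA"
        assert idn.orf_scan(with_atg, min_len=60, require_init=True)[0] == 93


class TestLengthFilter:
    @pytest.mark.parametrize("n,kept", [(199, False), (200, True), (2573, True)])
    def test_strict_boundary(self, n, kept):
        tu = make_tu("a", random_seq(n))
        assert (idn.length_filter([tu]) == [tu]) is kept


class TestHomologyScreen:
    def test_shared_block_with_cds_triggers_protein_screen(self):
        rng = np.random.default_rng(8)
        nonstop = [c for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3)) if c not in STOPS]
        cds = "".join(rng.choice(nonstop, size=100))
        protein = idn._translate(cds)
        tu_seq = random_seq(100, rng) + cds[30:81] + random_seq(100, rng)
        tu = make_tu("a", tu_seq)
        hits, kept = idn.homology_screen([tu], [("p1", protein)], "protein")
        assert kept == [] and hits[0].subject_id == "p1"

    def test_random_tu_passes_unrelated_library(self):
        tu = make_tu("a", random_seq(300))
        library = [("x", random_seq(5000))]
        hits, kept = idn.homology_screen([tu], library, "nt_like")
        assert hits == [] and kept == [tu]

    def test_external_hit_table_is_honored_verbatim(self):
        tu = make_tu("a", random_seq(300))
        table = [idn.ScreenHit("a", "subj", "nt_like", True)]
        hits, kept = idn.homology_screen([tu], [("x", tu.seq)], "nt_like", hit_table=table)
        assert kept == [] and hits == table
        # and a non-significant table keeps the TU even though k-mers match
        table2 = [idn.ScreenHit("a", "subj", "nt_like", False)]
        _, kept2 = idn.homology_screen([tu], [("x", tu.seq)], "nt_like", hit_table=table2)
        assert kept2 == [tu]

    def test_empty_library_passes_all_with_warning(self, caplog):
        tu = make_tu("a", random_seq(300))
        with caplog.at_level("WARNING"):
            hits, kept = idn.homology_screen([tu], [], "nt_like")
        assert kept == [tu] and "empty library" in caplog.text


class TestClusterRedundant:
    def test_identical_sequences_collapse(self):
        s = random_seq(400)
        reps = idn.cluster_redundant([make_tu("a", s), make_tu("b", s)])
        assert len(reps) == 1

    def test_constructed_96pct_copy_joins_longest_representative(self):
        rng = np.random.default_rng(3)
        long_seq = random_seq(1000, rng)
        copy = list(long_seq[:900])
        for p in rng.choice(900, size=36, replace=False):  # identity 0.96
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
        reps = idn.cluster_redundant(
            [make_tu("short", "".join(copy)), make_tu("long", long_seq)]
        )
        assert [t.tu_id for t in reps] == ["long"]
        assert idn.pair_identity("".join(copy), long_seq) == pytest.approx(0.96)

    def test_unrelated_sequences_stay_separate(self):
        reps = idn.cluster_redundant(
            [make_tu("a", random_seq(400)), make_tu("b", random_seq(400))]
        )
        assert len(reps) == 2

    def test_no_output_pair_reaches_threshold(self, default_dataset):
        seqs = default_dataset.transcripts.sequences
        tus = [make_tu(t, s) for t, s in sorted(seqs.items())]
        reps = idn.cluster_redundant(tus)
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert idn.pair_identity(a.seq, b.seq) < 0.95


class TestPipeline:
    def test_empty_input_yields_zero_report(self):
        lincs, report, _ = idn.run_identification([], {}, [], ["c1"])
        assert lincs == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.steps)
        assert report.validate_chain()

    def test_report_chains_and_recovers_truth(self, default_dataset):
        ds = default_dataset
        tr = ds.transcripts
        lincs, report, _ = idn.run_identification(
            tr.alignments, tr.sequences, ds.annotation,
            [g.chrom_id for g in ds.genome], libraries=tr.libraries,
        )
        assert report.validate_chain()
        assert {t.tu_id for t in lincs} == {
            t for t, c in tr.truth_labels.items() if c == "lincRNA"
        }

    def test_disabling_screens_shortens_report_chain_intact(self, default_dataset):
        ds = default_dataset
        tr = ds.transcripts
        cfg = idn.IdentifyConfig(screens=())
        _, report, _ = idn.run_identification(
            tr.alignments, tr.sequences, ds.annotation,
            [g.chrom_id for g in ds.genome], config=cfg,
        )
        assert len(report.steps) == 7  # map, 3 overlaps, orf, length, cluster
        assert report.validate_chain()

    def test_overlap_filter_order_invariance(self, default_dataset):
        ds = default_dataset
        tr = ds.transcripts
        tus = idn.map_filter(
            tr.alignments, tr.sequences, [g.chrom_id for g in ds.genome]
        )
        surviving = {}
        for order in (
            ("gene_nat", "repeat", "flank500"),
            ("flank500", "gene_nat", "repeat"),
            ("repeat", "flank500", "gene_nat"),
        ):
            current = tus
            for mode in order:
                current = idn.interval_overlap_filter(current, ds.annotation, mode)
            surviving[order] = {t.tu_id for t in current}
        assert len(set(map(frozenset, surviving.values()))) == 1

    def test_broken_chain_is_rejected(self):
        report = idn.FilterReport()
        report.add("a", 10, 3)
        with pytest.raises(ValueError, match="chain broken"):
            report.add("b", 8, 1)


class TestChromosomeDistribution:
    LENGTHS = {f"c{i}": 1000 for i in range(1, 8)}

    def test_uniform_counts_give_zero_statistic(self):
        counts = {f"c{i}": 10 for i in range(1, 8)}
        stat, p = idn.chromosome_distribution_test(counts, self.LENGTHS, "equal")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_p_matches_numeric_chi_square_integration(self):
        counts = dict(zip(self.LENGTHS, [20, 10, 10, 10, 10, 10, 0]))
        stat, p = idn.chromosome_distribution_test(counts, self.LENGTHS, "equal")
        k = 6  # degrees of freedom

        def chi2_pdf(x):
            return x ** (k / 2 - 1) * math.exp(-x / 2) / (2 ** (k / 2) * math.gamma(k / 2))

        upper_tail, _ = integrate.quad(chi2_pdf, stat, np.inf)
        assert p == pytest.approx(upper_tail, rel=1e-8)

    def test_length_proportional_equals_equal_for_equal_lengths(self):
        counts = dict(zip(self.LENGTHS, [5, 9, 12, 3, 7, 8, 6]))
        s1, p1 = idn.chromosome_distribution_test(counts, self.LENGTHS, "equal")
        s2, p2 = idn.chromosome_distribution_test(
            counts, self.LENGTHS, "length_proportional"
        )
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_expected_count_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            idn.chromosome_distribution_test(
                {"c1": 0, "c2": 0}, {"c1": 100, "c2": 100}, "equal"
            )
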