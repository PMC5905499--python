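"""Assembly statistics: gap cutting, Nx oracle equivalence, termini, report arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapqc.assembly_metrics import (
    assembly_summary,
    classify_termini,
    cut_at_gaps,
    inferred_repeat_pct,
    nx_stats,
    percent,
    ssr_density,
)
from hapqc.io_formats import Category, Interval, Scaffold


def brute_force_n50(lengths):
    """O(n^2) cumulative oracle: largest L such that sequences >= L sum to >= half."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    cum = 0
    for i, l in enumerate(lengths):
        cum += l
        if cum * 2 >= total:
            return l, i + 1
    raise AssertionError("unreachable")


class TestCutAtGaps:
    def test_hand_segmentation(self):
        contigs, gaps = cut_at_gaps(Scaffold("s", "ACGTNNNNACG"), min_run=3)
        assert [c.seq for c in contigs] == ["ACGT", "ACG"]
        assert len(gaps) == 1 and gaps[0].length == 4

    def test_run_shorter_than_min_run_stays(self):
        contigs, gaps = cut_at_gaps(Scaffold("s", "ACGTNNNNACG"), min_run=5)
        assert [c.seq for c in contigs] == ["ACGTNNNNACG"]
        assert gaps == []

    def test_no_ns_identity(self):
        contigs, gaps = cut_at_gaps(Scaffold("s", "ACGTACGT"), min_run=1)
        assert [c.seq for c in contigs] == ["ACGTACGT"] and gaps == []

    def test_all_n_scaffold(self):
        contigs, gaps = cut_at_gaps(Scaffold("s", "NNNNN"), min_run=3)
        assert contigs == [] and len(gaps) == 1

    @settings(max_examples=100, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=200),
        min_run=st.integers(1, 10),
    )
    def test_round_trip_reconstruction(self, seq, min_run):
        scaf = Scaffold("s", seq)
        contigs, gaps = cut_at_gaps(scaf, min_run)
        pieces = sorted(
            [(c.start, c.end, c.seq) for c in contigs]
            + [(g.start, g.end, "N" * g.length) for g in gaps]
        )
        assert "".join(p[2] for p in pieces) == seq
        assert all(len(c.seq) == c.end - c.start for c in contigs)


class TestNxStats:
    def test_hand_example(self):
        assert nx_stats([8, 8, 4, 3, 3, 2, 2, 2]) == (8, 2)

    def test_single_sequence(self):
        assert nx_stats([12345]) == (12345, 1)

    def test_ng50_with_double_genome_size(self):
        lengths = [8, 8, 4, 3, 3, 2, 2, 2]
        n50, _, ng50 = nx_stats(lengths, 50.0, genome_size=2 * sum(lengths))
        assert ng50 <= n50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nx_stats([])

    @settings(max_examples=200, deadline=None)
    @given(lengths=st.lists(st.integers(1, 10**6), min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, lengths):
        assert nx_stats(lengths) == brute_force_n50(lengths)

    @settings(max_examples=50, deadline=None)
    @given(
        lengths=st.lists(st.integers(1, 10**4), min_size=1, max_size=50),
        c=st.integers(2, 10),
    )
    def test_scale_equivariance(self, lengths, c):
        n50, l50 = nx_stats(lengths)
        n50c, l50c = nx_stats([c * l for l in lengths])
        assert (n50c, l50c) == (c * n50, l50)


class TestAssemblySummary:
    def test_hand_counts(self):
        scafs = [Scaffold("s1", "ACGTNNNNACGT"), Scaffold("s2", "GGCC")]
        st_ = assembly_summary(scafs, min_len=1)
        assert st_.total_with_gaps == 16
        assert st_.gap_bp == 4 and st_.gap_count == 1
        assert st_.total_without_gaps == 12
        # GC over non-N bases: (4 + 4) / (8 + 4)
        assert st_.gc_pct == pytest.approx(100 * 8 / 12)
        assert st_.gap_pct == pytest.approx(100 * 4 / 16)

    def test_all_at_assembly_zero_gc(self):
        st_ = assembly_summary([Scaffold("s", "ATAT" * 300)], min_len=1)
        assert st_.gc_pct == 0.0

    def test_min_len_filter(self):
        scafs = [Scaffold("s1", "A" * 1500), Scaffold("s2", "A" * 500)]
        assert assembly_summary(scafs).n_sequences == 1

    def test_empty_after_filter_rejected(self):
        with pytest.raises(ValueError):
            assembly_summary([Scaffold("s", "ACGT")], min_len=1000)

    def test_genome_relative_percentage_convention(self):
        # bases in scaffolds >= 20 kbp over the genome size: 461/557 Mbp -> 83%
        assert percent(461, 557, 0) == 83


class TestClassifyTermini:
    def test_precedence_repeat_over_gene(self):
        contigs, _ = cut_at_gaps(Scaffold("s", "ACGTACGTACGT" * 20), min_run=1)
        ivs = [
            Interval("s", 0, 240, Category.INTERSPERSED_REPEAT),
            Interval("s", 0, 240, Category.GENE),
        ]
        cls = classify_termini(contigs, ivs)
        assert cls.counts["interspersed_repeat"] == cls.n_termini
        assert cls.counts["gene"] == 0

    def test_zero_coverage_outranks_all(self):
        contigs, _ = cut_at_gaps(Scaffold("s", "A" * 1000), min_run=1)
        ivs = [
            Interval("s", 0, 1000, Category.ZERO_COVERAGE),
            Interval("s", 0, 1000, Category.INTERSPERSED_REPEAT),
        ]
        cls = classify_termini(contigs, ivs)
        assert cls.counts["zero_coverage"] == 2

    def test_no_intervals_all_none(self):
        contigs, _ = cut_at_gaps(Scaffold("s", "A" * 100), min_run=1)
        cls = classify_termini(contigs, [])
        assert cls.percentages["none"] == 100.0

    def test_hand_fixture_percentages(self):
        # 5 contigs on 5 scaffolds -> 10 termini: 2 in zero-coverage,
        # 3 in interspersed repeats, 5 uncovered -> 20/30/50%
        scafs = [Scaffold(f"s{i}", "ACGT" * 25) for i in range(5)]
        contigs = [c for s in scafs for c in cut_at_gaps(s, 1)[0]]
        ivs = [
            Interval("s0", 0, 100, Category.ZERO_COVERAGE),  # both termini of s0
            Interval("s1", 0, 50, Category.INTERSPERSED_REPEAT),  # start of s1
            Interval("s2", 0, 100, Category.INTERSPERSED_REPEAT),  # both of s2
        ]
        cls = classify_termini(contigs, ivs)
        assert cls.percentages == {
            "zero_coverage": 20.0,
            "interspersed_repeat": 30.0,
            "tandem_repeat": 0.0,
            "gene": 0.0,
            "none": 50.0,
        }

    def test_invariant_to_interval_order(self):
        contigs, _ = cut_at_gaps(Scaffold("s", "ACGT" * 100), min_run=1)
        ivs = [
            Interval("s", 0, 10, Category.GENE),
            Interval("s", 390, 400, Category.TANDEM_REPEAT),
        ]
        a = classify_termini(contigs, ivs)
        b = classify_termini(contigs, list(reversed(ivs)))
        assert a.counts == b.counts

    def test_terminus_beyond_scaffold_rejected(self):
        from hapqc.assembly_metrics import Contig

        bad = Contig("s", 0, 500, "A" * 500)
        with pytest.raises(ValueError):
            classify_termini([bad], [], scaffold_lengths={"s": 100})

    def test_flank_extends_overlap(self):
        contigs, _ = cut_at_gaps(Scaffold("s", "A" * 100), min_run=1)
        iv = [Interval("s", 10, 20, Category.GENE)]  # misses terminus 0 by 10
        assert classify_termini(contigs, iv).counts["gene"] == 0
        assert classify_termini(contigs, iv, flank=10).counts["gene"] == 1


class TestReportArithmetic:
    def test_percent_rounding_conventions(self):
        assert percent(155_348_349, 503_314_177, 1) == 30.9
        assert percent(26_447_057, 503_308_897, 2) == 5.25

    def test_inferred_repeat_fraction(self):
        assert inferred_repeat_pct(155_348_349, 503_314_177, 557_000_000) == 37.5

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_ssr_density_per_mbp(self):
        assert ssr_density(182_115, 503_000_000) == pytest.approx(362.1, abs=0.1)
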