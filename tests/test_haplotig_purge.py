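"""Haplotig purge: similarity estimation, best-match filtering, redundancy rule."""

import numpy as np
import pytest

from hapqc.haplotig_purge import (
    PurgeConfig,
    all_vs_all,
    estimate_similarity,
    filter_best_matches,
    identify_redundant,
    purge,
    run_purge_pipeline,
)
from hapqc.io_formats import Scaffold, SimilarityMatch
from hapqc.synthetic_data import simulate_diploid, simulate_fragmented_assembly


def _match(q, t, identity=95.0, coverage=90.0, bases=900):
    return SimilarityMatch(q, t, identity, coverage, bases)


def _mutate(seq: str, rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for p in np.flatnonzero(rng.random(len(seq)) < rate):
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestEstimateSimilarity:
    def test_identical_sequences(self):
        g = simulate_diploid(5000, 0.0, seed=60)
        a = Scaffold("a", g.hapA)
        identity, coverage = estimate_similarity(a, Scaffold("b", g.hapA))
        assert identity == 100.0 and coverage == 100.0

    def test_five_percent_divergence(self):
        # survival model: containment ~ 0.95^15 ~ 0.463 -> identity ~ 95
        g = simulate_diploid(5000, 0.0, seed=61)
        a = Scaffold("a", g.hapA)
        b = Scaffold("b", _mutate(g.hapA, 0.05, 62))
        identity, coverage = estimate_similarity(a, b)
        assert 92 <= identity <= 98
        assert coverage > 80

    def test_unrelated_sequences_floor_to_zero(self):
        a = Scaffold("a", simulate_diploid(5000, 0.0, seed=63).hapA)
        b = Scaffold("b", simulate_diploid(5000, 0.0, seed=64).hapA)
        identity, coverage = estimate_similarity(a, b)
        assert identity == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            estimate_similarity(Scaffold("a", "ACGT" * 10), Scaffold("b", "ACGT" * 100))


class TestFilterBestMatches:
    def test_identity_boundary_inclusive(self):
        kept = filter_best_matches([_match("q", "t", identity=92.0)])
        dropped = filter_best_matches([_match("q", "t", identity=91.9)])
        assert len(kept) == 1 and dropped == []

    def test_coverage_boundary_inclusive(self):
        kept = filter_best_matches([_match("q", "t", coverage=80.0)])
        dropped = filter_best_matches([_match("q", "t", coverage=79.9)])
        assert len(kept) == 1 and dropped == []

    def test_self_hits_dropped(self):
        assert filter_best_matches([_match("q", "q")]) == []

    def test_ties_for_best_match_bases_all_kept(self):
        ms = [
            _match("q", "t1", bases=900),
            _match("q", "t2", bases=900),
            _match("q", "t3", bases=500),
        ]
        kept = filter_best_matches(ms)
        assert {m.target_id for m in kept} == {"t1", "t2"}


class TestIdentifyRedundant:
    def test_exactly_one_partner_haploid(self):
        pairs = identify_redundant(
            [_match("S", "P")], {"S": "haploid", "P": "diploid"}
        )
        assert pairs == [("P", "S")]

    def test_two_partners_excluded(self):
        ms = [_match("S", "P"), _match("S", "Q")]
        assert identify_redundant(ms, {"S": "haploid"}) == []

    def test_diploid_candidate_excluded(self):
        assert identify_redundant([_match("S", "P")], {"S": "diploid"}) == []

    def test_ambiguous_candidate_excluded(self):
        assert identify_redundant([_match("S", "P")], {"S": "ambiguous"}) == []

    def test_missing_depth_class_raises(self):
        with pytest.raises(ValueError, match="S"):
            identify_redundant([_match("S", "P")], {})

    def test_pair_emitted_once_for_reciprocal_hits(self):
        ms = [_match("S", "P"), _match("P", "S")]
        pairs = identify_redundant(ms, {"S": "haploid", "P": "haploid"})
        assert pairs == [("P", "S")]


class TestPurge:
    def _scafs(self, spec):
        return [Scaffold(name, "ACGT" * (n // 4)) for name, n in spec.items()]

    def test_shorter_member_removed(self):
        scafs = self._scafs({"A": 5000, "B": 4800})
        retained, rep = purge([("A", "B")], scafs)
        assert {s.id for s in retained} == {"A"}
        assert rep.removed[0][:2] == ("B", "A")

    def test_equal_length_lexicographic_tiebreak(self):
        scafs = self._scafs({"s1": 1000, "s2": 1000})
        retained, _ = purge([("s1", "s2")], scafs)
        assert {s.id for s in retained} == {"s1"}

    def test_chain_single_removal_per_surviving_pair(self):
        # A(6000)-B(5000), B(5000)-C(4800): B removed by the first pair, so the
        # second pair no longer triggers; C survives
        scafs = self._scafs({"A": 6000, "B": 5000, "C": 4800})
        retained, rep = purge([("A", "B"), ("B", "C")], scafs)
        assert {s.id for s in retained} == {"A", "C"}
        assert len(rep.removed) == 1

    def test_unknown_id_raises(self):
        with pytest.raises(ValueError, match="X"):
            purge([("A", "X")], self._scafs({"A": 1000}))

    def test_report_accounting(self):
        scafs = self._scafs({"A": 5000, "B": 4800, "C": 3000})
        retained, rep = purge([("A", "B")], scafs)
        assert set(rep.removed_ids) | set(rep.retained_ids) == {"A", "B", "C"}
        assert not set(rep.removed_ids) & set(rep.retained_ids)
        assert rep.n_input == 3 and rep.n_output == 2


@pytest.fixture(scope="module")
def truth_assembly():
    genome = simulate_diploid(600_000, 0.03, seed=70)
    return simulate_fragmented_assembly(
        genome, segment_len=10_000, divergence_threshold=0.03,
        lambda_hom=60.0, seed=71,
    )


class TestPipeline:
    def test_homozygous_assembly_zero_removals(self):
        genome = simulate_diploid(100_000, 0.0, seed=72)
        asm = simulate_fragmented_assembly(genome, segment_len=10_000, seed=73)
        retained, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        assert rep.removed == []
        assert len(retained) == len(asm.scaffolds)

    def test_truth_recovery_precision_recall(self, truth_assembly):
        asm = truth_assembly
        retained, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        truth = {frozenset(p) for p in asm.truth_pairs}
        tp = sum(
            1 for rem, kept, *_ in rep.removed if frozenset((rem, kept)) in truth
        )
        assert tp / len(rep.removed) >= 0.9  # precision
        assert tp / len(truth) >= 0.9  # recall

    def test_no_diploid_class_scaffold_removed(self, truth_assembly):
        asm = truth_assembly
        _, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        assert all(dclass != "diploid" for *_, dclass in rep.removed)

    def test_base_accounting_exact(self, truth_assembly):
        asm = truth_assembly
        by_id = {s.id: len(s) for s in asm.scaffolds}
        retained, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        removed_bp = sum(by_id[r] for r in rep.removed_ids)
        assert sum(len(s) for s in retained) == sum(by_id.values()) - removed_bp

    def test_idempotence(self, truth_assembly):
        asm = truth_assembly
        retained, _ = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        depths = {s.id: asm.depth_table[s.id] for s in retained}
        _, rep2 = run_purge_pipeline(retained, depths)
        assert rep2.removed == []

    def test_haploid_fraction_decreases(self, truth_assembly):
        # purging removes haploid-depth scaffolds, pushing the depth histogram
        # toward the single diploid mode
        asm = truth_assembly
        retained, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        lam = 60.0
        before = np.mean([asm.depth_table[s.id] < 0.75 * lam for s in asm.scaffolds])
        after = np.mean([asm.depth_table[s.id] < 0.75 * lam for s in retained])
        assert after < before

    def test_psl_path_equivalent_to_internal(self, truth_assembly):
        # feeding the internal estimates through the PSL-style match interface
        # produces the same removals as the integrated path
        asm = truth_assembly
        matches = all_vs_all(asm.scaffolds)
        _, rep_direct = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        _, rep_psl = run_purge_pipeline(
            asm.scaffolds, asm.depth_table, psl_matches=matches
        )
        assert rep_direct.removed_ids == rep_psl.removed_ids

    def test_high_divergence_recall_collapses(self):
        # beyond ~8% divergence the 92% identity floor hides haplotig pairs
        genome = simulate_diploid(200_000, 0.12, seed=74)
        asm = simulate_fragmented_assembly(
            genome, segment_len=10_000, divergence_threshold=0.0,
            lambda_hom=60.0, seed=75,
        )
        assert len(asm.truth_pairs) > 0
        _, rep = run_purge_pipeline(asm.scaffolds, asm.depth_table)
        assert len(rep.removed) / len(asm.truth_pairs) < 0.1


class TestConfig:
    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            PurgeConfig(min_identity_pct=0)
        with pytest.raises(ValueError):
            PurgeConfig(min_coverage_pct=101)
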