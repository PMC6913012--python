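from __future__ import annotations

import numpy as np
import pytest

from asmdiff.alignio import Annotation, revcomp
from asmdiff.simrearrange import (
    SimConfig,
    TruthRecord,
    evaluate_indels,
    evaluate_predictions,
    indel_config,
    random_genome,
    simulate_rearrangements,
    truth_alignments,
)


class TestRandomGenome:
    def test_seed_reproducibility(self):
        assert random_genome(2, 10_000, 0.4, seed=5) == random_genome(2, 10_000, 0.4, seed=5)

    def test_different_seeds_differ(self):
        assert random_genome(1, 10_000, 0.4, seed=1) != random_genome(1, 10_000, 0.4, seed=2)

    def test_gc_content_is_controlled(self):
        (seq,) = random_genome(1, 1_000_000, 0.5, seed=3).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52


class TestSimulation:
    def test_inversion_conserves_length_and_sequence(self):
        g = random_genome(1, 50_000, 0.4, seed=9)
        cfg = SimConfig(n_inversions=1, n_transpositions=0, n_translocations=0,
                        n_tandem_dups=0, n_distal_dups=0)
        mut, truth = simulate_rearrangements(g, cfg, seed=10)
        (t,) = truth
        assert t.kind == "INV"
        assert len(mut["chr1"]) == len(g["chr1"])
        src = g["chr1"][t.ref_start - 1 : t.ref_end]
        dst = mut["chr1"][t.qry_start - 1 : t.qry_end]
        assert dst == revcomp(src)

    def test_tandem_duplication_extends_genome_by_its_size(self):
        g = random_genome(1, 50_000, 0.4, seed=9)
        cfg = SimConfig(n_inversions=0, n_transpositions=0, n_translocations=0,
                        n_tandem_dups=1, n_distal_dups=0, tandem_dup_size=(500, 500))
        mut, truth = simulate_rearrangements(g, cfg, seed=10)
        assert len(mut["chr1"]) == len(g["chr1"]) + 500
        (t,) = truth
        assert mut["chr1"][t.qry_start - 1 : t.qry_end] == g["chr1"][t.ref_start - 1 : t.ref_end]

    def test_length_bookkeeping_over_all_events(self, mixed_sim):
        """Mutated length = original + insertions + duplications - deletions."""
        truth = mixed_sim["truth"]
        delta = sum(
            t.size if t.kind in ("INS", "TANDEM_DUP", "DISTAL_DUP")
            else -t.size if t.kind == "DEL" else 0
            for t in truth
        )
        orig = sum(len(s) for s in mixed_sim["genome"].values())
        mut = sum(len(s) for s in mixed_sim["mutated"].values())
        assert mut == orig + delta

    def test_seed_reproducibility_byte_for_byte(self):
        g = random_genome(2, 30_000, 0.4, seed=1)
        cfg = SimConfig(n_inversions=2, n_transpositions=2, n_translocations=1,
                        n_tandem_dups=1, n_distal_dups=1,
                        inversion_size=(200, 500), transposition_size=(200, 500),
                        translocation_size=(200, 500), distal_dup_size=(200, 500))
        m1, t1 = simulate_rearrangements(g, cfg, seed=2)
        m2, t2 = simulate_rearrangements(g, cfg, seed=2)
        assert m1 == m2 and t1 == t2

    def test_source_intervals_never_overlap(self, mixed_sim):
        by_chr: dict[str, list] = {}
        for t in mixed_sim["truth"]:
            if t.kind != "INS":
                by_chr.setdefault(t.ref_chr, []).append((t.ref_start, t.ref_end))
        for spans in by_chr.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestTruthAlignments:
    def test_no_events_gives_one_full_length_alignment_per_chromosome(self):
        g = random_genome(2, 20_000, 0.4, seed=4)
        cfg = SimConfig(n_inversions=0, n_transpositions=0, n_translocations=0,
                        n_tandem_dups=0, n_distal_dups=0)
        mut, truth = simulate_rearrangements(g, cfg, seed=5)
        alns = truth_alignments(truth, g, mut)
        assert len(alns) == 2
        assert all(a.ref_len == 20_000 and a.strand == "+" for a in alns)

    def test_single_inversion_gives_three_alignments_with_mirrored_middle(self):
        g = random_genome(1, 50_000, 0.4, seed=9)
        cfg = SimConfig(n_inversions=1, n_transpositions=0, n_translocations=0,
                        n_tandem_dups=0, n_distal_dups=0)
        mut, truth = simulate_rearrangements(g, cfg, seed=10)
        alns = truth_alignments(truth, g, mut)
        assert len(alns) == 3
        (t,) = truth
        (mid,) = [a for a in alns if a.strand == "-"]
        assert (mid.ref_start, mid.ref_end) == (t.ref_start, t.ref_end)
        assert (mid.qry_start, mid.qry_end) == (t.qry_start, t.qry_end)

    def test_alignments_are_sequence_exact(self, mixed_sim):
        g, mut = mixed_sim["genome"], mixed_sim["mutated"]
        for a in mixed_sim["alignments"]:
            r = g[a.ref_chr][a.ref_start - 1 : a.ref_end]
            q = mut[a.qry_chr][a.qry_start - 1 : a.qry_end]
            assert r == (revcomp(q) if a.strand == "-" else q)


class TestEvaluation:
    def _truth(self):
        return [TruthRecord("INV", "chr1", 1000, 2000, "chr1", 1000, 2000, size=1001)]

    def _ann(self, type_, rs=1000, re_=2000, qs=1000, qe=2000):
        return Annotation(type_, "chr1", rs, re_, "chr1", qs, qe)

    def test_exact_prediction_is_identified(self):
        table = evaluate_predictions([self._ann("INV")], self._truth())
        assert table.counts["INV"]["identified"] == 1

    def test_one_breakpoint_with_correct_type_is_indicated(self):
        table = evaluate_predictions([self._ann("INV", 1000, 5000, 1000, 5000)], self._truth())
        assert table.counts["INV"]["indicated"] == 1

    def test_right_breakpoints_wrong_type_is_incorrect(self):
        table = evaluate_predictions([self._ann("TRANS")], self._truth())
        assert table.counts["INV"]["incorrect"] == 1

    def test_no_overlap_is_missed(self):
        table = evaluate_predictions([self._ann("INV", 8000, 9000, 8000, 9000)], self._truth())
        assert table.counts["INV"]["missed"] == 1

    def test_tolerance_bounds_breakpoint_matching(self):
        shifted = self._ann("INV", 1100, 2100, 1100, 2100)
        assert evaluate_predictions([shifted], self._truth(), tolerance=150).counts["INV"]["identified"] == 1
        assert evaluate_predictions([shifted], self._truth(), tolerance=50).counts["INV"]["missed"] == 1

    def test_duplication_truth_accepts_any_duplication_like_type(self):
        truth = [TruthRecord("DISTAL_DUP", "chr1", 1000, 2000, "chr1", 5000, 6000, size=1001)]
        ann = Annotation("INVDP", "chr1", 1000, 2000, "chr1", 5000, 6000)
        table = evaluate_predictions([ann], truth)
        assert table.counts["DISTAL_DUP"]["identified"] == 1

    def test_categories_partition_the_truth_set(self, mixed_sim):
        table = evaluate_predictions(mixed_sim["result"].annotations, mixed_sim["truth"])
        from collections import Counter
        truth_kinds = Counter(t.kind for t in mixed_sim["truth"] if t.kind not in ("INS", "DEL"))
        for kind, n in truth_kinds.items():
            assert sum(table.counts[kind].values()) == n


class TestIndelEvaluation:
    def _truth(self):
        return [
            TruthRecord("INS", "chr1", 1000, 1000, size=100),
            TruthRecord("DEL", "chr1", 5000, 5199, size=200),
        ]

    def _pred(self, kind, pos, size):
        from asmdiff.alignio import VariantCall
        if kind == "INS":
            return VariantCall("INS", "chr1", pos, pos, "chr1", 1, size)
        return VariantCall("DEL", "chr1", pos, pos + size - 1, "chr1", 1, 1)

    def test_exact_predictions_score_perfectly(self):
        preds = [self._pred("INS", 1000, 100), self._pred("DEL", 5000, 200)]
        res = evaluate_indels(preds, self._truth())
        assert res[5] == (1.0, 1.0) and res[100] == (1.0, 1.0)

    def test_empty_predictions_follow_the_convention(self):
        res = evaluate_indels([], self._truth())
        assert res[5] == (0.0, 1.0)

    def test_perturbed_positions_match_only_at_the_loose_tolerance(self):
        preds = [self._pred("INS", 1060, 100), self._pred("DEL", 5060, 200)]
        res = evaluate_indels(preds, self._truth())
        assert res[5] == (0.0, 0.0)
        assert res[100] == (1.0, 1.0)

    def test_type_must_match(self):
        preds = [self._pred("DEL", 1000, 100)]
        res = evaluate_indels(preds, self._truth())
        assert res[100][0] == 0.0

    def test_matching_is_one_to_one(self):
        preds = [self._pred("INS", 1000, 100), self._pred("INS", 1003, 100)]
        res = evaluate_indels(preds, self._truth())
        # one truth insertion: only one prediction can match
        assert res[100] == (0.5, 0.5)
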