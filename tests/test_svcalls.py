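from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmdiff.alignio import Alignment, Annotation, ContractViolation, GenomePair, revcomp
from asmdiff.svcalls import (
    AnnotationBlock,
    build_blocks,
    call_gap_variants,
    call_small_variants,
    classify_gap,
    find_unaligned,
)


def _aln(rs, re_, qs, qe, i=0, strand="+", cigar=None):
    return Alignment("r1", rs, re_, "q1", qs, qe, strand, 1.0, cigar=cigar, id=i)


class TestBlocks:
    def _ann(self, type_, rs, re_, qs, qe):
        return Annotation(type_, "r1", rs, re_, "q1", qs, qe,
                          members=[_aln(rs, re_, qs, qe)])

    def test_consecutive_same_type_merge(self):
        anns = [self._ann("SYN", 1, 100, 1, 100), self._ann("SYN", 101, 200, 101, 200),
                self._ann("SYN", 201, 300, 201, 300)]
        (block,) = build_blocks(anns)
        assert block.type == "SYN" and len(block.members) == 3
        assert (block.ref_start, block.ref_end) == (1, 300)

    def test_type_change_opens_a_new_block(self):
        anns = [self._ann("SYN", 1, 100, 1, 100), self._ann("INV", 101, 200, 101, 200),
                self._ann("SYN", 201, 300, 201, 300)]
        assert [b.type for b in build_blocks(anns)] == ["SYN", "INV", "SYN"]

    def test_block_count_equals_type_changes_plus_one(self, rng):
        """Run-length oracle on random annotation sequences."""
        types = ["SYN", "INV", "TRANS"]
        for _ in range(30):
            seq = [types[i] for i in rng.integers(0, 3, size=int(rng.integers(1, 40)))]
            anns = [self._ann(t, 100 * k + 1, 100 * k + 90, 100 * k + 1, 100 * k + 90)
                    for k, t in enumerate(seq)]
            changes = sum(a != b for a, b in zip(seq, seq[1:]))
            assert len(build_blocks(anns)) == changes + 1


class TestSmallVariants:
    def test_snp_from_mismatch(self):
        a = _aln(1, 8, 1, 8, cigar="3=1X4=")
        (v,) = call_small_variants(a, "AAATAAAA", "AAACAAAA")
        assert (v.kind, v.ref_start, v.ref_allele, v.qry_allele) == ("SNP", 4, "T", "C")
        assert v.qry_start == 4

    def test_insertion_anchored_after_preceding_base(self):
        a = _aln(1, 8, 1, 10, cigar="5=2I3=")
        (v,) = call_small_variants(a, "AAAAATTT", "AAAAAGGTTT")
        assert (v.kind, v.ref_start, v.ref_end) == ("INS", 5, 5)
        assert (v.qry_start, v.qry_end, v.qry_allele) == (6, 7, "GG")

    def test_deletion_reports_reference_interval(self):
        a = _aln(1, 10, 1, 8, cigar="5=2D3=")
        (v,) = call_small_variants(a, "AAAAAGGTTT", "AAAAATTT")
        assert (v.kind, v.ref_start, v.ref_end, v.ref_allele) == ("DEL", 6, 7, "GG")

    def test_plain_m_ops_split_with_sequences(self):
        a = _aln(1, 8, 1, 8, cigar="8M")
        vs = call_small_variants(a, "AAATAAAA", "AAACAAAA")
        assert [(v.kind, v.ref_start) for v in vs] == [("SNP", 4)]

    def test_minus_strand_query_positions_map_back(self):
        ref = "AAATAAAA"
        qry_fwd = "AAACAAAA"              # aligned (strand-normalised) query
        qry = revcomp(qry_fwd)            # genome stores the reverse complement
        a = _aln(1, 8, 1, 8, strand="-", cigar="8M")
        (v,) = call_small_variants(a, ref, qry)
        assert v.kind == "SNP" and v.ref_start == 4
        assert v.qry_start == 8 - 4 + 1   # mirrored position

    def test_cigar_length_mismatch_is_a_contract_violation(self):
        a = _aln(1, 8, 1, 8, cigar="5=")
        with pytest.raises(ContractViolation):
            call_small_variants(a, "A" * 8, "A" * 8)

    def test_variant_walk_reconstructs_query(self, rng):
        """Applying the called variants to the reference segment reproduces
        the aligned query segment exactly (round-trip)."""
        bases = np.array(list("ACGT"))
        for _ in range(25):
            ref = "".join(bases[rng.integers(0, 4, 60)])
            qry = []
            cigar = []
            i = 0
            last_op = ""
            while i < 60:
                op = rng.choice(["=", "X", "I", "D"], p=[0.6, 0.2, 0.1, 0.1])
                if op == "I" and last_op == "I":
                    continue  # two stacked insertions share one anchor
                last_op = op
                n = int(rng.integers(1, 6))
                if op == "=":
                    n = min(n, 60 - i)
                    qry.append(ref[i : i + n]); i += n
                elif op == "X":
                    n = min(n, 60 - i)
                    qry.append("".join("ACGT"[("ACGT".index(c) + 1) % 4] for c in ref[i : i + n]))
                    i += n
                elif op == "I":
                    qry.append("".join(bases[rng.integers(0, 4, n)]))
                else:
                    n = min(n, 60 - i)
                    i += n
                if n:
                    cigar.append(f"{n}{op}")
            qry_s = "".join(qry)
            if not qry_s:
                continue
            a = _aln(1, 60, 1, len(qry_s), cigar="".join(cigar))
            variants = call_small_variants(a, ref, qry_s)
            rebuilt = list(ref)
            # apply right-to-left so coordinates stay valid
            for v in sorted(variants, key=lambda v: -v.ref_start):
                if v.kind == "SNP":
                    rebuilt[v.ref_start - 1] = v.qry_allele
                elif v.kind == "DEL":
                    del rebuilt[v.ref_start - 1 : v.ref_end]
                elif v.kind == "INS":
                    rebuilt.insert(v.ref_start, v.qry_allele)
            assert "".join(rebuilt) == qry_s


class TestGapVariants:
    def test_reference_gap_is_deletion(self):
        block = AnnotationBlock("SYN", "r1", 1, 300, "q1", 1, 250,
                                members=[_aln(1, 100, 1, 100, 0), _aln(151, 300, 101, 250, 1)])
        (v,) = call_gap_variants(block)
        assert (v.kind, v.ref_start, v.ref_end) == ("DEL", 101, 150)

    def test_double_gap_is_hdr(self):
        block = AnnotationBlock("SYN", "r1", 1, 300, "q1", 1, 320,
                                members=[_aln(1, 100, 1, 100, 0), _aln(141, 300, 171, 320, 1)])
        (v,) = call_gap_variants(block)
        assert v.kind == "HDR"
        assert (v.ref_start, v.ref_end) == (101, 140)
        assert (v.qry_start, v.qry_end) == (101, 170)

    def test_reference_overlap_is_copy_loss(self):
        block = AnnotationBlock("SYN", "r1", 1, 200, "q1", 1, 190,
                                members=[_aln(1, 100, 1, 100, 0), _aln(91, 200, 101, 190, 1)])
        (v,) = call_gap_variants(block)
        assert (v.kind, v.ref_start, v.ref_end) == ("CPL", 91, 100)

    def test_query_overlap_is_copy_gain(self):
        block = AnnotationBlock("SYN", "r1", 1, 200, "q1", 1, 200,
                                members=[_aln(1, 100, 1, 100, 0), _aln(101, 200, 91, 200, 1)])
        (v,) = call_gap_variants(block)
        assert v.kind == "CPG"

    def test_inverted_block_gap_uses_reversed_query_order(self):
        # inversion pieces: reference ascending, query descending
        block = AnnotationBlock("INV", "r1", 1, 300, "q1", 1, 290,
                                members=[_aln(1, 100, 191, 290, 0, strand="-"),
                                         _aln(111, 300, 1, 190, 1, strand="-")])
        (v,) = call_gap_variants(block)
        assert (v.kind, v.ref_start, v.ref_end) == ("DEL", 101, 110)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(r=st.integers(-50, 50), q=st.integers(-50, 50))
    def test_classification_is_total_and_unique(self, r, q):
        kind = classify_gap(r, q)
        if r == 0 and q == 0:
            assert kind is None
        else:
            assert kind in {"DEL", "INS", "HDR", "CPL", "CPG", "TDM"}
        if r > 0 and q > 0:
            assert kind == "HDR"
        if r < 0 and q < 0:
            assert kind == "TDM"


class TestUnaligned:
    def _block(self, rs, re_, qs, qe):
        return AnnotationBlock("SYN", "r1", rs, re_, "q1", qs, qe)

    def test_fully_covered_chromosome_has_no_notal(self):
        gp = GenomePair({"r1": 1000}, {"q1": 1000})
        assert find_unaligned([self._block(1, 1000, 1, 1000)], gp) == []

    def test_tail_reported(self):
        gp = GenomePair({"r1": 1000}, {"q1": 900})
        calls = find_unaligned([self._block(1, 900, 1, 900)], gp)
        (v,) = [c for c in calls if c.ref_chr]
        assert (v.kind, v.ref_start, v.ref_end) == ("NOTAL", 901, 1000)

    def test_block_plus_notal_bases_partition_the_chromosome(self, rng):
        """Interval-union oracle: covered plus reported un-aligned bases
        equal the chromosome length, with no double counting."""
        for _ in range(20):
            spans = []
            pos = 1
            while pos < 900:
                s = pos + int(rng.integers(0, 60))
                e = s + int(rng.integers(0, 100))
                if e > 1000:
                    break
                spans.append((s, min(e, 1000)))
                pos = e + 2
            gp = GenomePair({"r1": 1000}, {"q1": 1000})
            blocks = [self._block(s, e, s, e) for s, e in spans]
            notal = [v for v in find_unaligned(blocks, gp) if v.ref_chr]
            covered = set()
            for s, e in spans:
                covered.update(range(s, e + 1))
            notal_bases = sum(v.ref_end - v.ref_start + 1 for v in notal)
            assert notal_bases == 1000 - len(covered)
            for v in notal:
                assert not covered & set(range(v.ref_start, v.ref_end + 1))
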