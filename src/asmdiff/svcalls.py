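"""Annotation blocks and local sequence differences (step 3).

Neighbouring annotations of the same structural class merge into annotation
blocks; a syntenic block holds all consecutive syntenic alignments, an
inversion or TD block the full extent of that rearrangement.  Local
differences then come from two sources: SNPs and small indels are parsed
directly out of the alignment CIGARs, while larger events live in the gaps
and overlaps *between* consecutive alignments of a block — a reference-only
gap is a deletion, a query-only gap an insertion, a gap on both sides a
highly divergent region (HDR), and overlaps signal copy-number changes
(CPL: the query lost copies, CPG: the query gained copies, TDM: overlap on
both sides, a tandem-repeat discrepancy).  Whatever ends up in no block at
all is reported as un-aligned (NOTAL).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .alignio import Alignment, Annotation, ContractViolation, GenomePair, VariantCall, revcomp

__all__ = [
    "AnnotationBlock",
    "build_blocks",
    "call_small_variants",
    "call_gap_variants",
    "find_unaligned",
    "classify_gap",
]

log = logging.getLogger(__name__)

MIN_NOTAL = 1  # bp; report every un-aligned region

_INVERTED_TYPES = {"INV", "INVTR", "INVDP"}


@dataclass
class AnnotationBlock:
    """A maximal run of consecutive same-type annotations."""

    type: str
    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str
    qry_start: int
    qry_end: int
    members: list[Alignment] = field(default_factory=list)
    id: int = -1

    @property
    def inverted(self) -> bool:
        return self.type in _INVERTED_TYPES


def build_blocks(annotations: list[Annotation]) -> list[AnnotationBlock]:
    """Merge neighbouring same-type annotations into blocks.

    Annotations are walked in reference order per chromosome; a block closes
    whenever the type or either chromosome changes, so on an interleaved
    annotation sequence the number of blocks equals the number of
    type-change boundaries plus one.  Two refinements keep block spans
    honest in rearranged regions: an annotation nested inside the reference
    extent of the current run (e.g. the origin of a duplication inside a
    syntenic stretch) becomes its own block without interrupting the run,
    and a run is split wherever the query-side gap between consecutive
    members is occupied by some other annotation (e.g. a transposition
    target), because the run is not contiguous in the query there.
    """
    from intervaltree import IntervalTree

    ordered = sorted(annotations, key=lambda a: (a.ref_chr, a.ref_start, -a.ref_end))
    qry_trees: dict[str, IntervalTree] = {}
    for i, ann in enumerate(ordered):
        if ann.qry_chr:
            qry_trees.setdefault(ann.qry_chr, IntervalTree()).addi(
                ann.qry_start, ann.qry_end + 1, i
            )

    runs: list[list[tuple[int, Annotation]]] = []
    current: list[tuple[int, Annotation]] = []
    cur_ref_end = -1
    for i, ann in enumerate(ordered):
        if current:
            same = (
                ann.type == current[0][1].type
                and ann.ref_chr == current[0][1].ref_chr
                and ann.qry_chr == current[0][1].qry_chr
            )
            if same:
                current.append((i, ann))
                cur_ref_end = max(cur_ref_end, ann.ref_end)
                continue
            if ann.ref_chr == current[0][1].ref_chr and ann.ref_end <= cur_ref_end:
                runs.append([(i, ann)])  # nested: standalone block, run continues
                continue
            runs.append(current)
            current = []
        current = [(i, ann)]
        cur_ref_end = ann.ref_end
    if current:
        runs.append(current)

    def qry_gap_occupied(a: Annotation, b: Annotation, own: set[int]) -> bool:
        inverted = a.type in _INVERTED_TYPES
        lo, hi = (
            (b.qry_end + 1, a.qry_start) if inverted else (a.qry_end + 1, b.qry_start)
        )
        if hi <= lo:
            return False
        tree = qry_trees.get(a.qry_chr)
        return tree is not None and any(
            iv.data not in own for iv in tree.overlap(lo, hi)
        )

    blocks: list[AnnotationBlock] = []

    def emit(run: list[tuple[int, Annotation]]) -> None:
        anns = [a for _, a in run]
        blocks.append(
            AnnotationBlock(
                anns[0].type,
                anns[0].ref_chr,
                min(a.ref_start for a in anns),
                max(a.ref_end for a in anns),
                anns[0].qry_chr,
                min(a.qry_start for a in anns),
                max(a.qry_end for a in anns),
                members=[m for a in anns for m in a.members],
                id=len(blocks),
            )
        )

    for run in runs:
        own = {i for i, _ in run}
        piece: list[tuple[int, Annotation]] = []
        for item in run:
            if piece and qry_gap_occupied(piece[-1][1], item[1], own):
                emit(piece)
                piece = []
            piece.append(item)
        if piece:
            emit(piece)
    return blocks


# ---------------------------------------------------------------------------
# SNPs and small indels from CIGAR strings
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ContractViolation(f"unparsable cigar {cigar!r}")
    return ops


def call_small_variants(
    alignment: Alignment,
    ref_seq: str,
    qry_seq: str,
    parent: int = -1,
) -> list[VariantCall]:
    """Walk an alignment CIGAR and emit SNP / INS / DEL calls.

    ``ref_seq`` and ``qry_seq`` are the full chromosome sequences.  For
    minus-strand alignments the query segment is reverse-complemented before
    the walk and query genome coordinates are mapped back accordingly.
    Insertions use the zero-reference-length convention (anchored at the
    preceding reference base).
    """
    a = alignment
    if a.cigar is None:
        raise ContractViolation(f"alignment {a.id} has no cigar")
    ops = parse_cigar(a.cigar)
    ref_used = sum(n for n, op in ops if op in "MDN=X")
    qry_used = sum(n for n, op in ops if op in "MI=X")
    if ref_used != a.ref_len or qry_used != a.qry_len:
        raise ContractViolation(
            f"alignment {a.id}: cigar walks {ref_used}/{qry_used} bases but "
            f"coordinates span {a.ref_len}/{a.qry_len}"
        )
    R = ref_seq[a.ref_start - 1 : a.ref_end]
    Q = qry_seq[a.qry_start - 1 : a.qry_end]
    if a.strand == "-":
        Q = revcomp(Q)

    def qry_pos(j: int) -> int:
        # j is a 0-based offset in the walked (strand-normalised) query
        return a.qry_start + j if a.strand == "+" else a.qry_end - j

    out: list[VariantCall] = []
    i = j = 0  # offsets into R and walked Q
    for n, op in ops:
        if op in "=M":
            if op == "M":
                seg_r, seg_q = R[i : i + n], Q[j : j + n]
                for k in range(n):
                    if seg_r[k] != seg_q[k]:
                        out.append(_snp(a, i + k, j + k, seg_r[k], seg_q[k], qry_pos, parent))
            i += n
            j += n
        elif op == "X":
            for k in range(n):
                out.append(_snp(a, i + k, j + k, R[i + k], Q[j + k], qry_pos, parent))
            i += n
            j += n
        elif op == "I":
            qs, qe = qry_pos(j), qry_pos(j + n - 1)
            out.append(
                VariantCall(
                    "INS", a.ref_chr, a.ref_start + i - 1, a.ref_start + i - 1,
                    a.qry_chr, min(qs, qe), max(qs, qe),
                    ref_allele="-", qry_allele=Q[j : j + n], parent=parent,
                )
            )
            j += n
        elif op in "DN":
            out.append(
                VariantCall(
                    "DEL", a.ref_chr, a.ref_start + i, a.ref_start + i + n - 1,
                    a.qry_chr, qry_pos(j - 1) if j else qry_pos(0), qry_pos(j - 1) if j else qry_pos(0),
                    ref_allele=R[i : i + n], qry_allele="-", parent=parent,
                )
            )
            i += n
        elif op in "SHP":
            raise ContractViolation(f"unsupported cigar op {op} in genome alignment")
    return out


def _snp(a: Alignment, i: int, j: int, rb: str, qb: str, qry_pos, parent: int) -> VariantCall:
    p = qry_pos(j)
    return VariantCall(
        "SNP", a.ref_chr, a.ref_start + i, a.ref_start + i,
        a.qry_chr, p, p, ref_allele=rb, qry_allele=qb, parent=parent,
    )


# ---------------------------------------------------------------------------
# Structural differences from gaps/overlaps between consecutive alignments
# ---------------------------------------------------------------------------

def classify_gap(r: int, q: int) -> str | None:
    """Total classification of the (reference gap, query gap) pair between
    two consecutive alignments of a block.  Negative values are overlaps."""
    if r > 0 and q > 0:
        return "HDR"
    if r > 0 and q == 0:
        return "DEL"
    if r == 0 and q > 0:
        return "INS"
    if r < 0 and q < 0:
        return "TDM"
    if r < 0:
        return "CPL"
    if q < 0:
        return "CPG"
    return None


def call_gap_variants(block: AnnotationBlock) -> list[VariantCall]:
    """Classify the gap/overlap between every consecutive alignment pair of
    a block.  Members are ordered along the reference; in inverted blocks
    the query runs backwards, which the query-gap computation accounts for."""
    members = sorted(block.members, key=lambda a: (a.ref_start, a.ref_end))
    out: list[VariantCall] = []
    for a, b in zip(members, members[1:]):
        if b.ref_start <= a.ref_start:
            raise ContractViolation("block members out of order on reference")
        r = b.ref_start - a.ref_end - 1
        if block.inverted:
            q = a.qry_start - b.qry_end - 1
            q_gap = (b.qry_end + 1, a.qry_start - 1)     # interval when q > 0
            q_olap = (a.qry_start, b.qry_end)            # interval when q < 0
            q_anchor = a.qry_start
        else:
            q = b.qry_start - a.qry_end - 1
            q_gap = (a.qry_end + 1, b.qry_start - 1)
            q_olap = (b.qry_start, a.qry_end)
            q_anchor = a.qry_end
        kind = classify_gap(r, q)
        if kind is None:
            continue
        r_gap = (a.ref_end + 1, b.ref_start - 1)
        r_olap = (b.ref_start, a.ref_end)
        r_anchor = a.ref_end
        if kind == "DEL":
            coords = (*r_gap, q_anchor, q_anchor)
        elif kind == "INS":
            coords = (r_anchor, r_anchor, *q_gap)
        elif kind == "HDR":
            coords = (*r_gap, *q_gap)
        elif kind == "CPL":
            coords = (*r_olap, q_anchor, q_anchor) if q == 0 else (*r_olap, *q_gap)
        elif kind == "CPG":
            coords = (r_anchor, r_anchor, *q_olap) if r == 0 else (*r_gap, *q_olap)
        else:  # TDM
            coords = (*r_olap, *q_olap)
        out.append(
            VariantCall(
                kind, block.ref_chr, coords[0], coords[1],
                block.qry_chr, coords[2], coords[3], parent=block.id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Un-aligned regions
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_unaligned(
    blocks: list[AnnotationBlock],
    genomes: GenomePair,
    min_notal: int = MIN_NOTAL,
) -> list[VariantCall]:
    """Report, per genome and chromosome, the complement of the union of the
    block spans as NOTAL records (other-genome fields empty)."""
    out: list[VariantCall] = []
    for side, sizes in (("ref", genomes.ref_sizes), ("qry", genomes.qry_sizes)):
        per_chr: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
        for b in blocks:
            chrom = b.ref_chr if side == "ref" else b.qry_chr
            span = (b.ref_start, b.ref_end) if side == "ref" else (b.qry_start, b.qry_end)
            if chrom in per_chr:
                per_chr[chrom].append(span)
        for chrom in sorted(per_chr):
            length = sizes[chrom]
            pos = 1
            for s, e in _merge_intervals(per_chr[chrom]) + [(length + 1, length + 1)]:
                if s > pos and (s - pos) >= min_notal:
                    if side == "ref":
                        out.append(VariantCall("NOTAL", chrom, pos, s - 1, "", 0, 0))
                    else:
                        out.append(VariantCall("NOTAL", "", 0, 0, chrom, pos, s - 1))
                pos = max(pos, e + 1)
    return out
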