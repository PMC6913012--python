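"""Translocation, transposition and duplication identification (step 2b).

After the syntenic backbone and the inversions are fixed, every remaining
alignment is either the footprint of a relocated / duplicated region or a
redundant (repetitive) alignment.  The scan proceeds in four moves:

1. *group* residual alignments into candidate rearranged regions (chains
   bounded by a maximum gap, one orientation and chromosome pair each);
2. *filter* low-scoring candidates and candidates redundant with already
   annotated regions;
3. *resolve* conflicts between candidates that would place the same query
   sequence twice, keeping the maximum-total-score conflict-free subset;
4. *classify* the survivors: same-chromosome relocation is a transposition
   (TRANS), cross-chromosome a translocation (also reported TRANS, with the
   chromosome fields differing), inverted ones INVTR, and candidates whose
   span re-aligns material that is already annotated elsewhere are
   duplications (DUP / INVDP), tandem when the two copies are adjacent.

A candidate's score is its mean aligned length minus its mean gap length,
both averaged over the two genomes; the filter demands that at least
``min_score_ratio`` of the candidate span is net-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .alignio import Alignment, Annotation, GenomePair, group_by_chrom_pair
from .inversions import EXACT_LIMIT, OVERLAP_MARGIN, max_weight_independent_set, mirror_alignment
from .synteny import precedes

__all__ = [
    "CandidateTD",
    "group_candidate_tds",
    "filter_candidates",
    "resolve_td_conflicts",
    "classify_rearrangements",
    "find_tds",
]

MAX_GAP = 10_000        # bp allowed between consecutive chain members
MIN_SCORE_RATIO = 0.5   # net-aligned fraction of the span required
DUP_COV = 0.8           # coverage by other annotations that makes a duplication
TANDEM_GAP = 100        # bp separating tandem from distal duplication copies


@dataclass
class CandidateTD:
    """A chained group of residual alignments proposed as one rearrangement."""

    members: list[Alignment]        # original alignments, reference order
    inverted: bool
    ref_chr: str
    qry_chr: str
    ref_span: tuple[int, int]
    qry_span: tuple[int, int]
    aligned_len: float = 0.0        # mean over genomes of total aligned bases
    gap_len: float = 0.0            # mean over genomes of inter-member gaps

    @property
    def score(self) -> float:
        return self.aligned_len - self.gap_len

    @property
    def span_len(self) -> float:
        return (
            (self.ref_span[1] - self.ref_span[0] + 1)
            + (self.qry_span[1] - self.qry_span[0] + 1)
        ) / 2.0


def _make_candidate(members_mirrored: list[Alignment], originals: dict[int, Alignment],
                    inverted: bool) -> CandidateTD:
    origs = [originals[a.id] for a in members_mirrored]
    ref_span = (min(a.ref_start for a in origs), max(a.ref_end for a in origs))
    qry_span = (min(a.qry_start for a in origs), max(a.qry_end for a in origs))
    aligned_ref = sum(a.ref_len for a in origs)
    aligned_qry = sum(a.qry_len for a in origs)
    gap_ref = gap_qry = 0
    for a, b in zip(members_mirrored, members_mirrored[1:]):
        gap_ref += b.ref_start - a.ref_end - 1
        gap_qry += b.qry_start - a.qry_end - 1
    return CandidateTD(
        members=origs,
        inverted=inverted,
        ref_chr=origs[0].ref_chr,
        qry_chr=origs[0].qry_chr,
        ref_span=ref_span,
        qry_span=qry_span,
        aligned_len=(aligned_ref + aligned_qry) / 2.0,
        gap_len=(gap_ref + gap_qry) / 2.0,
    )


def group_candidate_tds(
    residual: list[Alignment],
    qry_sizes: dict[str, int],
    max_gap: int = MAX_GAP,
) -> list[CandidateTD]:
    """Chain residual alignments into candidate rearranged regions.

    Alignments are bucketed by (ref_chr, qry_chr, orientation); inverted
    buckets are mirrored first so the collinearity predicate applies.  In
    each bucket the gap-bounded chain DAG is built and, proceeding from the
    highest-scoring start, the best chain from every not-yet-consumed
    alignment is emitted.  Every residual alignment ends up in at least one
    candidate.
    """
    candidates: list[CandidateTD] = []
    buckets: dict[tuple[str, str, str], list[Alignment]] = {}
    for a in residual:
        buckets.setdefault((a.ref_chr, a.qry_chr, a.strand), []).append(a)

    for (ref_chr, qry_chr, strand) in sorted(buckets):
        bucket = buckets[(ref_chr, qry_chr, strand)]
        inverted = strand == "-"
        originals = {a.id: a for a in bucket}
        work = (
            [mirror_alignment(a, qry_sizes[qry_chr]) for a in bucket]
            if inverted
            else bucket
        )
        nodes = sorted(work, key=lambda a: (a.ref_start, a.ref_end, a.id))
        n = len(nodes)
        succ: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                a, b = nodes[i], nodes[j]
                if (
                    precedes(a, b)
                    and b.ref_start - a.ref_end - 1 <= max_gap
                    and b.qry_start - a.qry_end - 1 <= max_gap
                ):
                    succ[i].append(j)
        # best chain starting at each node, scored as aligned - gap (means)
        val = [0.0] * n
        nxt = [-1] * n
        for i in range(n - 1, -1, -1):
            a = nodes[i]
            val[i] = (a.ref_len + a.qry_len) / 2.0
            best = 0.0
            for j in succ[i]:
                b = nodes[j]
                gain = val[j] - ((b.ref_start - a.ref_end - 1) + (b.qry_start - a.qry_end - 1)) / 2.0
                if gain > best:
                    best = gain
                    nxt[i] = j
            if nxt[i] == -1:
                best = 0.0
            val[i] += best
        consumed = [False] * n
        for i in sorted(range(n), key=lambda i: (-val[i], nodes[i].id)):
            if consumed[i]:
                continue
            chain = []
            k = i
            while k != -1:
                chain.append(nodes[k])
                consumed[k] = True
                k = nxt[k]
            candidates.append(_make_candidate(chain, originals, inverted))
    return candidates


def _coverage(tree: IntervalTree, span: tuple[int, int]) -> int:
    """Bases of ``span`` (inclusive) covered by intervals in ``tree``."""
    lo, hi = span[0], span[1] + 1
    covered = IntervalTree()
    for iv in tree.overlap(lo, hi):
        covered.addi(max(iv.begin, lo), min(iv.end, hi))
    covered.merge_overlaps()
    return sum(iv.end - iv.begin for iv in covered)


def _annotation_trees(
    annotations: list[Annotation],
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    ref_trees: dict[str, IntervalTree] = {}
    qry_trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        if ann.ref_chr:
            ref_trees.setdefault(ann.ref_chr, IntervalTree()).addi(
                ann.ref_start, ann.ref_end + 1, ann
            )
        if ann.qry_chr:
            qry_trees.setdefault(ann.qry_chr, IntervalTree()).addi(
                ann.qry_start, ann.qry_end + 1, ann
            )
    return ref_trees, qry_trees


def filter_candidates(
    candidates: list[CandidateTD],
    annotations: list[Annotation],
    min_score_ratio: float = MIN_SCORE_RATIO,
    overlap_margin: int = OVERLAP_MARGIN,
) -> list[CandidateTD]:
    """Drop low-scoring candidates and candidates redundant with existing
    annotations.

    A candidate is low-scoring when its score falls below ``min_score_ratio``
    times its span length.  It is redundant when *both* its reference and its
    query span are overlapped (beyond ``overlap_margin`` bp) by syntenic or
    inverted regions — a candidate overlapping on one genome only is kept,
    because that is exactly the footprint of a duplication.
    """
    ref_trees, qry_trees = _annotation_trees(
        [a for a in annotations if a.type in ("SYN", "INV")]
    )
    kept: list[CandidateTD] = []
    for cand in candidates:
        if cand.score < min_score_ratio * cand.span_len:
            continue
        ref_ov = _coverage(ref_trees.get(cand.ref_chr, IntervalTree()), cand.ref_span)
        qry_ov = _coverage(qry_trees.get(cand.qry_chr, IntervalTree()), cand.qry_span)
        if ref_ov > overlap_margin and qry_ov > overlap_margin:
            continue
        kept.append(cand)
    return kept


def resolve_td_conflicts(
    candidates: list[CandidateTD],
    exact_limit: int = EXACT_LIMIT,
) -> tuple[list[CandidateTD], list[Alignment]]:
    """Keep the maximum-total-score subset of candidates no two of which
    place the same query sequence, i.e. whose query spans overlap or which
    share a member alignment.  Alignments of discarded candidates that occur
    in no selected candidate are returned as redundant."""
    n = len(candidates)
    adj: list[set[int]] = [set() for _ in range(n)]
    member_ids = [frozenset(a.id for a in c.members) for c in candidates]
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = candidates[i], candidates[j]
            conflict = bool(member_ids[i] & member_ids[j])
            if not conflict and ci.qry_chr == cj.qry_chr:
                conflict = (
                    min(ci.qry_span[1], cj.qry_span[1])
                    >= max(ci.qry_span[0], cj.qry_span[0])
                )
            if conflict:
                adj[i].add(j)
                adj[j].add(i)
    idx, _ = max_weight_independent_set([c.score for c in candidates], adj, exact_limit)
    selected = [candidates[i] for i in idx]
    kept_ids = {a.id for c in selected for a in c.members}
    redundant = [
        a for c in candidates for a in c.members if a.id not in kept_ids
    ]
    # dedupe while keeping order
    seen: set[int] = set()
    redundant = [a for a in redundant if not (a.id in seen or seen.add(a.id))]
    return selected, redundant


def classify_rearrangements(
    selected: list[CandidateTD],
    annotations: list[Annotation],
    genomes: GenomePair,
    dup_cov: float = DUP_COV,
    tandem_gap: int = TANDEM_GAP,
) -> list[Annotation]:
    """Assign exactly one structural class to every selected candidate.

    A candidate whose reference span is already covered (>= ``dup_cov``) by
    other annotations re-aligns known reference material to a new query
    location: the query holds the extra copy (DUP, copy_in_query).  The
    symmetric case marks a copy on the reference side.  The copy is tandem
    when it lies within ``tandem_gap`` bp of the query (resp. reference)
    image of the duplicated region.  Everything else is a relocation: TRANS
    for plain orientation (intra- or inter-chromosomal), INVTR when
    inverted.
    """
    ref_trees, qry_trees = _annotation_trees(
        [a for a in annotations if a.type in ("SYN", "INV")]
    )
    out: list[Annotation] = []
    for cand in sorted(selected, key=lambda c: (-c.score, c.ref_chr, c.ref_span)):
        ref_tree = ref_trees.setdefault(cand.ref_chr, IntervalTree())
        qry_tree = qry_trees.setdefault(cand.qry_chr, IntervalTree())
        ref_frac = _coverage(ref_tree, cand.ref_span) / (cand.ref_span[1] - cand.ref_span[0] + 1)
        qry_frac = _coverage(qry_tree, cand.qry_span) / (cand.qry_span[1] - cand.qry_span[0] + 1)
        tandem = False
        if ref_frac >= dup_cov:
            atype = "INVDP" if cand.inverted else "DUP"
            copy_status = "copy_in_query"
            tandem = _is_tandem(
                ref_tree, cand.ref_span, cand.qry_chr, cand.qry_span, "qry", tandem_gap
            )
        elif qry_frac >= dup_cov:
            atype = "INVDP" if cand.inverted else "DUP"
            copy_status = "copy_in_ref"
            tandem = _is_tandem(
                qry_tree, cand.qry_span, cand.ref_chr, cand.ref_span, "ref", tandem_gap
            )
        else:
            atype = "INVTR" if cand.inverted else "TRANS"
            copy_status = "-"
        ann = Annotation(
            atype, cand.ref_chr, cand.ref_span[0], cand.ref_span[1],
            cand.qry_chr, cand.qry_span[0], cand.qry_span[1],
            members=list(cand.members), copy_status=copy_status, tandem=tandem,
        )
        out.append(ann)
        ref_tree.addi(cand.ref_span[0], cand.ref_span[1] + 1, ann)
        qry_tree.addi(cand.qry_span[0], cand.qry_span[1] + 1, ann)
    return out


def _is_tandem(
    covering_tree: IntervalTree,
    covered_span: tuple[int, int],
    copy_chr: str,
    copy_span: tuple[int, int],
    copy_side: str,
    tandem_gap: int,
) -> bool:
    """The copy is tandem when it sits within ``tandem_gap`` of the image,
    on the copy's genome, of the region it duplicates."""
    for iv in covering_tree.overlap(covered_span[0], covered_span[1] + 1):
        ann: Annotation = iv.data
        if copy_side == "qry":
            img_chr, img = ann.qry_chr, (ann.qry_start, ann.qry_end)
        else:
            img_chr, img = ann.ref_chr, (ann.ref_start, ann.ref_end)
        if img_chr != copy_chr:
            continue
        dist = max(img[0] - copy_span[1], copy_span[0] - img[1], 0)
        if dist <= tandem_gap:
            return True
    return False


def find_tds(
    residual: list[Alignment],
    annotations: list[Annotation],
    genomes: GenomePair,
    max_gap: int = MAX_GAP,
    min_score_ratio: float = MIN_SCORE_RATIO,
    overlap_margin: int = OVERLAP_MARGIN,
    exact_limit: int = EXACT_LIMIT,
    dup_cov: float = DUP_COV,
    tandem_gap: int = TANDEM_GAP,
) -> tuple[list[Annotation], list[Alignment]]:
    """Full step-2b scan: group, filter, resolve, classify.  Returns the new
    annotations and the redundant alignments (filtered plus out-conflicted)."""
    cands = group_candidate_tds(residual, genomes.qry_sizes, max_gap)
    kept = filter_candidates(cands, annotations, min_score_ratio, overlap_margin)
    selected, redundant = resolve_td_conflicts(kept, exact_limit)
    selected_ids = {a.id for c in selected for a in c.members}
    dropped = [a for a in residual if a.id not in selected_ids]
    new = classify_rearrangements(selected, annotations, genomes, dup_cov, tandem_gap)
    return new, dropped
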