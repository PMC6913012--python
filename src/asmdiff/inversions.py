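"""Inversion identification (step 2a).

An inversion is a run of inverted alignments sitting between two syntenic
anchors.  Reverse-complementing the query chromosome turns inverted
alignments into forward ones, so after mirroring the query coordinates the
same collinearity DAG used for synteny applies.  Every contiguous subchain
of every maximal chain in that DAG is a *candidate* inversion; candidates
can overlap and contradict each other, so the final annotation is the
maximum-total-score subset of mutually non-conflicting candidates.

The conflict-free selection (exact branch-and-bound up to ``exact_limit``
candidates per conflict component, greedy with local exchange beyond) is
shared with translocation/duplication resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignio import Alignment, Annotation, ContractViolation
from .synteny import build_synteny_dag, highest_scoring_path, precedes

__all__ = [
    "CandidateInversion",
    "mirror_inverted_alignments",
    "mirror_alignment",
    "enumerate_candidate_inversions",
    "select_inversions",
    "find_inversions",
    "max_weight_independent_set",
]

MAX_CANDIDATES = 5000     # per connected component, before falling back
OVERLAP_MARGIN = 10       # bp of tolerated overlap with syntenic alignments
EXACT_LIMIT = 20          # component size up to which selection is exact


def mirror_alignment(a: Alignment, qry_chr_length: int) -> Alignment:
    """Mirror the query interval of one alignment: [s, e] -> [L-e+1, L-s+1],
    flipping the strand.  Applying the operation twice is the identity."""
    if a.qry_end > qry_chr_length:
        raise ContractViolation(
            f"alignment {a.id}: query interval exceeds chromosome length {qry_chr_length}"
        )
    return Alignment(
        a.ref_chr, a.ref_start, a.ref_end,
        a.qry_chr,
        qry_chr_length - a.qry_end + 1,
        qry_chr_length - a.qry_start + 1,
        "+" if a.strand == "-" else "-",
        a.identity, a.cigar, a.id,
    )


def mirror_inverted_alignments(alignments: list[Alignment], qry_chr_length: int) -> list[Alignment]:
    """Mirror a set of inverted alignments so they chain like forward ones.
    All inputs must be minus-strand alignments of one chromosome pair."""
    for a in alignments:
        if a.strand != "-":
            raise ContractViolation(f"alignment {a.id} is not inverted")
    return [mirror_alignment(a, qry_chr_length) for a in alignments]


@dataclass
class CandidateInversion:
    """A scored group of inverted alignments proposed as one inversion."""

    members: list[Alignment]            # original (unmirrored) alignments
    ref_span: tuple[int, int]
    qry_span: tuple[int, int]           # original query coordinates
    score: float
    ref_chr: str = ""
    qry_chr: str = ""


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _maximal_chains(nodes: list[Alignment], cap: int) -> list[list[Alignment]] | None:
    """All maximal chains of the collinearity DAG over ``nodes`` (sorted),
    or None when more than ``cap`` chains would be produced."""
    n = len(nodes)
    reach: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if precedes(nodes[i], nodes[j]):
                reach[i].add(j)
    # transitive reduction: a chain never skips a member it could include
    succ: list[list[int]] = [
        sorted(j for j in reach[i] if not any(j in reach[k] for k in reach[i] if k != j))
        for i in range(n)
    ]
    has_pred = [False] * n
    for i in range(n):
        for j in succ[i]:
            has_pred[j] = True
    chains: list[list[Alignment]] = []
    stack: list[int] = []

    def dfs(i: int) -> bool:
        stack.append(i)
        if not succ[i]:
            chains.append([nodes[k] for k in stack])
            if len(chains) > cap:
                return False
        else:
            for j in succ[i]:
                if not dfs(j):
                    return False
        stack.pop()
        return True

    for i in range(n):
        if not has_pred[i]:
            if not dfs(i):
                return None
            stack.clear()
    return chains


def enumerate_candidate_inversions(
    mirrored: list[Alignment],
    syn_annotations: list[Annotation],
    originals: dict[int, Alignment],
    max_candidates: int = MAX_CANDIDATES,
    overlap_margin: int = OVERLAP_MARGIN,
) -> list[CandidateInversion]:
    """Enumerate candidate inversions from mirrored (now forward) alignments.

    Every contiguous subchain of every maximal chain of the mirrored DAG is
    a candidate; a component producing more than ``max_candidates`` chains
    falls back to its single best chain.  Candidates whose span overlaps a
    syntenic alignment by more than ``overlap_margin`` bp on either genome
    are discarded.  ``originals`` maps alignment id to the unmirrored record
    (for query spans in genome coordinates).
    """
    if not mirrored:
        return []
    nodes = sorted(mirrored, key=lambda a: (a.ref_start, a.ref_end, a.id))
    # weak connectivity under the comparability relation partitions the work
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if precedes(nodes[i], nodes[j]) or precedes(nodes[j], nodes[i]):
                parent[find(i)] = find(j)
    comps: dict[int, list[Alignment]] = {}
    for i, a in enumerate(nodes):
        comps.setdefault(find(i), []).append(a)

    candidates: list[CandidateInversion] = []
    seen: set[tuple[int, ...]] = set()
    for comp in comps.values():
        chains = _maximal_chains(comp, max_candidates)
        if chains is None:
            chains = [highest_scoring_path(build_synteny_dag(comp))]
            subchains = chains  # fallback: single best chain, taken whole
        else:
            subchains = [
                chain[i:j]
                for chain in chains
                for i in range(len(chain))
                for j in range(i + 1, len(chain) + 1)
            ]
        for sub in subchains:
            key = tuple(a.id for a in sub)
            if not key or key in seen:
                continue
            seen.add(key)
            origs = [originals[a.id] for a in sub]
            ref_span = (min(a.ref_start for a in origs), max(a.ref_end for a in origs))
            qry_span = (min(a.qry_start for a in origs), max(a.qry_end for a in origs))
            cand = CandidateInversion(
                members=origs,
                ref_span=ref_span,
                qry_span=qry_span,
                score=sum(a.score for a in origs),
                ref_chr=origs[0].ref_chr,
                qry_chr=origs[0].qry_chr,
            )
            if _conflicts_with_syn(cand, syn_annotations, overlap_margin):
                continue
            candidates.append(cand)
    return candidates


def _conflicts_with_syn(
    cand: CandidateInversion, syn_annotations: list[Annotation], margin: int
) -> bool:
    for s in syn_annotations:
        if s.ref_chr == cand.ref_chr and _overlap(cand.ref_span, (s.ref_start, s.ref_end)) > margin:
            return True
        if s.qry_chr == cand.qry_chr and _overlap(cand.qry_span, (s.qry_start, s.qry_end)) > margin:
            return True
    return False


# ---------------------------------------------------------------------------
# Maximum-weight conflict-free selection (shared with TD resolution)
# ---------------------------------------------------------------------------

def _mwis_exact(weights: list[float], adj: list[set[int]]) -> tuple[list[int], float]:
    """Branch-and-bound maximum-weight independent set; exact."""
    order = sorted(range(len(weights)), key=lambda i: -weights[i])
    best: tuple[float, list[int]] = (0.0, [])
    chosen: list[int] = []

    def rec(pos: int, total: float, banned: set[int]) -> None:
        nonlocal best
        remaining = sum(weights[order[k]] for k in range(pos, len(order)) if order[k] not in banned)
        if total + remaining <= best[0] + 1e-12:
            return
        if pos == len(order):
            if total > best[0]:
                best = (total, chosen.copy())
            return
        v = order[pos]
        if v not in banned:
            chosen.append(v)
            rec(pos + 1, total + weights[v], banned | adj[v])
            chosen.pop()
        rec(pos + 1, total, banned)
        if total > best[0]:
            best = (total, chosen.copy())

    rec(0, 0.0, set())
    return sorted(best[1]), best[0]


def _mwis_greedy(weights: list[float], adj: list[set[int]]) -> tuple[list[int], float]:
    """Greedy by weight with single-vertex exchange passes; a heuristic used
    only above the exact-search size limit."""
    order = sorted(range(len(weights)), key=lambda i: -weights[i])
    chosen: set[int] = set()
    for v in order:
        if not (adj[v] & chosen):
            chosen.add(v)
    improved = True
    while improved:
        improved = False
        for v in order:
            if v in chosen:
                continue
            displaced = adj[v] & chosen
            if weights[v] > sum(weights[d] for d in displaced):
                chosen -= displaced
                chosen.add(v)
                improved = True
    return sorted(chosen), sum(weights[c] for c in chosen)


def max_weight_independent_set(
    weights: list[float],
    adj: list[set[int]],
    exact_limit: int = EXACT_LIMIT,
) -> tuple[list[int], float]:
    """Select the maximum-total-weight subset of items no two of which
    conflict.  The conflict graph is decomposed into connected components;
    components up to ``exact_limit`` vertices are solved exactly by
    branch-and-bound, larger ones greedily with local exchange."""
    n = len(weights)
    seen = [False] * n
    picked: list[int] = []
    total = 0.0
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        queue = [start]
        while queue:
            v = queue.pop()
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    queue.append(w)
        local = {v: k for k, v in enumerate(comp)}
        w_local = [weights[v] for v in comp]
        adj_local = [
            {local[u] for u in adj[v] if u in local} for v in comp
        ]
        solver = _mwis_exact if len(comp) <= exact_limit else _mwis_greedy
        idx, score = solver(w_local, adj_local)
        picked.extend(comp[i] for i in idx)
        total += score
    return sorted(picked), total


def select_inversions(
    candidates: list[CandidateInversion], exact_limit: int = EXACT_LIMIT
) -> list[CandidateInversion]:
    """Choose the best non-conflicting candidate set.  Two candidates
    conflict when their reference spans or query spans overlap (same
    chromosome) or when they share a member alignment."""
    n = len(candidates)
    adj: list[set[int]] = [set() for _ in range(n)]
    member_ids = [frozenset(a.id for a in c.members) for c in candidates]
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = candidates[i], candidates[j]
            conflict = bool(member_ids[i] & member_ids[j])
            if not conflict and ci.ref_chr == cj.ref_chr:
                conflict = _overlap(ci.ref_span, cj.ref_span) > 0
            if not conflict and ci.qry_chr == cj.qry_chr:
                conflict = _overlap(ci.qry_span, cj.qry_span) > 0
            if conflict:
                adj[i].add(j)
                adj[j].add(i)
    idx, _ = max_weight_independent_set([c.score for c in candidates], adj, exact_limit)
    return [candidates[i] for i in idx]


def find_inversions(
    residual: list[Alignment],
    syn_annotations: list[Annotation],
    qry_sizes: dict[str, int],
    homolog_map: dict[str, str],
    max_candidates: int = MAX_CANDIDATES,
    overlap_margin: int = OVERLAP_MARGIN,
    exact_limit: int = EXACT_LIMIT,
) -> tuple[list[Annotation], list[Alignment]]:
    """Run inversion identification over the residual alignments.

    Only inverted alignments between homologous chromosome pairs are
    considered.  Returns INV annotations (one per selected candidate) and
    the residual alignments that remain for TD scanning.
    """
    from .alignio import group_by_chrom_pair

    annotations: list[Annotation] = []
    chosen_ids: set[int] = set()
    groups = group_by_chrom_pair(residual)
    for (ref_chr, qry_chr) in sorted(groups):
        if homolog_map.get(ref_chr) != qry_chr:
            continue
        inverted = [a for a in groups[(ref_chr, qry_chr)] if a.strand == "-"]
        if not inverted:
            continue
        L = qry_sizes[qry_chr]
        mirrored = mirror_inverted_alignments(inverted, L)
        originals = {a.id: a for a in inverted}
        syn_here = [
            s for s in syn_annotations if s.ref_chr == ref_chr and s.qry_chr == qry_chr
        ]
        cands = enumerate_candidate_inversions(
            mirrored, syn_here, originals, max_candidates, overlap_margin
        )
        for cand in select_inversions(cands, exact_limit):
            annotations.append(
                Annotation(
                    "INV", cand.ref_chr, cand.ref_span[0], cand.ref_span[1],
                    cand.qry_chr, cand.qry_span[0], cand.qry_span[1],
                    members=list(cand.members),
                )
            )
            chosen_ids.update(a.id for a in cand.members)
    remaining = [a for a in residual if a.id not in chosen_ids]
    return annotations, remaining
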