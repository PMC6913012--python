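"""Syntenic-path identification (step 1 of the comparison).

For every pair of homologous chromosomes the forward alignments form a
directed acyclic graph: there is an edge from alignment ``a`` to alignment
``b`` when ``b`` starts strictly after ``a`` ends on *both* genomes.  Any
path through this DAG is a collinear chain, and the highest-scoring path is
the syntenic backbone of the chromosome pair — the longest set of
non-rearranged regions.  Everything not on the chosen path is, by
definition, a candidate rearrangement and is handed to the later steps.

The chain score is the plain sum of node scores (no gap penalty); ties are
broken first towards smaller total gap length, then towards smaller
alignment ids, which makes the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignio import Alignment, Annotation, ContractViolation, GenomePair, group_by_chrom_pair

__all__ = [
    "SyntenyGraph",
    "precedes",
    "build_synteny_dag",
    "highest_scoring_path",
    "find_synteny",
]


def precedes(a: Alignment, b: Alignment) -> bool:
    """True when ``b`` may follow ``a`` in a collinear chain: ``b`` starts
    strictly after ``a`` ends on both the reference and the query."""
    return b.ref_start > a.ref_end and b.qry_start > a.qry_end


def chain_gap(a: Alignment, b: Alignment) -> int:
    """Total unaligned bases between consecutive chain members, summed over
    both genomes (both terms are >= 0 when ``precedes(a, b)``)."""
    return (b.ref_start - a.ref_end - 1) + (b.qry_start - a.qry_end - 1)


@dataclass
class SyntenyGraph:
    """Collinearity DAG over the forward alignments of one chromosome pair.

    ``nodes`` are sorted by (ref_start, ref_end, id); ``edges`` holds the
    index pairs (i, j) with ``precedes(nodes[i], nodes[j])``.  Node weight is
    the alignment score.
    """

    nodes: list[Alignment]
    edges: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.nodes)


def build_synteny_dag(alignments: list[Alignment]) -> SyntenyGraph:
    """Build the collinearity DAG for the forward alignments of one
    (ref_chr, qry_chr) pair.

    Raises :class:`ContractViolation` on mixed chromosomes or strands.
    """
    if alignments:
        pair = (alignments[0].ref_chr, alignments[0].qry_chr)
        for a in alignments:
            if (a.ref_chr, a.qry_chr) != pair:
                raise ContractViolation("alignments span more than one chromosome pair")
            if a.strand != "+":
                raise ContractViolation("synteny DAG accepts forward alignments only")
    nodes = sorted(alignments, key=lambda a: (a.ref_start, a.ref_end, a.id))
    edges: set[tuple[int, int]] = set()
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if precedes(a, nodes[j]):
                edges.add((i, j))
    return SyntenyGraph(nodes, edges)


def highest_scoring_path(graph: SyntenyGraph) -> list[Alignment]:
    """Maximum-weight chain through the collinearity DAG, by dynamic
    programming over nodes in topological (reference) order.

    Returns the chain as a list ordered along both genomes; empty graph
    gives an empty chain.  Ties are resolved towards smaller total gap, then
    smaller predecessor id.
    """
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        return []
    pred_lists: list[list[int]] = [[] for _ in range(n)]
    for i, j in graph.edges:
        pred_lists[j].append(i)

    score = [0.0] * n  # best chain score ending at i
    gap = [0] * n      # total gap of that chain (tie-break)
    prev = [-1] * n
    for i, node in enumerate(nodes):
        score[i] = node.score
        best_key = None
        for p in sorted(pred_lists[i]):
            key = (score[p], -(gap[p] + chain_gap(nodes[p], node)), -nodes[p].id)
            if best_key is None or key > best_key:
                best_key = key
                prev[i] = p
        if prev[i] >= 0:
            score[i] += score[prev[i]]
            gap[i] = gap[prev[i]] + chain_gap(nodes[prev[i]], node)

    best = max(range(n), key=lambda i: (score[i], -gap[i], -nodes[i].id))
    chain: list[Alignment] = []
    while best >= 0:
        chain.append(nodes[best])
        best = prev[best]
    chain.reverse()
    return chain


def find_synteny(
    alignments: list[Alignment], genomes: GenomePair
) -> tuple[list[Annotation], list[Alignment]]:
    """Label the syntenic backbone and split off all other alignments.

    For each homologous chromosome pair the forward alignments are chained
    and the chain members annotated SYN, one annotation per member.  Every
    other alignment — inverted, off the chain, or between non-homologous
    chromosomes — is returned as the residual set for rearrangement
    identification.  Chromosome pairs are processed independently.
    """
    annotations: list[Annotation] = []
    residual: list[Alignment] = []
    groups = group_by_chrom_pair(alignments)
    for (ref_chr, qry_chr) in sorted(groups):
        bucket = groups[(ref_chr, qry_chr)]
        if not genomes.is_homologous(ref_chr, qry_chr):
            residual.extend(bucket)
            continue
        forward = [a for a in bucket if a.strand == "+"]
        chain = highest_scoring_path(build_synteny_dag(forward))
        chosen = {a.id for a in chain}
        for a in chain:
            annotations.append(
                Annotation(
                    "SYN", a.ref_chr, a.ref_start, a.ref_end,
                    a.qry_chr, a.qry_start, a.qry_end, members=[a],
                )
            )
        residual.extend(a for a in bucket if a.id not in chosen)
    return annotations, residual
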