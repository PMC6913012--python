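"""Deterministic orchestration of the full identification pipeline.

``identify`` runs the steps in order — syntenic path, inversions,
translocations/duplications, annotation blocks, local variants, un-aligned
regions — and reports a per-class summary (bases, % of genome, feature
count) on both genomes.  ``RunConfig`` gathers every tunable threshold with
its documented default and round-trips to a flat key=value text file.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import alignio, inversions, svcalls, tdscan
from .alignio import Alignment, Annotation, GenomePair, VariantCall
from .synteny import find_synteny

__all__ = ["RunConfig", "IdentifyResult", "identify", "summary_table"]

log = logging.getLogger("asmdiff")


@dataclass
class RunConfig:
    """All pipeline thresholds, with their defaults."""

    min_len: int = 0                 # bp: drop shorter alignments on ingest
    min_identity: float = 0.0        # fraction: drop lower-identity alignments
    max_gap: int = tdscan.MAX_GAP
    min_score_ratio: float = tdscan.MIN_SCORE_RATIO
    dup_cov: float = tdscan.DUP_COV
    tandem_gap: int = tdscan.TANDEM_GAP
    overlap_margin: int = inversions.OVERLAP_MARGIN
    exact_limit: int = inversions.EXACT_LIMIT
    max_candidates: int = inversions.MAX_CANDIDATES
    tolerance: int = 150             # bp: breakpoint tolerance in evaluation
    min_notal: int = svcalls.MIN_NOTAL
    seed: int = 1

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                k = k.strip()
                if k not in types:
                    raise ValueError(f"unknown config key {k!r}")
                caster = float if "float" in str(types[k]) else int
                kwargs[k] = caster(v.strip())
        return cls(**kwargs)


@dataclass
class IdentifyResult:
    annotations: list[Annotation]
    blocks: list[svcalls.AnnotationBlock]
    variants: list[VariantCall]
    redundant: list[Alignment]
    summary: pd.DataFrame


def identify(
    alignments: list[Alignment],
    genomes: GenomePair,
    config: RunConfig | None = None,
    call_snps: bool | None = None,
) -> IdentifyResult:
    """Run the complete identification pipeline over a set of alignments.

    ``call_snps`` controls CIGAR-based SNP/small-indel parsing; by default
    it is on exactly when genome sequences and CIGARs are available.
    Raises when SNP calling is requested without sequences.
    """
    cfg = config or RunConfig()
    genomes.check_alignments(alignments)
    n_in = len(alignments)
    alignments = alignio.filter_alignments(alignments, cfg.min_len, cfg.min_identity)
    log.info("input alignments: %d, after length/identity filter: %d", n_in, len(alignments))

    syn, residual = find_synteny(alignments, genomes)
    log.info("syntenic alignments: %d, residual: %d", len(syn), len(residual))

    inv, residual = inversions.find_inversions(
        residual, syn, genomes.qry_sizes, genomes.homolog_map,
        cfg.max_candidates, cfg.overlap_margin, cfg.exact_limit,
    )
    log.info("inversions: %d, residual after step 2a: %d", len(inv), len(residual))

    tds, redundant = tdscan.find_tds(
        residual, syn + inv, genomes,
        cfg.max_gap, cfg.min_score_ratio, cfg.overlap_margin,
        cfg.exact_limit, cfg.dup_cov, cfg.tandem_gap,
    )
    log.info("TD annotations: %d, redundant alignments: %d", len(tds), len(redundant))
    placed = {m.id for ann in syn + inv + tds for m in ann.members}
    if len(placed) + len(redundant) != len(alignments):
        log.warning(
            "record conservation: %d placed + %d redundant != %d filtered input",
            len(placed), len(redundant), len(alignments),
        )

    annotations = syn + inv + tds
    for i, ann in enumerate(annotations):
        ann.id = i
    blocks = svcalls.build_blocks(annotations)

    variants: list[VariantCall] = []
    have_seq = genomes.ref_seq is not None and genomes.qry_seq is not None
    if call_snps is None:
        call_snps = have_seq and any(a.cigar for a in alignments)
    if call_snps and not have_seq:
        raise ValueError("SNP calling requested but genome sequences are missing")
    if call_snps:
        for block in blocks:
            for m in block.members:
                if m.cigar is None:
                    log.warning("alignment %d lacks a cigar; no SNP parsing", m.id)
                    continue
                variants.extend(
                    svcalls.call_small_variants(
                        m, genomes.ref_seq[m.ref_chr], genomes.qry_seq[m.qry_chr],
                        parent=block.id,
                    )
                )
    for block in blocks:
        if len(block.members) > 1:
            variants.extend(svcalls.call_gap_variants(block))
    variants.extend(svcalls.find_unaligned(blocks, genomes, cfg.min_notal))

    return IdentifyResult(
        annotations=annotations,
        blocks=blocks,
        variants=variants,
        redundant=redundant,
        summary=summary_table(blocks, variants, genomes),
    )


_SUMMARY_CLASSES = {
    "Syntenic regions": ("SYN",),
    "Inversions": ("INV",),
    "Translocations": ("TRANS", "INVTR"),
    "Duplications": ("DUP", "INVDP"),
}


def _union_bases(spans: list[tuple[int, int]]) -> int:
    total = 0
    last_end = 0
    for s, e in sorted(spans):
        s = max(s, last_end + 1)
        if e >= s:
            total += e - s + 1
            last_end = max(last_end, e)
    return total


def summary_table(
    blocks: list[svcalls.AnnotationBlock],
    variants: list[VariantCall],
    genomes: GenomePair,
) -> pd.DataFrame:
    """Per-class summary: bases covered, % of genome and feature count, on
    the reference and the query genome."""
    ref_total = sum(genomes.ref_sizes.values())
    qry_total = sum(genomes.qry_sizes.values())
    rows = []
    for label, types in _SUMMARY_CLASSES.items():
        sel = [b for b in blocks if b.type in types]
        ref_bp = sum(
            _union_bases([(b.ref_start, b.ref_end) for b in sel if b.ref_chr == c])
            for c in genomes.ref_sizes
        )
        qry_bp = sum(
            _union_bases([(b.qry_start, b.qry_end) for b in sel if b.qry_chr == c])
            for c in genomes.qry_sizes
        )
        rows.append((label, ref_bp, 100 * ref_bp / ref_total, qry_bp,
                     100 * qry_bp / qry_total, len(sel)))
    notal = [v for v in variants if v.kind == "NOTAL"]
    ref_bp = sum(v.ref_end - v.ref_start + 1 for v in notal if v.ref_chr)
    qry_bp = sum(v.qry_end - v.qry_start + 1 for v in notal if v.qry_chr)
    rows.append(("Un-aligned", ref_bp, 100 * ref_bp / ref_total, qry_bp,
                 100 * qry_bp / qry_total, len(notal)))
    return pd.DataFrame(
        rows, columns=["class", "ref_bp", "ref_pct", "qry_bp", "qry_pct", "count"]
    )
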