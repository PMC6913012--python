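"""Rearranged-genome simulation, truth alignments and evaluation.

The simulator plants inversions, transpositions (within-chromosome moves),
translocations (between-chromosome moves), tandem and distal duplications,
insertions and deletions into a genome, keeping an exact truth record for
every event.  Default event counts follow the benchmark mix of 40
inversions, 436 transpositions, 100 translocations, 100 tandem duplications
(100-1000 bp) and 1241 distal duplications; translocations are 1-5 kb and
the indel preset plants 1000 indels of 1-500 bp.  Sizes without a stated
range default to log-uniform 500 bp - 10 kb.

``truth_alignments`` emits the local alignments an ideal whole-genome
aligner would produce from the simulated pair (identity 1, all-match
CIGARs), so the identification pipeline can be exercised without an
external aligner.  ``evaluate_predictions`` scores predicted annotations
against the truth with the four-category scheme: *identified* (all four
breakpoints hit by one correctly-typed annotation), *indicated* (at least
one breakpoint, correct type), *incorrect* (breakpoints hit but wrongly
typed) and *missed*; breakpoints match within a tolerance (default
±150 bp).  Indels are scored separately by location and size agreement at
5 bp and 100 bp error limits.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignio import Alignment, Annotation, ContractViolation, VariantCall, revcomp

__all__ = [
    "SimConfig",
    "TruthRecord",
    "EvalTable",
    "PlacementError",
    "random_genome",
    "simulate_rearrangements",
    "truth_alignments",
    "evaluate_predictions",
    "evaluate_indels",
    "default_config",
    "indel_config",
]

RELOCATED = ("TRANSPOSITION", "TRANSLOCATION")
DUPLICATED = ("TANDEM_DUP", "DISTAL_DUP")

# truth kind -> acceptable predicted annotation types
MATCHING_TYPES = {
    "INV": {"INV"},
    "TRANSPOSITION": {"TRANS", "INVTR"},
    "TRANSLOCATION": {"TRANS", "INVTR"},
    "TANDEM_DUP": {"DUP", "INVDP"},   # anything duplication-like counts
    "DISTAL_DUP": {"DUP", "INVDP"},
}
REARRANGEMENT_TYPES = {"INV", "TRANS", "INVTR", "DUP", "INVDP"}


class PlacementError(RuntimeError):
    """The genome could not accommodate the requested events."""


@dataclass
class SimConfig:
    """Event counts and size ranges (bp) for one simulated genome."""

    n_inversions: int = 40
    n_transpositions: int = 436
    n_translocations: int = 100
    n_tandem_dups: int = 100
    n_distal_dups: int = 1241
    n_insertions: int = 0
    n_deletions: int = 0
    inversion_size: tuple[int, int] = (500, 10_000)      # log-uniform
    transposition_size: tuple[int, int] = (500, 10_000)  # log-uniform
    translocation_size: tuple[int, int] = (1000, 5000)   # uniform
    tandem_dup_size: tuple[int, int] = (100, 1000)       # uniform
    distal_dup_size: tuple[int, int] = (500, 10_000)     # log-uniform
    indel_size: tuple[int, int] = (1, 500)               # uniform
    max_tries: int = 200


def default_config() -> SimConfig:
    return SimConfig()


def indel_config(n_indels: int = 1000) -> SimConfig:
    half = n_indels // 2
    return SimConfig(
        n_inversions=0, n_transpositions=0, n_translocations=0,
        n_tandem_dups=0, n_distal_dups=0,
        n_insertions=n_indels - half, n_deletions=half,
    )


@dataclass
class TruthRecord:
    """Ground truth for one simulated event.

    ``ref_*`` is the source interval in the original genome (for INS, the
    insertion point as a zero-width anchor).  ``qry_*`` is the destination
    interval in the mutated genome (for DEL, the join position).
    ``insert_after`` is the original-genome position after which relocated /
    copied / inserted material was placed, when applicable.
    """

    kind: str
    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str = ""
    qry_start: int = 0
    qry_end: int = 0
    size: int = 0
    insert_after: tuple[str, int] | None = None

    @property
    def breakpoints_ref(self) -> list[tuple[str, int]]:
        return [(self.ref_chr, self.ref_start), (self.ref_chr, self.ref_end)]

    @property
    def breakpoints_qry(self) -> list[tuple[str, int]]:
        return [(self.qry_chr, self.qry_start), (self.qry_chr, self.qry_end)]


def random_genome(
    n_chroms: int = 1,
    chrom_len: int = 1_000_000,
    gc: float = 0.38,
    seed: int | np.random.Generator | None = None,
) -> dict[str, str]:
    """Generate a random genome with the requested GC content; reproducible
    for a fixed seed."""
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.choice(4, size=chrom_len, p=p)])
        for i in range(n_chroms)
    }


# ---------------------------------------------------------------------------
# Event planning and genome mutation
# ---------------------------------------------------------------------------

@dataclass
class _Event:
    kind: str
    chr: str = ""            # source chromosome ('' for INS)
    start: int = 0
    end: int = 0
    size: int = 0
    insert_chr: str = ""     # destination chromosome, when relocated/copied
    insert_after: int = 0    # insert after this original-genome position
    novel_seq: str = ""      # INS payload


def _sample_size(rng: np.random.Generator, lo: int, hi: int, log: bool) -> int:
    if log:
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return int(rng.integers(lo, hi + 1))


class _IntervalBook:
    """Sorted non-overlapping intervals per chromosome, for rejection tests."""

    def __init__(self) -> None:
        self._by_chr: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, chrom: str, s: int, e: int) -> bool:
        ivs = self._by_chr.get(chrom, [])
        i = bisect_left(ivs, (s, s))
        if i < len(ivs) and ivs[i][0] <= e:
            return True
        return i > 0 and ivs[i - 1][1] >= s

    def add(self, chrom: str, s: int, e: int) -> None:
        insort(self._by_chr.setdefault(chrom, []), (s, e))

    def contains_point_zone(self, chrom: str, p: int) -> bool:
        """True when inserting after ``p`` would split a source interval,
        i.e. p lies in [s-1, e] of some interval."""
        return self.overlaps(chrom, p, p + 1)


def _plan_events(genome: dict[str, str], config: SimConfig, rng: np.random.Generator) -> list[_Event]:
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    book = _IntervalBook()
    points: set[tuple[str, int]] = set()
    points_by_chr: dict[str, list[int]] = {c: [] for c in chroms}
    events: list[_Event] = []

    def pick_chr(exclude: str | None = None) -> str:
        cands = [c for c in chroms if c != exclude]
        if not cands:
            raise PlacementError("translocation requires at least two chromosomes")
        w = np.array([lengths[c] for c in cands], dtype=float)
        return cands[rng.choice(len(cands), p=w / w.sum())]

    def point_in(chrom: str, s: int, e: int) -> bool:
        pts = points_by_chr[chrom]
        i = bisect_left(pts, s)
        return i < len(pts) and pts[i] <= e

    def place_interval(size: int) -> tuple[str, int, int]:
        for _ in range(config.max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            if lengths[chrom] <= size + 2:
                continue
            s = int(rng.integers(2, lengths[chrom] - size))
            e = s + size - 1
            if book.overlaps(chrom, s - 1, e + 1) or point_in(chrom, s - 1, e):
                continue
            book.add(chrom, s, e)
            return chrom, s, e
        raise PlacementError(f"could not place an interval of {size} bp")

    def place_point(chrom: str | None = None, exclude: str | None = None) -> tuple[str, int]:
        for _ in range(config.max_tries):
            if chrom is not None:
                c = chrom
            elif exclude is not None:
                c = pick_chr(exclude)
            else:
                c = chroms[rng.choice(len(chroms), p=weights)]
            p = int(rng.integers(1, lengths[c]))
            if (c, p) in points or book.contains_point_zone(c, p):
                continue
            points.add((c, p))
            insort(points_by_chr[c], p)
            return c, p
        raise PlacementError("could not place an insertion point")

    spec = [
        ("INV", config.n_inversions, config.inversion_size, True),
        ("TRANSPOSITION", config.n_transpositions, config.transposition_size, True),
        ("TRANSLOCATION", config.n_translocations, config.translocation_size, False),
        ("TANDEM_DUP", config.n_tandem_dups, config.tandem_dup_size, False),
        ("DISTAL_DUP", config.n_distal_dups, config.distal_dup_size, True),
        ("DEL", config.n_deletions, config.indel_size, False),
        ("INS", config.n_insertions, config.indel_size, False),
    ]
    for kind, count, (lo, hi), logspace in spec:
        for _ in range(count):
            size = _sample_size(rng, lo, hi, logspace)
            if kind == "INS":
                c, p = place_point()
                seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size)])
                events.append(_Event(kind, chr=c, start=p, end=p, size=size,
                                     insert_chr=c, insert_after=p, novel_seq=seq))
                continue
            chrom, s, e = place_interval(size)
            ev = _Event(kind, chr=chrom, start=s, end=e, size=size)
            if kind == "TRANSPOSITION":
                ev.insert_chr, ev.insert_after = place_point(chrom=chrom)
            elif kind == "TRANSLOCATION":
                ev.insert_chr, ev.insert_after = place_point(exclude=chrom)
            elif kind == "DISTAL_DUP":
                ev.insert_chr, ev.insert_after = place_point()
            events.append(ev)
    return events


@dataclass
class _Piece:
    """One contiguous slice of the mutated genome."""

    kind: str                # plain | inv | moved | copy | novel
    ref_chr: str = ""
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    novel_len: int = 0
    event_idx: int = -1

    @property
    def length(self) -> int:
        return self.novel_len if self.kind == "novel" else self.ref_end - self.ref_start + 1


def _build_pieces(genome: dict[str, str], events: list[_Event]) -> dict[str, list[_Piece]]:
    """Deterministically derive the mutated-genome piece lists from events."""
    by_interval: dict[tuple[str, int, int], tuple[int, _Event]] = {}
    inserts: dict[tuple[str, int], list[tuple[int, _Event]]] = {}
    cuts: dict[str, set[int]] = {c: set() for c in genome}
    for idx, ev in enumerate(events):
        if ev.kind != "INS":
            by_interval[(ev.chr, ev.start, ev.end)] = (idx, ev)
            cuts[ev.chr].update((ev.start - 1, ev.end))
        if ev.insert_chr:
            inserts.setdefault((ev.insert_chr, ev.insert_after), []).append((idx, ev))
            cuts[ev.insert_chr].add(ev.insert_after)

    pieces: dict[str, list[_Piece]] = {}
    for chrom, seq in genome.items():
        L = len(seq)
        bounds = sorted(b for b in cuts[chrom] if 0 < b < L)
        out: list[_Piece] = []
        prev = 0
        for b in bounds + [L]:
            s, e = prev + 1, b
            prev = b
            key = (chrom, s, e)
            hit = by_interval.get(key)
            if hit is None:
                out.append(_Piece("plain", chrom, s, e))
            else:
                idx, ev = hit
                if ev.kind == "DEL":
                    pass
                elif ev.kind == "INV":
                    out.append(_Piece("inv", chrom, s, e, strand="-", event_idx=idx))
                elif ev.kind in RELOCATED:
                    pass  # re-emitted at the insertion point
                elif ev.kind == "TANDEM_DUP":
                    out.append(_Piece("plain", chrom, s, e))
                    out.append(_Piece("copy", chrom, s, e, event_idx=idx))
                elif ev.kind == "DISTAL_DUP":
                    out.append(_Piece("plain", chrom, s, e))
                else:  # pragma: no cover
                    raise AssertionError(ev.kind)
            for idx, ev in inserts.get((chrom, e), []):
                if ev.kind in RELOCATED:
                    out.append(_Piece("moved", ev.chr, ev.start, ev.end, event_idx=idx))
                elif ev.kind == "DISTAL_DUP":
                    out.append(_Piece("copy", ev.chr, ev.start, ev.end, event_idx=idx))
                elif ev.kind == "INS":
                    out.append(_Piece("novel", novel_len=ev.size, event_idx=idx))
        pieces[chrom] = out
    return pieces


def simulate_rearrangements(
    genome: dict[str, str],
    config: SimConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant the configured events into ``genome``.

    Source intervals never overlap each other and insertion points never
    fall inside a source interval, so every event's breakpoints are exact.
    Returns the mutated genome (same chromosome names) and the truth
    records.  Byte-for-byte reproducible for a fixed seed.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = _plan_events(genome, config, rng)
    pieces = _build_pieces(genome, events)

    mutated: dict[str, str] = {}
    truth: dict[int, TruthRecord] = {
        i: TruthRecord(ev.kind, ev.chr, ev.start, ev.end, size=ev.size,
                       insert_after=(ev.insert_chr, ev.insert_after) if ev.insert_chr else None)
        for i, ev in enumerate(events)
    }
    for chrom in sorted(genome):
        parts: list[str] = []
        pos = 0
        prev_deleted_event: int | None = None
        for pc in pieces[chrom]:
            if pc.kind == "novel":
                seq = events[pc.event_idx].novel_seq
            else:
                seq = genome[pc.ref_chr][pc.ref_start - 1 : pc.ref_end]
                if pc.strand == "-":
                    seq = revcomp(seq)
            start, end = pos + 1, pos + len(seq)
            if pc.event_idx >= 0 and pc.kind in ("inv", "moved", "copy", "novel"):
                rec = truth[pc.event_idx]
                rec.qry_chr, rec.qry_start, rec.qry_end = chrom, start, end
            parts.append(seq)
            pos = end
        mutated[chrom] = "".join(parts)
    # deletion join positions in the mutated frame
    for i, ev in enumerate(events):
        if ev.kind == "DEL":
            rec = truth[i]
            join = _ref_to_mut(pieces, ev.chr, ev.start - 1)
            rec.qry_chr, rec.qry_start, rec.qry_end = ev.chr, join, join
    return mutated, [truth[i] for i in range(len(events))]


def _ref_to_mut(pieces: dict[str, list[_Piece]], chrom: str, ref_pos: int) -> int:
    """Mutated coordinate of original base (chrom, ref_pos) via the plain
    piece containing it; 0 when the base was removed."""
    pos = 0
    for pc in pieces[chrom]:
        if (
            pc.kind in ("plain", "inv")
            and pc.ref_chr == chrom
            and pc.ref_start <= ref_pos <= pc.ref_end
        ):
            if pc.strand == "+":
                return pos + (ref_pos - pc.ref_start + 1)
            return pos + (pc.ref_end - ref_pos + 1)
        pos += pc.length
    return 0


def truth_alignments(
    truth: list[TruthRecord],
    genome: dict[str, str],
    mutated: dict[str, str],
) -> list[Alignment]:
    """Emit the exact local alignments an ideal aligner would produce for
    the simulated pair: collinear segments between events, inverted
    alignments for inversions, relocated alignments for transpositions and
    translocations, and double alignments for duplications.  Identity is 1
    and CIGARs are all-match; insertions and deletions split alignments."""
    events = [
        _Event(
            t.kind, chr=t.ref_chr, start=t.ref_start, end=t.ref_end, size=t.size,
            insert_chr=t.insert_after[0] if t.insert_after else "",
            insert_after=t.insert_after[1] if t.insert_after else 0,
        )
        for t in truth
    ]
    pieces = _build_pieces(genome, events)
    raw: list[Alignment] = []
    for chrom in sorted(genome):
        pos = 0
        merged: list[_Piece] = []
        for pc in pieces[chrom]:
            if (
                merged
                and pc.kind == "plain"
                and merged[-1].kind == "plain"
                and merged[-1].ref_chr == pc.ref_chr
                and merged[-1].ref_end + 1 == pc.ref_start
            ):
                merged[-1] = replace(merged[-1], ref_end=pc.ref_end)
            else:
                merged.append(replace(pc))
        for pc in merged:
            start, end = pos + 1, pos + pc.length
            pos = end
            if pc.kind == "novel":
                continue
            raw.append(
                Alignment(
                    pc.ref_chr, pc.ref_start, pc.ref_end,
                    chrom, start, end, pc.strand, 1.0,
                    cigar=f"{pc.length}=",
                )
            )
        if pos != len(mutated[chrom]):
            raise ContractViolation(
                f"truth inconsistent with mutated genome on {chrom}: "
                f"{pos} vs {len(mutated[chrom])}"
            )
    raw.sort(key=lambda a: (a.ref_chr, a.ref_start, a.ref_end, a.qry_chr, a.qry_start))
    return [a.with_id(i) for i, a in enumerate(raw)]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

CATEGORIES = ("identified", "indicated", "incorrect", "missed")


@dataclass
class EvalTable:
    """Four-category evaluation counts per rearrangement kind."""

    counts: dict[str, Counter] = field(default_factory=dict)

    def rate(self, kind: str, category: str) -> float:
        total = sum(self.counts.get(kind, Counter()).values())
        if total == 0:
            return float("nan")
        return self.counts[kind][category] / total

    def to_frame(self) -> pd.DataFrame:
        rows = {
            kind: {c: self.counts[kind][c] for c in CATEGORIES}
            for kind in sorted(self.counts)
        }
        return pd.DataFrame(rows).T.fillna(0).astype(int)


def _bp_match(bp: tuple[str, int], chrom: str, positions: tuple[int, ...], tol: int) -> bool:
    return bp[0] == chrom and any(abs(bp[1] - p) <= tol for p in positions)


def _match_annotation(rec: TruthRecord, ann: Annotation, tol: int) -> tuple[bool, bool]:
    """(all four breakpoints match, at least one matches) for one annotation."""
    ref_hits = [
        _bp_match(bp, ann.ref_chr, (ann.ref_start, ann.ref_end), tol)
        for bp in rec.breakpoints_ref
    ]
    qry_hits = [
        _bp_match(bp, ann.qry_chr, (ann.qry_start, ann.qry_end), tol)
        for bp in rec.breakpoints_qry
    ]
    full = (
        abs(ann.ref_start - rec.ref_start) <= tol
        and abs(ann.ref_end - rec.ref_end) <= tol
        and ann.ref_chr == rec.ref_chr
        and abs(ann.qry_start - rec.qry_start) <= tol
        and abs(ann.qry_end - rec.qry_end) <= tol
        and ann.qry_chr == rec.qry_chr
    )
    return full, any(ref_hits) or any(qry_hits)


def evaluate_predictions(
    predictions: list[Annotation],
    truth: list[TruthRecord],
    tolerance: int = 150,
) -> EvalTable:
    """Score predicted rearrangement annotations against the truth records
    with the four-category scheme.  Indel truth records are ignored here
    (see :func:`evaluate_indels`)."""
    rearr = [p for p in predictions if p.type in REARRANGEMENT_TYPES]
    table = EvalTable()
    for rec in truth:
        if rec.kind not in MATCHING_TYPES:
            continue
        good_types = MATCHING_TYPES[rec.kind]
        category = "missed"
        partial_correct = partial_any = False
        for ann in rearr:
            full, partial = _match_annotation(rec, ann, tolerance)
            if ann.type in good_types:
                if full:
                    category = "identified"
                    break
                partial_correct = partial_correct or partial
            else:
                partial_any = partial_any or partial
        if category != "identified":
            if partial_correct:
                category = "indicated"
            elif partial_any:
                category = "incorrect"
        table.counts.setdefault(rec.kind, Counter())[category] += 1
    return table


def evaluate_indels(
    predicted: list[VariantCall],
    truth: list[TruthRecord],
    tolerances: tuple[int, ...] = (5, 100),
) -> dict[int, tuple[float, float]]:
    """Sensitivity and precision of indel calls at each error limit.

    A predicted indel matches a truth indel of the same type when both the
    position error and the size error are within the limit; matching is
    greedy one-to-one by position distance.  With zero predictions the
    precision is reported as 1.0 by convention.
    """
    truth_indels = [t for t in truth if t.kind in ("INS", "DEL")]
    pred = [
        (v.kind, v.ref_chr, v.ref_start,
         (v.qry_end - v.qry_start + 1) if v.kind == "INS" else (v.ref_end - v.ref_start + 1))
        for v in predicted
        if v.kind in ("INS", "DEL")
    ]
    out: dict[int, tuple[float, float]] = {}
    for tol in tolerances:
        pairs: list[tuple[int, int, int]] = []
        for ti, t in enumerate(truth_indels):
            t_pos = t.ref_start
            for pi, (kind, chrom, pos, size) in enumerate(pred):
                if kind != t.kind or chrom != t.ref_chr:
                    continue
                if abs(pos - t_pos) <= tol and abs(size - t.size) <= tol:
                    pairs.append((abs(pos - t_pos), ti, pi))
        pairs.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for _, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
        sens = len(used_t) / len(truth_indels) if truth_indels else float("nan")
        prec = len(used_p) / len(pred) if pred else 1.0
        out[tol] = (sens, prec)
    return out
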