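"""Reading, normalising and writing whole-genome-alignment records.

A pairwise whole-genome alignment (WGA) is a set of local alignments, each
connecting an interval on the reference assembly to an interval on the query
assembly.  Two on-disk dialects are supported:

* the MUMmer ``show-coords -THrd`` tab-delimited table, in which a minus-strand
  alignment is encoded by ``qry_start > qry_end``;
* PAF (minimap2 and friends), 0-based half-open, with an explicit strand
  column and an optional ``cg:Z`` CIGAR tag.

Internally every coordinate is 1-based inclusive on both genomes and
``start <= end`` always holds; orientation is carried by a strand flag, never
by reversed coordinates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Alignment",
    "Annotation",
    "VariantCall",
    "GenomePair",
    "ParseError",
    "ContractViolation",
    "read_alignments",
    "write_alignments",
    "filter_alignments",
    "group_by_chrom_pair",
    "read_fasta",
    "write_fasta",
    "read_homolog_map",
    "write_annotation_tsv",
    "write_vcf",
]


class ParseError(ValueError):
    """Raised for malformed alignment records; carries the 1-based line number."""


class ContractViolation(ValueError):
    """An operation was handed inputs that violate its preconditions."""


@dataclass(frozen=True)
class Alignment:
    """One local alignment between the reference and query genomes.

    Coordinates are 1-based inclusive on both genomes with ``start <= end``;
    ``strand`` is ``'+'`` or ``'-'``.  ``identity`` is the fraction of
    matching bases in ``(0, 1]``.  ``cigar`` uses standard operation letters
    (``=XMID``) and is ``None`` when the source format did not provide one.
    """

    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str
    qry_start: int
    qry_end: int
    strand: str
    identity: float
    cigar: str | None = None
    id: int = -1

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end or self.qry_start > self.qry_end:
            raise ContractViolation(
                f"alignment {self.id}: start must not exceed end "
                f"({self.ref_start}-{self.ref_end}, {self.qry_start}-{self.qry_end})"
            )
        if self.strand not in "+-":
            raise ContractViolation(f"invalid strand {self.strand!r}")
        if not 0.0 < self.identity <= 1.0:
            raise ContractViolation(f"identity {self.identity} outside (0, 1]")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start + 1

    @property
    def score(self) -> float:
        """Alignment score: identity times the mean aligned length."""
        return self.identity * (self.ref_len + self.qry_len) / 2.0

    def with_id(self, new_id: int) -> "Alignment":
        return replace(self, id=new_id)


@dataclass
class Annotation:
    """An alignment or region labelled with a structural class.

    ``type`` is one of SYN (syntenic), INV (inversion), TRANS (translocation /
    transposition), INVTR (inverted translocation), DUP / INVDP (distal or
    tandem duplication, plain or inverted) and NOTAL (un-aligned region).
    ``copy_status`` distinguishes the original copy from the extra copy of a
    duplication ('origin' / 'copy'), '-' otherwise.
    """

    type: str
    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str
    qry_start: int
    qry_end: int
    members: list[Alignment] = field(default_factory=list)
    copy_status: str = "-"
    tandem: bool = False
    id: int = -1
    parent_id: int = -1

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start + 1


@dataclass
class VariantCall:
    """A local sequence difference anchored in both genomes.

    ``kind`` is one of SNP, INS, DEL, HDR (highly divergent region), CPG
    (copy gain in query), CPL (copy loss in query), TDM (tandem-repeat
    overlap) or NOTAL.  Alleles are sequences when genome sequences were
    available, otherwise ``'-'``.
    """

    kind: str
    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str
    qry_start: int
    qry_end: int
    ref_allele: str = "-"
    qry_allele: str = "-"
    parent: int = -1


@dataclass
class GenomePair:
    """Chromosome sizes, optional sequences and the homologous-chromosome map.

    ``homolog_map`` maps each reference chromosome to its query homolog; by
    default chromosomes pair by identical name.  The map must be injective.
    """

    ref_sizes: dict[str, int]
    qry_sizes: dict[str, int]
    ref_seq: dict[str, str] | None = None
    qry_seq: dict[str, str] | None = None
    homolog_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.homolog_map is None:
            self.homolog_map = {c: c for c in self.ref_sizes if c in self.qry_sizes}
        vals = list(self.homolog_map.values())
        if len(vals) != len(set(vals)):
            raise ContractViolation("homolog_map is not injective")

    @classmethod
    def from_sequences(
        cls,
        ref_seq: Mapping[str, str],
        qry_seq: Mapping[str, str],
        homolog_map: dict[str, str] | None = None,
    ) -> "GenomePair":
        return cls(
            ref_sizes={c: len(s) for c, s in ref_seq.items()},
            qry_sizes={c: len(s) for c, s in qry_seq.items()},
            ref_seq=dict(ref_seq),
            qry_seq=dict(qry_seq),
            homolog_map=homolog_map,
        )

    def is_homologous(self, ref_chr: str, qry_chr: str) -> bool:
        return self.homolog_map.get(ref_chr) == qry_chr

    def check_alignments(self, alignments: Iterable[Alignment]) -> None:
        for a in alignments:
            if a.ref_chr not in self.ref_sizes:
                raise ContractViolation(f"unknown reference chromosome {a.ref_chr!r}")
            if a.qry_chr not in self.qry_sizes:
                raise ContractViolation(f"unknown query chromosome {a.qry_chr!r}")


# ---------------------------------------------------------------------------
# Alignment-coordinate input
# ---------------------------------------------------------------------------

_COORDS_HEADERS = ("NUCMER", "PROMER", "/", "[", "=")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _detect_format(fields: Sequence[str]) -> str:
    # PAF carries the strand in column 5; show-coords has a number there.
    if len(fields) >= 12 and fields[4] in "+-":
        return "paf"
    return "coords"


def _parse_coords_line(fields: Sequence[str], lineno: int, next_id: int) -> Alignment:
    # show-coords -THrd: S1 E1 S2 E2 LEN1 LEN2 %IDY [FRM FRM] REF QRY
    if len(fields) < 9:
        raise ParseError(f"line {lineno}: expected >=9 tab-separated columns, got {len(fields)}")
    try:
        rs, re_, qs, qe = (int(fields[i]) for i in range(4))
        idy = float(fields[6])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    ref_chr, qry_chr = fields[-2], fields[-1]
    if not 0.0 < idy <= 100.0:
        raise ParseError(f"line {lineno}: identity {idy} outside (0, 100]")
    strand = "+"
    if qs > qe:
        strand = "-"
        qs, qe = qe, qs
    if rs > re_:
        raise ParseError(f"line {lineno}: reference interval reversed")
    return Alignment(ref_chr, rs, re_, qry_chr, qs, qe, strand, idy / 100.0, None, next_id)


def _parse_paf_line(fields: Sequence[str], lineno: int, next_id: int) -> Alignment:
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: PAF requires >=12 columns")
    try:
        qname = fields[0]
        qs, qe = int(fields[2]), int(fields[3])
        strand = fields[4]
        tname = fields[5]
        ts, te = int(fields[7]), int(fields[8])
        nmatch, alen = int(fields[9]), int(fields[10])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if strand not in "+-":
        raise ParseError(f"line {lineno}: bad strand {strand!r}")
    if alen <= 0 or not 0 < nmatch <= alen:
        raise ParseError(f"line {lineno}: bad match/block lengths {nmatch}/{alen}")
    cigar = None
    for tag in fields[12:]:
        if tag.startswith("cg:Z:"):
            cigar = tag[5:]
    # 0-based half-open -> 1-based inclusive
    return Alignment(
        tname, ts + 1, te, qname, qs + 1, qe, strand, nmatch / alen, cigar, next_id
    )


def read_alignments(path: str | Path, format: str | None = None) -> list[Alignment]:
    """Read local alignments from a show-coords table or a PAF file.

    ``format`` is ``'coords'``, ``'paf'`` or ``None`` (auto-detect from the
    column signature of the first record).  Records get sequential ids in
    file order starting at 0.
    """
    out: list[Alignment] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_COORDS_HEADERS):
                continue
            fields = line.split("\t")
            if len(fields) < 9:  # space-separated header remnants
                if format in (None, "coords") and not line[0].isdigit():
                    continue
                raise ParseError(f"line {lineno}: too few columns")
            fmt = format or _detect_format(fields)
            if fmt == "paf":
                out.append(_parse_paf_line(fields, lineno, len(out)))
            elif fmt == "coords":
                out.append(_parse_coords_line(fields, lineno, len(out)))
            else:
                raise ValueError(f"unknown alignment format {fmt!r}")
    return out


def write_alignments(alignments: Iterable[Alignment], path: str | Path, format: str = "coords") -> None:
    """Write alignments back out in the coords or PAF dialect (lossless round-trip
    up to record ids; PAF query/target lengths are taken from the intervals)."""
    with open(path, "w") as fh:
        for a in alignments:
            if format == "coords":
                qs, qe = (a.qry_end, a.qry_start) if a.strand == "-" else (a.qry_start, a.qry_end)
                fh.write(
                    f"{a.ref_start}\t{a.ref_end}\t{qs}\t{qe}\t{a.ref_len}\t{a.qry_len}\t"
                    f"{a.identity * 100:.4f}\t{a.ref_chr}\t{a.qry_chr}\n"
                )
            elif format == "paf":
                nmatch = max(1, round(a.identity * max(a.ref_len, a.qry_len)))
                fields = [
                    a.qry_chr, str(a.qry_end), str(a.qry_start - 1), str(a.qry_end),
                    a.strand,
                    a.ref_chr, str(a.ref_end), str(a.ref_start - 1), str(a.ref_end),
                    str(nmatch), str(max(a.ref_len, a.qry_len)), "60",
                ]
                if a.cigar:
                    fields.append(f"cg:Z:{a.cigar}")
                fh.write("\t".join(fields) + "\n")
            else:
                raise ValueError(f"unknown alignment format {format!r}")


def filter_alignments(
    alignments: Iterable[Alignment],
    min_len: int = 0,
    min_identity: float = 0.0,
) -> list[Alignment]:
    """Drop alignments shorter than ``min_len`` (on either genome) or below
    ``min_identity``.  Inter-chromosomal and inverted alignments are retained:
    routing them happens downstream."""
    if min_len < 0 or min_identity < 0:
        raise ContractViolation("thresholds must be >= 0")
    return [
        a
        for a in alignments
        if min(a.ref_len, a.qry_len) >= min_len and a.identity >= min_identity
    ]


def group_by_chrom_pair(alignments: Iterable[Alignment]) -> dict[tuple[str, str], list[Alignment]]:
    groups: dict[tuple[str, str], list[Alignment]] = {}
    for a in alignments:
        groups.setdefault((a.ref_chr, a.qry_chr), []).append(a)
    return groups


# ---------------------------------------------------------------------------
# FASTA and auxiliary tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (optionally gzipped) FASTA file into a name -> sequence dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_homolog_map(path: str | Path) -> dict[str, str]:
    """Two-column mapping file: reference chromosome <tab> query chromosome."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected two columns")
            out[parts[0]] = parts[1]
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "ref_chr", "ref_start", "ref_end", "ref_seq", "qry_seq",
    "qry_chr", "qry_start", "qry_end", "unique_id", "parent_id",
    "annotation_type", "copy_status",
]


def write_annotation_tsv(
    annotations: Iterable[Annotation],
    variants: Iterable[VariantCall],
    path: str | Path,
    genomes: GenomePair | None = None,
) -> None:
    """Write the combined annotation table: one row per structural annotation
    followed by one row per local variant, ``'-'`` marking absent fields."""

    def seqs_for(chrom: str, start: int, end: int, which: str) -> str:
        if genomes is None:
            return "-"
        book = genomes.ref_seq if which == "ref" else genomes.qry_seq
        if not book or chrom not in book or end - start > 10_000:
            return "-"
        return book[chrom][start - 1 : end]

    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for ann in annotations:
            row = [
                ann.ref_chr if ann.ref_chr else "-",
                str(ann.ref_start) if ann.ref_chr else "-",
                str(ann.ref_end) if ann.ref_chr else "-",
                "-",
                "-",
                ann.qry_chr if ann.qry_chr else "-",
                str(ann.qry_start) if ann.qry_chr else "-",
                str(ann.qry_end) if ann.qry_chr else "-",
                str(ann.id),
                str(ann.parent_id) if ann.parent_id >= 0 else "-",
                ann.type + ("_TANDEM" if ann.tandem else ""),
                ann.copy_status,
            ]
            fh.write("\t".join(row) + "\n")
        for v in variants:
            row = [
                v.ref_chr or "-",
                str(v.ref_start) if v.ref_chr else "-",
                str(v.ref_end) if v.ref_chr else "-",
                v.ref_allele,
                v.qry_allele,
                v.qry_chr or "-",
                str(v.qry_start) if v.qry_chr else "-",
                str(v.qry_end) if v.qry_chr else "-",
                "-",
                str(v.parent) if v.parent >= 0 else "-",
                v.kind,
                "-",
            ]
            fh.write("\t".join(row) + "\n")


_VCF_SVTYPES = {"INS": "INS", "DEL": "DEL", "HDR": "HDR", "CPG": "CNV",
                "CPL": "CNV", "TDM": "TDM", "NOTAL": "NOTAL"}


def write_vcf(
    variants: Iterable[VariantCall],
    path: str | Path,
    genomes: GenomePair | None = None,
    sample_name: str = "query",
) -> None:
    """Write local variants as VCF 4.2 against the reference genome.

    SNPs get literal REF/ALT alleles.  Everything else is written as a
    symbolic allele with END, SVTYPE and SVLEN INFO keys; query-side
    coordinates are carried in QCHR/QSTART/QEND.
    """
    variants = [v for v in variants if v.ref_chr]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length difference">\n')
        fh.write('##INFO=<ID=QCHR,Number=1,Type=String,Description="Query chromosome">\n')
        fh.write('##INFO=<ID=QSTART,Number=1,Type=Integer,Description="Query start">\n')
        fh.write('##INFO=<ID=QEND,Number=1,Type=Integer,Description="Query end">\n')
        if genomes is not None:
            for chrom, size in genomes.ref_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(sorted(variants, key=lambda v: (v.ref_chr, v.ref_start))):
            if v.kind == "SNP":
                fh.write(
                    f"{v.ref_chr}\t{v.ref_start}\t.\t{v.ref_allele}\t{v.qry_allele}"
                    f"\t.\tPASS\t.\n"
                )
                continue
            svtype = _VCF_SVTYPES.get(v.kind, v.kind)
            if v.kind == "INS":
                svlen = v.qry_end - v.qry_start + 1
            elif v.kind == "DEL":
                svlen = -(v.ref_end - v.ref_start + 1)
            else:
                svlen = (v.qry_end - v.qry_start + 1) - (v.ref_end - v.ref_start + 1)
            info = f"END={v.ref_end};SVTYPE={svtype};SVLEN={svlen}"
            if v.qry_chr:
                info += f";QCHR={v.qry_chr};QSTART={v.qry_start};QEND={v.qry_end}"
            ref_allele = v.ref_allele if v.ref_allele not in ("-", "") else "N"
            fh.write(f"{v.ref_chr}\t{v.ref_start}\t.\t{ref_allele[:1]}\t<{svtype}>\t.\tPASS\t{info}\n")
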