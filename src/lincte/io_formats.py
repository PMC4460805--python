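"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are normalized at this boundary to a single internal
convention: 0-based, half-open, with strand one of ``+``, ``-`` or ``.``.
RepeatMasker ``.out`` files (1-based inclusive, ``C`` for the minus strand)
and MAF query lines (strand-relative starts) are converted on read and
re-converted on write, so nothing downstream ever sees another convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

__all__ = [
    "GenomicInterval",
    "TEClass",
    "TEAnnotation",
    "GeneModel",
    "AlignmentBlock",
    "ParseError",
    "classify_repeat_family",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "parse_bed12",
    "write_bed12",
    "parse_maf",
    "write_maf",
    "read_fasta",
    "write_fasta",
    "write_report_tsv",
    "format_number",
]


class ParseError(ValueError):
    """A malformed record in an input file; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic segment in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class TEClass(Enum):
    """Major transposable-element classes plus the non-TE repeat bucket."""

    LINE = "LINE"
    SINE = "SINE"
    LTR = "LTR"
    DNA = "DNA"
    OTHER = "OTHER"
    NON_TE = "NON_TE"


#: RepeatMasker families that are repeats but not transposable elements.
#: These are excluded from every TES total (switchable via ``include_non_te``
#: on the coverage functions).
NON_TE_FAMILIES = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "Satellite",
        "rRNA",
        "tRNA",
        "snRNA",
        "srpRNA",
        "scRNA",
        "Unknown",
    }
)

_TE_PREFIXES = {"LINE", "SINE", "LTR", "DNA"}


def classify_repeat_family(class_family: str) -> TEClass:
    """Map a RepeatMasker class/family string to a :class:`TEClass`.

    The prefix before ``/`` decides: LINE/SINE/LTR/DNA map to themselves,
    simple repeats and other non-TE annotation map to ``NON_TE``, and anything
    else (e.g. ``RC/Helitron``, ``Retroposon/SVA``) to ``OTHER``.
    """
    prefix = class_family.split("/", 1)[0]
    if prefix in _TE_PREFIXES:
        return TEClass[prefix]
    if prefix in NON_TE_FAMILIES:
        return TEClass.NON_TE
    return TEClass.OTHER


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker record, with its class/family resolved to a TEClass."""

    interval: GenomicInterval
    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    repeat_name: str
    class_family: str
    te_id: int

    @property
    def te_class(self) -> TEClass:
        return classify_repeat_family(self.class_family)


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered chain of exons on one strand of one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chrom")
            if ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block; both starts on the + strand of each genome."""

    ref_chrom: str
    ref_start: int
    ref_text: str
    query_chrom: str
    query_start: int
    query_strand: str
    query_text: str

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.query_text):
            raise ParseError(
                f"alignment block at {self.ref_chrom}:{self.ref_start}: "
                "gapped texts have unequal length"
            )

    @property
    def columns(self) -> int:
        return len(self.ref_text)

    @property
    def ref_span(self) -> int:
        return sum(1 for c in self.ref_text if c != "-")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence  begin    end          (left)   repeat"
    "      class/family      begin  end    (left)   ID\n"
    "\n"
)


def parse_repeatmasker_out(stream: TextIO | str) -> list[TEAnnotation]:
    """Parse RepeatMasker ``.out`` text into :class:`TEAnnotation` records.

    Coordinates are converted from 1-based inclusive to 0-based half-open
    and the ``C`` strand code to ``-``. Records keep file order; ``te_id``
    is the 0-based ordinal within the file.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[TEAnnotation] = []
    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        first = stripped.split(None, 1)[0]
        if first in ("SW", "score"):  # the two header lines
            continue
        fields = stripped.split()
        if len(fields) < 11:
            raise ParseError(f"line {lineno}: short record ({len(fields)} fields)")
        try:
            sw = int(fields[0])
            div, dele, ins = (float(fields[i]) for i in (1, 2, 3))
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if begin > end:
            raise ParseError(f"line {lineno}: begin {begin} > end {end}")
        strand_code = fields[8]
        strand = "-" if strand_code == "C" else "+"
        out.append(
            TEAnnotation(
                interval=GenomicInterval(chrom, begin - 1, end, strand),
                sw_score=sw,
                pct_div=div,
                pct_del=dele,
                pct_ins=ins,
                repeat_name=fields[9],
                class_family=fields[10],
                te_id=len(out),
            )
        )
    return out


def write_repeatmasker_out(tes: Sequence[TEAnnotation], path_or_stream) -> None:
    """Write TE annotations back out in the RepeatMasker ``.out`` dialect."""

    def _emit(fh: TextIO) -> None:
        fh.write(_RM_HEADER)
        for te in tes:
            iv = te.interval
            strand = "C" if iv.strand == "-" else "+"
            L = len(iv)
            fh.write(
                f"{te.sw_score:5d} {te.pct_div:5.1f} {te.pct_del:4.1f} "
                f"{te.pct_ins:4.1f}  {iv.chrom}  {iv.start + 1} {iv.end} "
                f"(0) {strand}  {te.repeat_name}  {te.class_family}  "
                f"1 {L} (0) {te.te_id}\n"
            )

    if hasattr(path_or_stream, "write"):
        _emit(path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------


def parse_bed12(stream: TextIO | str) -> list[GeneModel]:
    """Parse 12-column BED into gene models (blocks become exons)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genes: list[GeneModel] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ParseError(f"line {lineno}: expected 12 BED columns, got {len(f)}")
        try:
            chrom = f[0]
            chrom_start = int(f[1])
            name = f[3]
            strand = f[5]
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if len(sizes) != block_count or len(starts) != block_count:
            raise ParseError(
                f"line {lineno}: blockCount {block_count} does not match "
                f"{len(sizes)} sizes / {len(starts)} starts"
            )
        exons = tuple(
            GenomicInterval(chrom, chrom_start + s, chrom_start + s + L, strand)
            for s, L in zip(starts, sizes)
        )
        try:
            genes.append(GeneModel(name, chrom, strand, exons))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return genes


def write_bed12(genes: Sequence[GeneModel], path_or_stream) -> None:
    def _emit(fh: TextIO) -> None:
        for g in genes:
            start = g.exons[0].start
            end = g.exons[-1].end
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - start) for e in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )

    if hasattr(path_or_stream, "write"):
        _emit(path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# MAF (pairwise usage: only the first two s-lines of each block are kept)
# ---------------------------------------------------------------------------


def parse_maf(stream: TextIO | str) -> list[AlignmentBlock]:
    """Parse MAF alignment text into pairwise :class:`AlignmentBlock` objects.

    The first ``s`` line of a block is the reference, the second the query;
    further rows are ignored. A query on the ``-`` strand has its start
    re-expressed on the + strand as ``srcSize - start - size``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    blocks: list[AlignmentBlock] = []
    current: list[tuple[str, int, int, str, int, str]] = []
    in_block = False

    def _flush(lineno: int) -> None:
        nonlocal current
        if not in_block:
            return
        if len(current) < 2:
            raise ParseError(
                f"line {lineno}: alignment block has fewer than two s-lines"
            )
        (r_src, r_start, _r_size, r_strand, _r_tot, r_text) = current[0]
        (q_src, q_start, q_size, q_strand, q_tot, q_text) = current[1]
        if len(r_text) != len(q_text):
            raise ParseError(f"line {lineno}: unequal gapped-text lengths")
        if r_strand != "+":
            raise ParseError(f"line {lineno}: reference s-line must be + strand")
        if q_strand == "-":
            q_plus_start = q_tot - q_start - q_size
        else:
            q_plus_start = q_start
        blocks.append(
            AlignmentBlock(
                ref_chrom=r_src,
                ref_start=r_start,
                ref_text=r_text,
                query_chrom=q_src,
                query_start=q_plus_start,
                query_strand=q_strand,
                query_text=q_text,
            )
        )
        current = []

    lineno = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if line.startswith("a"):
            _flush(lineno)
            in_block = True
            current = []
        elif line.startswith("s "):
            f = line.split()
            if len(f) != 7:
                raise ParseError(f"line {lineno}: malformed s-line")
            try:
                current.append(
                    (f[1], int(f[2]), int(f[3]), f[4], int(f[5]), f[6].upper())
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    _flush(lineno + 1)
    return blocks


def write_maf(blocks: Sequence[AlignmentBlock], path_or_stream,
              src_sizes: dict[str, int] | None = None) -> None:
    """Write pairwise blocks as MAF (+ strand for both rows)."""
    src_sizes = src_sizes or {}

    def _emit(fh: TextIO) -> None:
        fh.write("##maf version=1\n")
        for b in blocks:
            q_span = sum(1 for c in b.query_text if c != "-")
            r_tot = src_sizes.get(b.ref_chrom, b.ref_end)
            q_tot = src_sizes.get(b.query_chrom, b.query_start + q_span)
            fh.write("a score=0.0\n")
            fh.write(
                f"s {b.ref_chrom} {b.ref_start} {b.ref_span} + {r_tot} {b.ref_text}\n"
            )
            fh.write(
                f"s {b.query_chrom} {b.query_start} {q_span} "
                f"{b.query_strand} {q_tot} {b.query_text}\n\n"
            )

    if hasattr(path_or_stream, "write"):
        _emit(path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# FASTA and TSV reports
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{name: sequence}`` mapping."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def format_number(x) -> str:
    """Fixed 6-significant-digit formatting for numeric report cells."""
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, int):
        return str(x)
    if isinstance(x, float):
        if x != x:  # NaN → explicit missing marker
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_report_tsv(table: Iterable[Sequence], path_or_stream,
                     header: Sequence[str] | None = None) -> None:
    """Write a rectangular table as UTF-8 TSV with deterministic formatting.

    ``table`` may be a pandas DataFrame (header taken from its columns) or an
    iterable of rows with an explicit ``header``.
    """
    try:
        import pandas as pd

        if isinstance(table, pd.DataFrame):
            header = list(table.columns)
            table = table.itertuples(index=False)
    except ImportError:  # pragma: no cover
        pass
    if header is None:
        raise ValueError("header required for non-DataFrame tables")

    def _emit(fh: TextIO) -> None:
        fh.write("\t".join(str(h) for h in header) + "\n")
        for row in table:
            fh.write("\t".join(format_number(c) for c in row) + "\n")

    if hasattr(path_or_stream, "write"):
        _emit(path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            _emit(fh)
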