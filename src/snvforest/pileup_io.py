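"""Parsing of SAMtools mpileup lines into per-read observations.

The expected dialect carries, per line, eight tab-separated columns:

    CHROM  POS  REF  DEPTH  BASES  BASE-QUALS  MAP-QUALS  READ-POSITIONS

i.e. mpileup run with per-base mapping quality (``-s`` / ``--output-MQ``) and
within-read base position output (``-O`` / ``--output-BP``).  BASE-QUALS and
MAP-QUALS are ASCII-33 offset phred strings with one character per read;
READ-POSITIONS is a comma-separated list of 1-based within-read offsets.

The base-column grammar is consumed in full: read-start markers (``^`` plus a
mapping-quality character), read-end markers (``$``), indel segments
(``+N<seq>``/``-N<seq>``), deletion placeholders (``*``) and reference skips
(``<``/``>``).  Deletion placeholders, reference skips and ambiguous ``N``
bases occupy a quality slot but yield no observation; indels are attached to
the preceding base and never contribute an SNV allele.

Coordinates are 1-based throughout, matching mpileup and VCF.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_SIMPLE = frozenset(".,ACGTacgt")
_SPECIAL = frozenset("^$+-*<>Nn")


class PileupParseError(ValueError):
    """Raised for malformed mpileup input; carries line/column context."""

    def __init__(self, message: str, line_number: int | None = None, column: int | None = None):
        loc = []
        if line_number is not None:
            loc.append(f"line {line_number}")
        if column is not None:
            loc.append(f"column {column}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.line_number = line_number
        self.column = column


@dataclass(frozen=True, slots=True)
class ReadObservation:
    """One decoded per-read base call at a pileup position.

    ``allele`` is the resolved base (A/C/G/T) after '.'/',' REF substitution;
    ``read_pos`` is the 1-based offset of this base within its read.
    """

    allele: str
    strand: str  # "+" forward, "-" reverse
    bqv: int
    mqv: int
    read_pos: int
    is_read_start: bool = False
    is_read_end: bool = False

    def __post_init__(self):
        if self.allele not in _BASES:
            raise ValueError(f"allele must be one of A/C/G/T, got {self.allele!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.bqv < 0 or self.mqv < 0 or self.read_pos < 1:
            raise ValueError("bqv/mqv must be >= 0 and read_pos >= 1")


@dataclass
class PileupRecord:
    """All decoded observations for one sample at one reference position."""

    chrom: str
    pos: int
    ref: str
    depth: int
    observations: list[ReadObservation] = field(default_factory=list)
    n_placeholder: int = 0  # '*' '<' '>' and N slots consumed but not decoded

    @property
    def alt_alleles(self) -> list[str]:
        """Distinct non-reference alleles observed, alphabetical."""
        ref = self.ref.upper()
        return sorted({o.allele for o in self.observations if o.allele != ref})

    def count_allele(self, allele: str) -> int:
        a = allele.upper()
        return sum(1 for o in self.observations if o.allele == a)

    def to_mpileup_line(self) -> str:
        """Serialize back to the eight-column dialect (round-trip inverse of
        :func:`parse_mpileup_line`)."""
        ref = self.ref.upper()
        bases, bquals, mquals, rpos = [], [], [], []
        for o in self.observations:
            sym = "." if o.allele == ref else o.allele
            if o.strand == "-":
                sym = "," if sym == "." else sym.lower()
            piece = sym + ("$" if o.is_read_end else "")
            if o.is_read_start:
                piece = "^" + chr(min(o.mqv, 93) + 33) + piece
            bases.append(piece)
            bquals.append(chr(min(o.bqv, 93) + 33))
            mquals.append(chr(min(o.mqv, 93) + 33))
            rpos.append(str(o.read_pos))
        return "\t".join([
            self.chrom, str(self.pos), self.ref, str(self.depth),
            "".join(bases) or "*", "".join(bquals) or "*",
            "".join(mquals) or "*", ",".join(rpos) or "*",
        ])


@dataclass
class SitePair:
    """Matched tumor and normal pileup records at one locus."""

    tumor: PileupRecord
    normal: PileupRecord

    def __post_init__(self):
        if (self.tumor.chrom, self.tumor.pos) != (self.normal.chrom, self.normal.pos):
            raise ValueError("tumor and normal records are at different loci")
        if self.tumor.ref.upper() != self.normal.ref.upper():
            raise ValueError(
                f"reference mismatch at {self.tumor.chrom}:{self.tumor.pos}: "
                f"{self.tumor.ref!r} vs {self.normal.ref!r}"
            )


def parse_mpileup_line(line: str, line_number: int | None = None) -> PileupRecord | None:
    """Decode one eight-column mpileup line into a :class:`PileupRecord`.

    Returns ``None`` for reference-N sites (undefined alternative allele),
    after logging a warning.  Raises :class:`PileupParseError` on malformed
    input, naming the offending line and column.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise PileupParseError(
            f"expected 8 tab-separated columns, got {len(fields)}", line_number)
    chrom, pos_s, ref, depth_s, bases, bquals, mquals, rpos_s = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise PileupParseError(f"non-numeric POS {pos_s!r}", line_number, 2) from None
    try:
        depth = int(depth_s)
    except ValueError:
        raise PileupParseError(f"non-numeric DEPTH {depth_s!r}", line_number, 4) from None
    if pos < 1:
        raise PileupParseError(f"POS must be >= 1, got {pos}", line_number, 2)
    if ref.upper() == "N":
        logger.warning("skipping reference-N site %s:%d", chrom, pos)
        return None

    if depth == 0 or bases == "*" and depth == 0:
        return PileupRecord(chrom, pos, ref, 0, [])

    if rpos_s == "*":
        read_positions: list[int] = []
    else:
        try:
            read_positions = [int(x) for x in rpos_s.split(",")]
        except ValueError:
            raise PileupParseError(
                f"non-numeric read position in {rpos_s!r}", line_number, 8) from None

    ref_u = ref.upper()
    observations: list[ReadObservation] = []
    n_placeholder = 0

    if _SPECIAL.isdisjoint(bases):
        # fast path: plain base symbols only, one char per slot
        if not (len(bases) == len(bquals) == len(mquals) == len(read_positions)):
            raise PileupParseError(
                "quality/read-position string length mismatch with base count",
                line_number, 5)
        for i, c in enumerate(bases):
            allele, strand = _resolve(c, ref_u, line_number)
            observations.append(ReadObservation(
                allele, strand, ord(bquals[i]) - 33, ord(mquals[i]) - 33,
                read_positions[i]))
    else:
        i = 0  # index into bases string
        slot = 0  # index into quality/read-position arrays
        n = len(bases)
        pending_start = False
        while i < n:
            c = bases[i]
            if c == "^":
                if i + 1 >= n:
                    raise PileupParseError("dangling '^' marker", line_number, 5)
                pending_start = True
                i += 2  # caret + mapping-quality character
                continue
            if c in "+-":
                # indel attached to the previous base: +N<seq> / -N<seq>
                j = i + 1
                while j < n and bases[j].isdigit():
                    j += 1
                if j == i + 1:
                    raise PileupParseError("malformed indel length", line_number, 5)
                length = int(bases[i + 1:j])
                if j + length > n:
                    raise PileupParseError(
                        f"indel sequence truncated (length {length})", line_number, 5)
                i = j + length
                continue
            # every remaining symbol consumes one per-read slot
            if slot >= len(bquals) or slot >= len(mquals):
                raise PileupParseError(
                    "quality-string length mismatch with decoded base count",
                    line_number, 6)
            is_end = i + 1 < n and bases[i + 1] == "$"
            if c in "*<>Nn":
                n_placeholder += 1
            else:
                if slot >= len(read_positions):
                    raise PileupParseError(
                        "read-position list shorter than decoded base count",
                        line_number, 8)
                allele, strand = _resolve(c, ref_u, line_number)
                observations.append(ReadObservation(
                    allele, strand, ord(bquals[slot]) - 33, ord(mquals[slot]) - 33,
                    read_positions[slot], is_read_start=pending_start,
                    is_read_end=is_end))
            pending_start = False
            slot += 1
            i += 1 + (1 if is_end else 0)
        if slot != len(bquals):
            raise PileupParseError(
                f"decoded {slot} base slots but quality string has {len(bquals)}",
                line_number, 6)

    return PileupRecord(chrom, pos, ref, depth, observations, n_placeholder)


def _resolve(c: str, ref_u: str, line_number: int | None) -> tuple[str, str]:
    if c == ".":
        return ref_u, "+"
    if c == ",":
        return ref_u, "-"
    cu = c.upper()
    if cu in _BASES:
        return cu, "+" if c.isupper() else "-"
    raise PileupParseError(f"unexpected base symbol {c!r}", line_number, 5)


def _open_maybe_gzip(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_mpileup(source) -> Iterator[PileupRecord]:
    """Yield records from a path (plain or .gz) or an open text stream."""
    fh = _open_maybe_gzip(source)
    for ln, line in enumerate(fh, start=1):
        if not line.strip():
            continue
        rec = parse_mpileup_line(line, line_number=ln)
        if rec is not None:
            yield rec


def pair_streams(tumor: Iterable[PileupRecord],
                 normal: Iterable[PileupRecord],
                 contig_order: "list[str] | None" = None) -> Iterator[SitePair]:
    """Merge two position-sorted record streams into :class:`SitePair`s.

    Only loci present in both streams are yielded, in input order.  Both
    streams must be sorted by position within each contig and must list
    shared contigs in the same order; a position decrease within a contig
    raises ``ValueError``.

    When ``contig_order`` is given it defines the global contig ordering.
    Otherwise the ordering is inferred from first appearance across the two
    streams, which is unambiguous whenever both streams contain the same
    contigs (the usual matched tumor/normal case); a contig private to one
    stream is then assumed to sort after every contig already seen.
    """
    it_t, it_n = iter(tumor), iter(normal)
    t = next(it_t, None)
    n = next(it_n, None)
    ranks: dict[str, int] = (
        {c: i for i, c in enumerate(contig_order)} if contig_order else {}
    )
    fixed = contig_order is not None
    last_t: tuple[int, int] | None = None
    last_n: tuple[int, int] | None = None

    def key(rec: PileupRecord) -> tuple[int, int]:
        if rec.chrom not in ranks:
            if fixed:
                raise ValueError(f"contig {rec.chrom!r} not in contig_order")
            ranks[rec.chrom] = len(ranks)
        return (ranks[rec.chrom], rec.pos)

    while t is not None and n is not None:
        kt = key(t)
        kn = key(n)
        if last_t is not None and kt < last_t:
            raise ValueError(f"tumor stream unsorted at {t.chrom}:{t.pos}")
        if last_n is not None and kn < last_n:
            raise ValueError(f"normal stream unsorted at {n.chrom}:{n.pos}")
        if kt == kn:
            yield SitePair(t, n)
            last_t, last_n = kt, kn
            t = next(it_t, None)
            n = next(it_n, None)
        elif kt < kn:
            last_t = kt
            t = next(it_t, None)
        else:
            last_n = kn
            n = next(it_n, None)
    # one stream is exhausted; keep validating sort order on the other
    while t is not None:
        kt = key(t)
        if last_t is not None and kt < last_t:
            raise ValueError(f"tumor stream unsorted at {t.chrom}:{t.pos}")
        last_t = kt
        t = next(it_t, None)
    while n is not None:
        kn = key(n)
        if last_n is not None and kn < last_n:
            raise ValueError(f"normal stream unsorted at {n.chrom}:{n.pos}")
        last_n = kn
        n = next(it_n, None)
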