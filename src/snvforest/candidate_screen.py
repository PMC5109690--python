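"""Candidate somatic-SNV screening: quality filters, Fisher's exact somatic
test, and optional BED-region exclusion.

A matched locus nominates one candidate per distinct tumor alternative allele
that has at least ``min_alt_reads`` supporting reads passing both quality
thresholds (BQV >= 20 and MQV >= 10 by default), provided both samples reach
the minimum declared coverage (8X by default).  Each candidate carries a
two-sided Fisher's exact p-value comparing ref/alt read counts between tumor
and normal; the p-value is an annotation and a downstream feature, never a
hard cutoff here.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from scipy.stats import fisher_exact

from .pileup_io import SitePair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter thresholds for candidate nomination.

    ``min_coverage`` applies to the declared (column-4) depth of both
    samples; the BQV/MQV thresholds apply only to reads supporting the
    alternative allele.
    """

    min_alt_bqv: int = 20
    min_alt_mqv: int = 10
    min_coverage: int = 8
    min_alt_reads: int = 1

    def __post_init__(self):
        for name in ("min_alt_bqv", "min_alt_mqv", "min_coverage", "min_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CandidateVariant:
    """A putative somatic SNV at one matched locus, for one alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_counts: tuple[int, int]   # (ref_reads, alt_reads)
    normal_counts: tuple[int, int]
    somatic_p: float
    site: SitePair

    def __post_init__(self):
        if self.alt == self.ref.upper():
            raise ValueError("alt allele equals reference")
        if not (0.0 <= self.somatic_p <= 1.0):
            raise ValueError("somatic_p must lie in [0, 1]")


def fisher_somatic_test(tumor_counts: tuple[int, int],
                        normal_counts: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p for [[tumor_ref, tumor_alt],
    [normal_ref, normal_alt]].

    Raises ``ValueError`` on an all-zero table (no reads to compare).
    """
    tr, ta = tumor_counts
    nr, na = normal_counts
    if min(tr, ta, nr, na) < 0:
        raise ValueError("counts must be non-negative")
    if tr + ta + nr + na == 0:
        raise ValueError("all-zero 2x2 table has no defined Fisher p-value")
    return float(fisher_exact([[tr, ta], [nr, na]], alternative="two-sided")[1])


def screen_site(site: SitePair, cfg: FilterConfig = FilterConfig()) -> list[CandidateVariant]:
    """Nominate candidate variants at one matched locus.

    Returns one candidate per distinct tumor alt allele whose
    quality-filtered support (reads with BQV >= ``min_alt_bqv`` and
    MQV >= ``min_alt_mqv``) reaches ``min_alt_reads``.  Empty when either
    sample's declared depth is below ``min_coverage``.  Ref/alt counts and
    the somatic p-value use all observed reads of the two alleles.
    """
    t, n = site.tumor, site.normal
    if t.depth < cfg.min_coverage or n.depth < cfg.min_coverage:
        return []
    ref = t.ref.upper()
    support: dict[str, int] = {}
    totals: dict[str, int] = {}
    for o in t.observations:
        if o.allele == ref:
            continue
        totals[o.allele] = totals.get(o.allele, 0) + 1
        if o.bqv >= cfg.min_alt_bqv and o.mqv >= cfg.min_alt_mqv:
            support[o.allele] = support.get(o.allele, 0) + 1

    out: list[CandidateVariant] = []
    if not support:
        return out
    t_ref = t.count_allele(ref)
    n_ref = n.count_allele(ref)
    for alt in sorted(support):
        if support[alt] < cfg.min_alt_reads:
            continue
        t_alt = totals[alt]
        n_alt = n.count_allele(alt)
        p = fisher_somatic_test((t_ref, t_alt), (n_ref, n_alt))
        out.append(CandidateVariant(t.chrom, t.pos, ref, alt,
                                    (t_ref, t_alt), (n_ref, n_alt), p, site))
    return out


# ---------------------------------------------------------------------------
# BED-region exclusion


class BedParseError(ValueError):
    pass


def read_bed(source) -> dict[str, list[tuple[int, int]]]:
    """Parse a BED file (0-based half-open) into per-contig interval lists.

    Accepts a path or an open text stream; raises :class:`BedParseError`
    with the line number on malformed lines.
    """
    fh = open(source) if not hasattr(source, "read") else source
    intervals: dict[str, list[tuple[int, int]]] = {}
    for ln, line in enumerate(fh, start=1):
        s = line.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        parts = s.split("\t") if "\t" in s else s.split()
        if len(parts) < 3:
            raise BedParseError(f"BED line {ln}: expected >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise BedParseError(f"BED line {ln}: non-numeric interval bounds") from None
        if start < 0 or end < start:
            raise BedParseError(f"BED line {ln}: invalid interval [{start}, {end})")
        intervals.setdefault(parts[0], []).append((start, end))
    for ivs in intervals.values():
        ivs.sort()
    return intervals


def _overlaps(intervals: Sequence[tuple[int, int]], pos_1based: int) -> bool:
    # BED is 0-based half-open: 1-based position p falls in [start, end)
    # iff start < p <= end.  Intervals are sorted but may nest, so scan all
    # intervals starting at or before p.
    i = bisect.bisect_right(intervals, (pos_1based, float("inf")))
    return any(start < pos_1based <= end for start, end in intervals[:i])


def region_filter(candidates: Iterable[CandidateVariant],
                  exclude_tracks: Sequence[dict[str, list[tuple[int, int]]]],
                  track_names: Sequence[str] | None = None,
                  ) -> Iterator[CandidateVariant]:
    """Drop candidates overlapping any interval of any exclusion track.

    Tracks are per-contig interval dictionaries as returned by
    :func:`read_bed`.  Per-track drop counts are logged on exhaustion.
    """
    names = list(track_names) if track_names else [f"track{i}" for i in range(len(exclude_tracks))]
    drops = [0] * len(exclude_tracks)
    for cand in candidates:
        dropped = False
        for i, track in enumerate(exclude_tracks):
            ivs = track.get(cand.chrom)
            if ivs and _overlaps(ivs, cand.pos):
                drops[i] += 1
                dropped = True
                break
        if not dropped:
            yield cand
    for name, d in zip(names, drops):
        logger.info("region filter %s dropped %d candidates", name, d)
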