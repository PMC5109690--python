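"""Per-candidate feature extraction: the 15-feature representation.

Each candidate somatic SNV is summarised by fifteen numeric features in five
groups:

i.   quality bias of alternative bases —
     ``alt_bqv_mean_vs_med``, ``alt_mqv_mean_vs_med`` (mean alt BQV/MQV as a
     ratio to the background median of per-site mean qualities) and
     ``bqv_ranksum_p``, ``mqv_ranksum_p`` (two-sided Wilcoxon rank-sum p of
     alt- vs ref-supporting read qualities at the locus, the *vs_ref*
     comparisons);
ii.  coverage and VAF — ``tumor_depth_vs_med``, ``normal_depth_vs_med``
     (declared depths as ratios to background medians), ``tumor_vaf``,
     ``normal_vaf`` (alt-read fraction of decoded observations);
iii. location along the read — ``alt_read_pos_rel`` (mean relative within-
     read position of alt bases, in [0, 1]), ``read_pos_ranksum_p``
     (alt vs ref), ``alt_near_end_frac`` (fraction of alt bases within 5 bp
     of a read end);
iv.  strand bias — ``strand_fisher_p`` (two-sided Fisher p on alt fwd/rev vs
     ref fwd/rev) and ``alt_majority_strand_frac`` (fraction of alt reads on
     their majority strand);
v.   others — ``somatic_fisher_p`` (tumor-vs-normal ref/alt Fisher p carried
     from screening) and ``n_alt_alleles`` (distinct non-reference alleles
     observed in the tumor pileup).

Ratio (*vs_med*) features normalise absolute values against medians
estimated from randomly sampled pileup positions of the same input files,
so that models transfer across runs with different depth and quality scales.
Rank tests with an empty ref side return the neutral value 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact, rankdata

from .candidate_screen import CandidateVariant
from .pileup_io import PileupRecord, SitePair

#: small constant guarding ratio features against a zero background median
MEDIAN_EPSILON = 1e-6

#: bases within this distance of either read end count as "near end"
NEAR_END_BP = 5

#: exact rank-sum enumeration below this total sample size (no ties only)
EXACT_RANKSUM_CUTOFF = 10

FEATURE_NAMES: tuple[str, ...] = (
    "alt_bqv_mean_vs_med",
    "alt_mqv_mean_vs_med",
    "bqv_ranksum_p",
    "mqv_ranksum_p",
    "tumor_depth_vs_med",
    "normal_depth_vs_med",
    "tumor_vaf",
    "normal_vaf",
    "alt_read_pos_rel",
    "read_pos_ranksum_p",
    "alt_near_end_frac",
    "strand_fisher_p",
    "alt_majority_strand_frac",
    "somatic_fisher_p",
    "n_alt_alleles",
)

#: raw per-site quantities whose background medians drive the vs_med ratios
BACKGROUND_KEYS: tuple[str, ...] = (
    "mean_bqv", "mean_mqv", "tumor_depth", "normal_depth",
)


@dataclass
class BackgroundMedians:
    """Medians of raw per-site quantities from randomly sampled positions."""

    medians: dict[str, float]
    n_positions: int
    seed: int

    def __post_init__(self):
        missing = set(BACKGROUND_KEYS) - set(self.medians)
        if missing:
            raise ValueError(f"missing background medians: {sorted(missing)}")
        for k, v in self.medians.items():
            if not math.isfinite(v):
                raise ValueError(f"background median {k} is not finite")

    def __getitem__(self, key: str) -> float:
        return self.medians[key]


def median_normalize(raw: float, bg_median: float) -> float:
    """Ratio of a raw value to its background median, guarded by
    ``MEDIAN_EPSILON`` against degenerate zero medians."""
    return raw / max(bg_median, MEDIAN_EPSILON)


def rank_sum_test(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration of the null permutation distribution when the
    pooled sample is small (< ``EXACT_RANKSUM_CUTOFF``) and tie-free, and
    the tie-corrected normal approximation with continuity correction
    otherwise.  Identical samples give p = 1.0.
    """
    nx, ny = len(xs), len(ys)
    if nx == 0 or ny == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([np.asarray(xs, float), np.asarray(ys, float)])
    ranks = rankdata(pooled)  # midranks for ties
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0  # Mann-Whitney U for xs

    has_ties = len(np.unique(pooled)) < nx + ny
    if nx + ny < EXACT_RANKSUM_CUTOFF and not has_ties:
        return _exact_ranksum_p(u, nx, ny)

    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * _norm_sf(z)))


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def _exact_ranksum_p(u: float, nx: int, ny: int) -> float:
    """Two-sided exact p: P(|U - nx*ny/2| >= |u - nx*ny/2|) under the null,
    by enumerating every assignment of nx ranks to the first sample (pooled
    sizes here are < 10, so at most C(9, 4) = 126 assignments)."""
    from itertools import combinations

    n = nx + ny
    center = nx * ny / 2.0
    dev = abs(u - center)
    hits = total = 0
    for combo in combinations(range(1, n + 1), nx):
        u_c = sum(combo) - nx * (nx + 1) / 2.0
        total += 1
        if abs(u_c - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def _strand_fisher_p(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    if alt_fwd + alt_rev + ref_fwd + ref_rev == 0:
        return 1.0
    return float(fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]],
                              alternative="two-sided")[1])


def site_raw_background(pair: SitePair) -> dict[str, float]:
    """Raw per-site quantities entering the background medians."""
    t, n = pair.tumor, pair.normal
    k = len(t.observations)
    return {
        "mean_bqv": sum(o.bqv for o in t.observations) / k if k else 0.0,
        "mean_mqv": sum(o.mqv for o in t.observations) / k if k else 0.0,
        "tumor_depth": float(t.depth),
        "normal_depth": float(n.depth),
    }


class RawReservoir:
    """Seeded reservoir sampler of raw per-site background quantities,
    usable inline during a single streaming pass over paired pileups."""

    def __init__(self, n_positions: int, seed: int):
        if n_positions < 100:
            raise ValueError("n_positions must be >= 100 for stable medians")
        self.n_positions = n_positions
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._items: list[dict[str, float]] = []
        self._seen = 0

    def add(self, raw: dict[str, float]) -> None:
        self._seen += 1
        if len(self._items) < self.n_positions:
            self._items.append(raw)
        else:
            j = int(self._rng.integers(0, self._seen))
            if j < self.n_positions:
                self._items[j] = raw

    def medians(self) -> BackgroundMedians:
        import logging
        if not self._items:
            raise ValueError("no usable positions for background sampling")
        if len(self._items) < self.n_positions:
            logging.getLogger(__name__).warning(
                "background sampling requested %d positions but only %d available",
                self.n_positions, len(self._items))
        medians = {k: float(np.median([r[k] for r in self._items]))
                   for k in BACKGROUND_KEYS}
        return BackgroundMedians(medians, len(self._items), self.seed)


def sample_background(pairs: Iterable[SitePair], n_positions: int = 10_000,
                      seed: int = 0) -> BackgroundMedians:
    """Estimate background medians from a seeded reservoir sample of matched
    positions.

    Deterministic given the seed and input order.  If fewer than
    ``n_positions`` usable positions exist, all available are used (with a
    logged warning).
    """
    res = RawReservoir(n_positions, seed)
    for pair in pairs:
        res.add(site_raw_background(pair))
    return res.medians()


def extract_features(cand: CandidateVariant, bg: BackgroundMedians) -> dict[str, float]:
    """Compute the 15-feature vector for one candidate.

    Returns an ordered mapping keyed by :data:`FEATURE_NAMES`; every value is
    finite.  Observation order within the pileup records never affects the
    result.
    """
    t = cand.site.tumor
    n = cand.site.normal
    ref = cand.ref.upper()
    alt = cand.alt

    alt_obs = [o for o in t.observations if o.allele == alt]
    ref_obs = [o for o in t.observations if o.allele == ref]
    if not alt_obs:
        raise ValueError("candidate has no alt-supporting tumor observations")

    alt_bq = [o.bqv for o in alt_obs]
    alt_mq = [o.mqv for o in alt_obs]

    def vs_ref_p(alt_vals: list[float], ref_vals: list[float]) -> float:
        if not ref_vals:
            return 1.0  # no reference reads: no evidence of bias
        return rank_sum_test(alt_vals, ref_vals)

    # group iii: relative read positions; mpileup carries no read length, so
    # the maximum observed within-read offset at the locus is the proxy.
    all_pos = [o.read_pos for o in t.observations]
    read_len = max(all_pos)
    alt_pos = [o.read_pos for o in alt_obs]
    ref_pos = [o.read_pos for o in ref_obs]
    near_end = sum(1 for p in alt_pos
                   if p <= NEAR_END_BP or p > read_len - NEAR_END_BP)

    alt_fwd = sum(1 for o in alt_obs if o.strand == "+")
    alt_rev = len(alt_obs) - alt_fwd
    ref_fwd = sum(1 for o in ref_obs if o.strand == "+")
    ref_rev = len(ref_obs) - ref_fwd

    n_obs_t = len(t.observations)
    n_obs_n = len(n.observations)
    tumor_vaf = len(alt_obs) / n_obs_t if n_obs_t else 0.0
    normal_vaf = (n.count_allele(alt) / n_obs_n) if n_obs_n else 0.0

    fv = {
        "alt_bqv_mean_vs_med": median_normalize(float(np.mean(alt_bq)), bg["mean_bqv"]),
        "alt_mqv_mean_vs_med": median_normalize(float(np.mean(alt_mq)), bg["mean_mqv"]),
        "bqv_ranksum_p": vs_ref_p(alt_bq, [o.bqv for o in ref_obs]),
        "mqv_ranksum_p": vs_ref_p(alt_mq, [o.mqv for o in ref_obs]),
        "tumor_depth_vs_med": median_normalize(float(t.depth), bg["tumor_depth"]),
        "normal_depth_vs_med": median_normalize(float(n.depth), bg["normal_depth"]),
        "tumor_vaf": tumor_vaf,
        "normal_vaf": normal_vaf,
        "alt_read_pos_rel": float(np.mean(alt_pos)) / read_len,
        "read_pos_ranksum_p": vs_ref_p([float(p) for p in alt_pos],
                                       [float(p) for p in ref_pos]),
        "alt_near_end_frac": near_end / len(alt_obs),
        "strand_fisher_p": _strand_fisher_p(alt_fwd, alt_rev, ref_fwd, ref_rev),
        "alt_majority_strand_frac": max(alt_fwd, alt_rev) / len(alt_obs),
        "somatic_fisher_p": cand.somatic_p,
        "n_alt_alleles": float(len(t.alt_alleles)),
    }
    for k, v in fv.items():
        if not math.isfinite(v):
            raise AssertionError(f"non-finite feature {k}={v}")
    return fv


def features_to_array(fvs: Sequence[dict[str, float]],
                      names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
    """Stack feature dictionaries into an (n, len(names)) float array."""
    return np.array([[fv[name] for name in names] for fv in fvs], dtype=np.float64)
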