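"""Synthetic matched tumor/normal mpileup simulator with known ground truth.

The simulator emulates the study conditions of low-pass matched-pair
sequencing: per-site depths are negative-binomially overdispersed around a
configurable mean (30X low-pass and 90X WGS regimes as presets), sequencing
errors occur independently per observation at a configurable per-base rate,
and error observations carry the artifact signatures the classifier's
features target — a lower base- and mapping-quality distribution than true
bases, optional single-strand placement at a fraction of sites, and optional
bias toward read ends.  Planted somatic SNVs appear in the tumor only at
clonal/subclonal VAFs (default range 0.16-0.58); planted germline
heterozygous sites appear in both samples at VAF 0.5.

Everything is drawn from one seeded generator, so identical configurations
produce byte-identical files.  Output uses the eight-column mpileup dialect
of :mod:`snvforest.pileup_io` (bases, base qualities, mapping qualities,
within-read positions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

try:
    from importlib import resources as _resources
except ImportError:  # pragma: no cover
    _resources = None

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Scenario parameters for one matched-pair simulation."""

    n_sites: int = 10_000
    chrom: str = "chr1"
    start_pos: int = 1
    mean_depth_tumor: float = 30.0
    mean_depth_normal: float = 30.0
    depth_dispersion: float = 20.0   # negbin: var = mean + mean^2 / dispersion
    error_rate: float = 0.01         # per-base miscall probability
    read_length: int = 100
    true_bqv: tuple[float, float] = (36.0, 4.0)   # (mean, sd) of true-base BQV
    error_bqv: tuple[float, float] = (24.0, 7.0)
    true_mqv: tuple[float, float] = (55.0, 5.0)
    error_mqv: tuple[float, float] = (30.0, 12.0)
    strand_bias_fraction: float = 0.3  # sites whose error reads are one-stranded
    error_end_bias: float = 0.5        # P(error read position drawn near a read end)
    end_zone_bp: int = 5
    n_somatic: int = 0
    somatic_vafs: Sequence[float] | None = None   # explicit VAF list, or None
    somatic_vaf_range: tuple[float, float] = (0.16, 0.58)
    n_germline: int = 0
    germline_vaf: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")
        if not (0.0 <= self.strand_bias_fraction <= 1.0):
            raise ValueError("strand_bias_fraction must lie in [0, 1]")
        if self.n_somatic < 0 or self.n_germline < 0 or self.n_sites <= 0:
            raise ValueError("counts must be non-negative and n_sites positive")
        if self.n_somatic + self.n_germline > self.n_sites:
            raise ValueError("more planted sites than simulated sites")
        if self.somatic_vafs is not None:
            if len(self.somatic_vafs) != self.n_somatic:
                raise ValueError("somatic_vafs length must equal n_somatic")
            vafs = list(self.somatic_vafs)
        else:
            vafs = list(self.somatic_vaf_range)
        for v in vafs + [self.germline_vaf]:
            if not (0.0 < v < 1.0):
                raise ValueError("VAFs must lie in (0, 1)")


@dataclass
class TruthRecord:
    chrom: str
    pos: int
    kind: str        # "somatic" or "germline"
    vaf: float
    ref: str
    alt: str


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def somatic_loci(self) -> set[tuple[str, int, str]]:
        return {(r.chrom, r.pos, r.alt) for r in self.records if r.kind == "somatic"}

    def germline_loci(self) -> set[tuple[str, int]]:
        return {(r.chrom, r.pos) for r in self.records if r.kind == "germline"}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tkind\tvaf\tref\talt\n")
            for r in self.records:
                fh.write(f"{r.chrom}\t{r.pos}\t{r.kind}\t{r.vaf:.6g}\t{r.ref}\t{r.alt}\n")

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        recs = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                c, p, k, v, ref, alt = line.rstrip("\n").split("\t")
                recs.append(TruthRecord(c, int(p), k, float(v), ref, alt))
        return cls(recs)

    def germline_bed(self, path) -> None:
        """Write germline site positions as a 0-based half-open BED track."""
        with open(path, "w") as fh:
            for r in self.records:
                if r.kind == "germline":
                    fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\n")


def _negbin(rng: np.random.Generator, mean: float, dispersion: float,
            size: int) -> np.ndarray:
    # var = mean + mean^2/dispersion; numpy parameterization n, p
    n = dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _quality_chars(q: np.ndarray) -> str:
    return (np.clip(q, 0, 93).astype(np.uint8) + 33).tobytes().decode("latin1")


def simulate_pair(cfg: SimulationConfig, out_dir) -> tuple[Path, Path, TruthTable]:
    """Write ``tumor.mpileup``, ``normal.mpileup`` and ``truth.tsv`` under
    ``out_dir``; returns the two pileup paths and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_sites
    positions = np.arange(cfg.start_pos, cfg.start_pos + n)
    ref_idx = rng.integers(0, 4, size=n)

    # plant somatic and germline sites at distinct loci
    planted = rng.choice(n, size=cfg.n_somatic + cfg.n_germline, replace=False)
    somatic_sites = np.sort(planted[:cfg.n_somatic])
    germline_sites = np.sort(planted[cfg.n_somatic:])

    if cfg.somatic_vafs is not None:
        som_vaf = np.asarray(cfg.somatic_vafs, dtype=float)
    else:
        lo, hi = cfg.somatic_vaf_range
        som_vaf = rng.uniform(lo, hi, size=cfg.n_somatic)

    # per-site variant alt allele: shift within the 3 non-ref bases
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4

    vaf_tumor = np.zeros(n)
    vaf_normal = np.zeros(n)
    vaf_tumor[somatic_sites] = som_vaf
    vaf_tumor[germline_sites] = cfg.germline_vaf
    vaf_normal[germline_sites] = cfg.germline_vaf

    # per-site error strand bias, shared signature machinery per sample
    site_biased = rng.random(n) < cfg.strand_bias_fraction
    site_bias_fwd = rng.random(n) < 0.5

    truth = TruthTable(
        [TruthRecord(cfg.chrom, int(positions[s]), "somatic",
                     float(vaf_tumor[s]), str(_BASES[ref_idx[s]]),
                     str(_BASES[alt_idx[s]])) for s in somatic_sites]
        + [TruthRecord(cfg.chrom, int(positions[s]), "germline",
                       cfg.germline_vaf, str(_BASES[ref_idx[s]]),
                       str(_BASES[alt_idx[s]])) for s in germline_sites]
    )

    paths = (out / "tumor.mpileup", out / "normal.mpileup")
    for path, mean_depth, vaf in ((paths[0], cfg.mean_depth_tumor, vaf_tumor),
                                  (paths[1], cfg.mean_depth_normal, vaf_normal)):
        _write_sample(path, cfg, rng, positions, ref_idx, alt_idx, vaf,
                      mean_depth, site_biased, site_bias_fwd)
    truth.write_tsv(out / "truth.tsv")
    return paths[0], paths[1], truth


def _write_sample(path: Path, cfg: SimulationConfig, rng: np.random.Generator,
                  positions: np.ndarray, ref_idx: np.ndarray,
                  alt_idx: np.ndarray, vaf: np.ndarray, mean_depth: float,
                  site_biased: np.ndarray, site_bias_fwd: np.ndarray) -> None:
    n = len(positions)
    depths = _negbin(rng, mean_depth, cfg.depth_dispersion, n)
    total = int(depths.sum())
    site_of = np.repeat(np.arange(n), depths)

    is_variant = rng.random(total) < vaf[site_of]
    is_error = (~is_variant) & (rng.random(total) < cfg.error_rate)
    is_true_base = ~is_error  # variant reads are true bases, error reads are not

    # allele index per read
    allele = ref_idx[site_of].copy()
    allele[is_variant] = alt_idx[site_of[is_variant]]
    n_err = int(is_error.sum())
    err_shift = rng.integers(1, 4, size=n_err)
    allele[is_error] = (ref_idx[site_of[is_error]] + err_shift) % 4

    bqv = np.where(is_true_base,
                   rng.normal(*cfg.true_bqv, size=total),
                   rng.normal(*cfg.error_bqv, size=total))
    mqv = np.where(is_true_base,
                   rng.normal(*cfg.true_mqv, size=total),
                   rng.normal(*cfg.error_mqv, size=total))
    bqv = np.clip(np.rint(bqv), 2, 60).astype(np.int64)
    mqv = np.clip(np.rint(mqv), 0, 60).astype(np.int64)

    fwd = rng.random(total) < 0.5
    biased_err = is_error & site_biased[site_of]
    fwd[biased_err] = site_bias_fwd[site_of[biased_err]]

    read_pos = rng.integers(1, cfg.read_length + 1, size=total)
    end_biased = is_error & (rng.random(total) < cfg.error_end_bias)
    n_eb = int(end_biased.sum())
    if n_eb:
        zone = rng.integers(1, cfg.end_zone_bp + 1, size=n_eb)
        at_start = rng.random(n_eb) < 0.5
        read_pos[end_biased] = np.where(at_start, zone,
                                        cfg.read_length + 1 - zone)

    # base symbols
    is_ref_read = allele == ref_idx[site_of]
    syms = np.empty(total, dtype="<U1")
    syms[is_ref_read & fwd] = "."
    syms[is_ref_read & ~fwd] = ","
    for b in range(4):
        m = (~is_ref_read) & (allele == b)
        syms[m & fwd] = _BASES[b]
        syms[m & ~fwd] = _BASES[b].lower()

    pieces = syms.tolist()
    for i in np.flatnonzero(read_pos == 1):
        pieces[i] = "^" + chr(int(mqv[i]) + 33) + pieces[i]
    for i in np.flatnonzero(read_pos == cfg.read_length):
        pieces[i] = pieces[i] + "$"

    bq_str = _quality_chars(bqv)
    mq_str = _quality_chars(mqv)
    rp_list = [str(x) for x in read_pos.tolist()]

    offsets = np.concatenate([[0], np.cumsum(depths)]).astype(np.int64)
    ref_bases = _BASES[ref_idx]
    chrom = cfg.chrom
    with open(path, "w") as fh:
        for s in range(n):
            a, b = int(offsets[s]), int(offsets[s + 1])
            d = b - a
            if d == 0:
                fh.write(f"{chrom}\t{positions[s]}\t{ref_bases[s]}\t0\t*\t*\t*\t*\n")
                continue
            fh.write(f"{chrom}\t{positions[s]}\t{ref_bases[s]}\t{d}\t"
                     f"{''.join(pieces[a:b])}\t{bq_str[a:b]}\t{mq_str[a:b]}\t"
                     f"{','.join(rp_list[a:b])}\n")


def subsample_coverage(mpileup_path, keep_fraction: float, seed: int,
                       out_path) -> Path:
    """Thin a pileup by keeping each observation independently with
    probability ``keep_fraction``; the depth column is updated to the kept
    count.  Deterministic given the seed."""
    from .pileup_io import PileupRecord, read_mpileup

    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for rec in read_mpileup(mpileup_path):
            if rec.observations:
                keep = rng.random(len(rec.observations)) < keep_fraction
                obs = [o for o, k in zip(rec.observations, keep) if k]
            else:
                obs = []
            thinned = PileupRecord(rec.chrom, rec.pos, rec.ref, len(obs), obs)
            fh.write(thinned.to_mpileup_line() + "\n")
    return out_path


def label_candidates(candidates, truth: TruthTable) -> dict[tuple[str, int, str], str]:
    """Label screened candidates against the truth table, emulating
    orthogonal validation: TP for planted somatic loci, FP otherwise."""
    somatic = truth.somatic_loci()
    return {(c.chrom, c.pos, c.alt):
            ("TP" if (c.chrom, c.pos, c.alt) in somatic else "FP")
            for c in candidates}


# ---------------------------------------------------------------------------
# Scenario presets

PRESETS = {
    "lowpass30x": dict(
        n_sites=20_000, mean_depth_tumor=30.0, mean_depth_normal=30.0,
        error_rate=0.01, n_somatic=20, somatic_vaf_range=(0.16, 0.58),
        n_germline=50),
    "wgs90x": dict(
        n_sites=20_000, mean_depth_tumor=90.0, mean_depth_normal=90.0,
        error_rate=0.005, n_somatic=20, somatic_vaf_range=(0.16, 0.58),
        n_germline=50),
    "imbalanced-test": dict(
        n_sites=100_000, mean_depth_tumor=30.0, mean_depth_normal=30.0,
        error_rate=0.01, n_somatic=50, somatic_vaf_range=(0.10, 0.60),
        n_germline=100),
    "training-cohort": dict(
        n_sites=53_000, mean_depth_tumor=30.0, mean_depth_normal=30.0,
        error_rate=0.03, n_somatic=250, somatic_vaf_range=(0.16, 0.58),
        n_germline=150),
}


def load_preset(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named scenario preset.

    Presets are shipped as YAML files inside the package
    (``snvforest/presets``); the in-code table is the fallback when package
    data is unavailable.  Keyword overrides replace preset values.
    """
    params = None
    if _resources is not None:
        try:
            import yaml
            ref = _resources.files("snvforest.presets") / f"{name}.yaml"
            if ref.is_file():
                params = yaml.safe_load(ref.read_text())
        except (ModuleNotFoundError, FileNotFoundError, TypeError):
            params = None
    if params is None:
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        params = dict(PRESETS[name])
    params.update(overrides)
    if "somatic_vaf_range" in params:
        params["somatic_vaf_range"] = tuple(params["somatic_vaf_range"])
    return SimulationConfig(**params)
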