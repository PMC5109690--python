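"""End-to-end training and calling pipelines, and the annotated VCF writer.

``run_training`` screens candidates from a matched mpileup pair, extracts
features, joins orthogonal-validation labels, applies cost and VAF-interval
options, trains the cost-sensitive forest and cross-validates it.
``run_calling`` re-screens a new pair, extracts the model's features and
writes one VCF 4.2 record per candidate — rejected candidates are retained
with FILTER ``REJ`` and their class probabilities, so downstream users can
re-threshold numerically instead of trusting the categorical call.

VCF annotations: INFO ``SPV`` (somatic Fisher p), ``CP`` (class probability,
vote fraction of the assigned class, in [0.5, 1]); per-sample FORMAT
``DP:AD:VAF`` for NORMAL and TUMOR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .candidate_screen import CandidateVariant, FilterConfig, read_bed, region_filter, screen_site
from .evaluation import EvaluationReport, write_curves
from .features import BackgroundMedians, extract_features
from .forest import ForestModel, TrainingInstance, cross_validate, predict_batch, train_forest
from .pileup_io import pair_streams, read_mpileup

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs shared by the train and call commands."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    n_trees: int = 300
    cost_fp: float = 1.0
    cost_fn: float = 1.0
    vaf_interval: tuple[float, float] | None = None
    top_k_features: int | None = None
    cv_folds: int = 10
    background_positions: int = 10_000
    seed: int = 0
    germline_bed: str | None = None
    blacklist_bed: str | None = None


@dataclass
class VcfCall:
    """One output record of the calling phase."""

    chrom: str
    pos: int
    ref: str
    alt: str
    somatic_p: float
    filter: str            # "PASS" or "REJ"
    class_prob: float      # [0.5, 1]
    tumor_depth: int
    tumor_alt: int
    tumor_vaf: float
    normal_depth: int
    normal_alt: int
    normal_vaf: float

    def __post_init__(self):
        if self.filter not in ("PASS", "REJ"):
            raise ValueError("filter must be PASS or REJ")
        if not (0.5 <= self.class_prob <= 1.0):
            raise ValueError("class_prob must lie in [0.5, 1]")


def _exclusion_tracks(cfg: PipelineConfig):
    tracks, names = [], []
    if cfg.germline_bed:
        tracks.append(read_bed(cfg.germline_bed))
        names.append("germline")
    if cfg.blacklist_bed:
        tracks.append(read_bed(cfg.blacklist_bed))
        names.append("blacklist")
    return tracks, names


def screen_candidates(tumor_path, normal_path, cfg: PipelineConfig
                      ) -> tuple[list[CandidateVariant], BackgroundMedians]:
    """Shared front half of both phases: pair the pileups, sample the
    feature background, and screen/region-filter candidates."""
    from .features import RawReservoir, site_raw_background

    reservoir = RawReservoir(cfg.background_positions, cfg.seed)
    candidates: list[CandidateVariant] = []
    n_pairs = 0
    for pair in pair_streams(read_mpileup(tumor_path), read_mpileup(normal_path)):
        n_pairs += 1
        reservoir.add(site_raw_background(pair))
        candidates.extend(screen_site(pair, cfg.filters))
    if n_pairs == 0:
        raise ValueError("no matched loci between the tumor and normal pileups")
    background = reservoir.medians()
    tracks, names = _exclusion_tracks(cfg)
    if tracks:
        candidates = list(region_filter(candidates, tracks, names))
    logger.info("screened %d candidate variants from %d matched loci",
                len(candidates), n_pairs)
    return candidates, background


def read_labels(path) -> dict[tuple[str, int, str] | tuple[str, int], str]:
    """Read an orthogonal-validation label table.

    Tab-separated with a header; columns ``chrom pos label`` or
    ``chrom pos alt label``.  Keys with an alt allele take precedence over
    locus-only keys when both are present.
    """
    labels: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_alt = "alt" in header
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"label file line {ln}: expected >= 3 columns")
            row = dict(zip(header, parts))
            lab = row["label"].upper()
            if lab not in ("TP", "FP"):
                raise ValueError(f"label file line {ln}: label must be TP or FP")
            key = ((row["chrom"], int(row["pos"]), row["alt"])
                   if has_alt else (row["chrom"], int(row["pos"])))
            labels[key] = lab
    return labels


def _lookup_label(labels: dict, cand: CandidateVariant) -> str | None:
    return labels.get((cand.chrom, cand.pos, cand.alt),
                      labels.get((cand.chrom, cand.pos)))


def build_training_instances(candidates: Sequence[CandidateVariant],
                             background: BackgroundMedians,
                             labels: dict) -> list[TrainingInstance]:
    instances, unlabeled = [], 0
    for cand in candidates:
        lab = _lookup_label(labels, cand)
        if lab is None:
            unlabeled += 1
            continue
        instances.append(TrainingInstance(extract_features(cand, background), lab))
    if unlabeled:
        logger.info("excluded %d candidates with no validation label", unlabeled)
    return instances


def run_training(tumor_path, normal_path, labels_path, cfg: PipelineConfig,
                 model_path=None, curves_dir=None
                 ) -> tuple[ForestModel, EvaluationReport]:
    """Train the classifier from a matched pair plus validation labels.

    Returns the fitted model and the stratified cross-validation report;
    optionally persists both.  Raises when the labeled set lacks either
    class.
    """
    candidates, background = screen_candidates(tumor_path, normal_path, cfg)
    labels = read_labels(labels_path) if not isinstance(labels_path, dict) else labels_path
    matched = sum(1 for c in candidates if _lookup_label(labels, c) is not None)
    if matched < len(labels):
        logger.warning("%d labeled loci not found among screened candidates",
                       len(labels) - matched)
    instances = build_training_instances(candidates, background, labels)
    n_tp = sum(1 for i in instances if i.label == "TP")
    n_fp = len(instances) - n_tp
    if n_tp == 0 or n_fp == 0:
        raise ValueError(
            f"training needs both classes; got {n_tp} TP and {n_fp} FP labeled candidates")
    logger.info("training on %d TP and %d FP labeled candidates", n_tp, n_fp)

    if cfg.vaf_interval is not None:
        from .forest import filter_vaf_interval
        instances = filter_vaf_interval(instances, *cfg.vaf_interval)

    costs = (cfg.cost_fp, cfg.cost_fn)
    model = train_forest(instances, n_trees=cfg.n_trees, seed=cfg.seed,
                         costs=costs, top_k=cfg.top_k_features,
                         background=background)
    report = cross_validate(instances, k=cfg.cv_folds, seed=cfg.seed,
                            n_trees=cfg.n_trees, costs=costs,
                            top_k=cfg.top_k_features)
    logger.info("oob error %.4f; %d-fold CV ROC AUC %.4f, PR AUC %.4f, kappa %.4f",
                model.oob_error, cfg.cv_folds, report.roc_auc, report.pr_auc,
                report.kappa)
    if model_path:
        model.save(model_path)
    if curves_dir:
        write_curves(report, curves_dir)
    return model, report


def run_calling(model: ForestModel | str, tumor_path, normal_path,
                cfg: PipelineConfig, vcf_path=None) -> list[VcfCall]:
    """Apply a trained model to a new matched pair and emit VCF calls.

    Feature background medians are re-estimated from the input pileups (the
    vs_med ratios always normalise against the files being analysed).
    Records are sorted by (contig appearance order, position); rejected
    candidates are written with FILTER ``REJ``.
    """
    if not isinstance(model, ForestModel):
        model = ForestModel.load(model)
    candidates, background = screen_candidates(tumor_path, normal_path, cfg)
    calls: list[VcfCall] = []
    if candidates:
        fvs = [extract_features(c, background) for c in candidates]
        labels, frac_tp = predict_batch(model, fvs)
        for cand, lab, f in zip(candidates, labels, frac_tp):
            t, n = cand.site.tumor, cand.site.normal
            n_obs_t = len(t.observations) or 1
            n_obs_n = len(n.observations) or 1
            prob = float(f) if lab == "TP" else 1.0 - float(f)
            calls.append(VcfCall(
                chrom=cand.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
                somatic_p=cand.somatic_p,
                filter="PASS" if lab == "TP" else "REJ",
                class_prob=prob,
                tumor_depth=t.depth, tumor_alt=cand.tumor_counts[1],
                tumor_vaf=t.count_allele(cand.alt) / n_obs_t,
                normal_depth=n.depth, normal_alt=cand.normal_counts[1],
                normal_vaf=n.count_allele(cand.alt) / n_obs_n))
    if vcf_path:
        write_vcf(calls, vcf_path)
    return calls


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=snvforest
##INFO=<ID=SPV,Number=1,Type=Float,Description="Two-sided Fisher exact somatic p-value (tumor vs normal ref/alt counts)">
##INFO=<ID=CP,Number=1,Type=Float,Description="Random-forest class probability of the assigned label (vote fraction, 0.5-1)">
##FILTER=<ID=PASS,Description="Classified as a true somatic variant">
##FILTER=<ID=REJ,Description="Classified as a sequencing-error artifact; retained for numerical re-filtering">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Declared read depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Reads supporting the alternative allele">
##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Alternative allele fraction of decoded observations">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""


def write_vcf(calls: Iterable[VcfCall], path) -> None:
    """Write calls as VCF 4.2, sorted by (contig appearance order, pos)."""
    calls = list(calls)
    contig_rank: dict[str, int] = {}
    for c in calls:
        contig_rank.setdefault(c.chrom, len(contig_rank))
    calls.sort(key=lambda c: (contig_rank[c.chrom], c.pos, c.alt))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in calls:
            info = f"SPV={c.somatic_p:.6g};CP={c.class_prob:.6g}"
            normal = f"{c.normal_depth}:{c.normal_alt}:{c.normal_vaf:.6g}"
            tumor = f"{c.tumor_depth}:{c.tumor_alt}:{c.tumor_vaf:.6g}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter}\t"
                     f"{info}\tDP:AD:VAF\t{normal}\t{tumor}\n")


def read_vcf_calls(path) -> list[VcfCall]:
    """Re-parse a VCF written by :func:`write_vcf` (round-trip helper)."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            (chrom, pos, _id, ref, alt, _q, filt, info,
             _fmt, normal, tumor) = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in info.split(";"))
            nd, na, nv = normal.split(":")
            td, ta, tv = tumor.split(":")
            calls.append(VcfCall(chrom, int(pos), ref, alt,
                                 float(kv["SPV"]), filt, float(kv["CP"]),
                                 int(td), int(ta), float(tv),
                                 int(nd), int(na), float(nv)))
    return calls
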