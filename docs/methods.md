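# Methods

This document describes the statistical models, algorithmic choices and
numerical conventions implemented in `snvforest`, together with the scope
and limitations of the bundled simulator.

## Problem setting

Somatic single-nucleotide variants (SNVs) in a tumor must be separated
from germline variation and from sequencing/mapping artifacts, using a
matched tumor/normal pair sequenced at low coverage (order 10–30X). At
such depths a subclonal variant may be supported by only a handful of
reads, which is also exactly what a sequencing-error pileup looks like.
The approach here is two-staged: a permissive rule-based screen produces
candidate variants, and a supervised classifier — trained on candidates
whose true status was established by orthogonal validation (e.g.
re-sequencing) — assigns each candidate a class (true somatic variant
vs. artifact) with a confidence.

## Input decoding

Input is the text pileup format produced by `samtools mpileup` with both
mapping-quality and read-position reporting enabled (8 columns per
sample: chromosome, 1-based position, reference base, declared depth,
base column, base qualities, mapping qualities, comma-separated
within-read positions). The base-column grammar is decoded fully:
read-start (`^` + mapping-quality character) and read-end (`$`) marks,
indel insertions/deletions (`+N<seq>` / `-N<seq>`) attached to the
preceding base, deletion placeholders (`*`) and reference-skip
placeholders (`<`, `>`), and case-encoded strand (uppercase/`.` =
forward, lowercase/`,` = reverse). Placeholders and ambiguous `N` calls
consume their quality-column slots but yield no read observation.
Qualities are ASCII−33 (Phred). Parse errors report line and column.

Tumor and normal streams are merged by a single-pass sorted merge; only
loci present in both streams are analyzed. Contig order is taken from an
explicit list when given, otherwise inferred from first appearance
across the two streams.

## Candidate screening

A site yields one candidate per alternative allele that passes all of:

- raw declared depth ≥ 8 in **both** samples (raw coverage cut — the
  declared depth, not the count of decoded observations);
- at least one tumor read supporting the allele with base quality ≥ 20
  **and** mapping quality ≥ 10.

Each candidate is annotated with a two-sided Fisher's exact p-value on
the table [[tumor_ref, tumor_alt], [normal_ref, normal_alt]] built from
*all* decoded observations (the quality cut gates support, not
counting). No p-value threshold is applied at screening; the p-value
becomes a classifier feature and a VCF annotation. Optional BED tracks
(known-germline exclusion, blacklist) remove candidates; BED intervals
are 0-based half-open, so an interval `(start, end)` removes 1-based
positions `start < p ≤ end`.

## Feature representation (15 features, five groups)

Let *alt reads* be the tumor observations supporting the candidate
allele and *ref reads* the tumor observations matching the reference.

**i. Quality bias** — `alt_bqv_mean_vs_med`, `alt_mqv_mean_vs_med`:
mean alt base/mapping quality divided by the background median (below);
`bqv_ranksum_p`, `mqv_ranksum_p`: two-sided rank-sum p comparing alt
vs. ref read qualities.

**ii. Coverage and allele fraction** — `tumor_depth_vs_med`,
`normal_depth_vs_med`: declared depths over background medians;
`tumor_vaf`, `normal_vaf`: allele observations / decoded observations.

**iii. Read position** — `alt_read_pos_rel`: mean within-read offset of
alt reads divided by the read-length proxy (the maximum observed offset
at the locus — mpileup does not carry read length);
`read_pos_ranksum_p`: rank-sum p of alt vs. ref offsets;
`alt_near_end_frac`: fraction of alt reads within 5 bp of either read
end.

**iv. Strand** — `strand_fisher_p`: two-sided Fisher p on
[[alt_fwd, alt_rev], [ref_fwd, ref_rev]]; `alt_majority_strand_frac`:
fraction of alt reads on their majority strand.

**v. Other** — `somatic_fisher_p` (from screening); `n_alt_alleles`:
number of distinct non-reference alleles observed at the tumor locus.

### Background medians (`vs_med` normalization)

Per-site raw quantities (mean tumor base quality, mean tumor mapping
quality, tumor depth, normal depth) are collected from a seeded
reservoir sample of matched positions (default 10,000) in the same
single pass that screens candidates; their medians define the
normalization denominators. A ratio is `raw / max(median, 1e-6)`; the
epsilon guards degenerate all-zero backgrounds. **At call time the
medians are recomputed from the pileups being analyzed** — the ratios
always normalize against the current dataset, so a model trained on one
quality regime transfers its *relative* thresholds. The training-time
background is stored in the model archive for provenance. When a side
of a rank-sum comparison is empty the p-value is imputed neutrally
as 1.0.

### Rank-sum test

Implemented in-package. Ranks are midranks. For pooled n < 10 with no
ties the two-sided p is exact, by enumerating all C(n, n_alt)
assignments of the pooled values. Otherwise a tie-corrected,
continuity-corrected normal approximation is used. The exact path is
verified against an independent enumeration oracle, the asymptotic path
against `scipy.stats.mannwhitneyu`.

## Classifier

A bagged ensemble of 300 unpruned entropy decision trees
(`sklearn.tree.DecisionTreeClassifier`, criterion `entropy`). At each
node `floor(log2 M) + 1` of the M = 15 features are candidates (4 for
15 features; floor is the integer convention of the Weka default the
original workflow wrapped). Each tree is fit on a bootstrap of the same
size as the training set drawn **with replacement and probability
proportional to instance weight**.

### Cost sensitivity

`apply_costs(instances, cost_fp, cost_fn)` multiplies FP-class weights
by `cost_fp` and TP-class weights by `cost_fn`. The costs act **through
the weighted bootstrap only**: each resample already reflects the
weights in expectation, so they are not applied a second time inside
the split criterion (that would square the intended asymmetry). Raising
`cost_fp` makes the ensemble more reluctant to call a candidate
somatic: on a fixed unbalanced benchmark (~1:8 true:artifact), mean
false-positive calls at the decision threshold drop 10.8 → 1.2 → 0.2
as `cost_fp` goes 1 → 5 → 10 (5 seeds), at the price of recall
(0.75 → 0.52). Note the knob shifts the operating point; it does not
improve the score *ranking* — at a threshold re-swept to fixed recall,
FP counts do not decrease.

### Out-of-bag error, prediction, persistence

Each instance is scored by majority vote of the trees whose bootstrap
did not contain it; the out-of-bag (oob) error is the resulting
misclassification rate. Prediction is majority vote over all trees; the
reported class probability is the vote fraction for the assigned label
(∈ [0.5, 1] by construction). Exact ties are resolved to the artifact
class (conservative somatic calling). Models are saved as a versioned
JSON archive (trees flattened to arrays, feature list, background
medians, hyperparameters, seed); identical inputs and seed give
byte-identical archives.

Feature ranking uses single-feature information gain with supervised
binary-threshold discretization (best midpoint threshold by exhaustive
prefix-sum search); ties in gain break alphabetically. Optional
training restrictions: top-k features by gain, and a tumor-VAF interval
filter for targeted (e.g. subclonal) training.

### Evaluation

Stratified k-fold cross-validation (default 10) pools out-of-fold vote
fractions and sweeps thresholds over the distinct score values
(tie groups move together). ROC AUC is the trapezoid integral, which
equals the normalized Mann–Whitney U statistic; PR AUC is the
step-wise average-precision sum Σ ΔR·P (a trapezoidal variant is also
reported); the PR endpoint at recall 0 takes the precision of the
highest-score group. Cohen's kappa uses the closed form with the
convention kappa = 0 when chance agreement is 1. Curves, threshold
tables and metrics are written as TSV/JSON (deterministic `%.10g`
formatting) plus a PNG plot.

## Calling and VCF output

Calling screens candidates identically, recomputes background medians
from the input pair, extracts features and classifies. Output is VCF
4.2 with INFO `SPV` (somatic Fisher p) and `CP` (class probability),
FILTER `PASS`/`REJ` (rejected candidates are retained for numerical
re-filtering), and per-sample `DP:AD:VAF` for NORMAL and TUMOR.
Records sort by contig appearance order, then position.

## Simulator

The simulator writes matched mpileup text directly (no BAM stage) so
every pipeline stage is testable without patient data. Per site, depth
is negative-binomial (variance = mean + mean²/dispersion, dispersion
default 20), drawn independently for tumor and normal. Each read
observation is an independent draw:

- errors occur with the configured per-base rate and carry the artifact
  signatures the features target: lower base quality (Normal(24, 7) vs.
  Normal(36, 4) for true bases), lower mapping quality (Normal(30, 12)
  vs. Normal(55, 5)), strand bias (a configurable fraction of sites,
  default 0.3, emits its errors on a single strand), and read-end
  enrichment (probability 0.5 of drawing the error's read position
  within 5 bp of an end);
- planted somatic SNVs appear in the tumor only, with per-site VAFs
  from an explicit list or a configurable range (default 0.16–0.58);
  planted germline heterozygotes appear in both samples at VAF 0.5;
- qualities are clipped to valid Phred range; output is byte-identical
  given the configuration and seed.

A truth table (TSV) records every planted site for labeling and
scoring, and a coverage-subsampling utility thins a pileup to a keep
fraction per read (Binomial thinning), mirroring down-sampling
experiments (e.g. 90X → 45X at fraction 0.5).

Named presets are study conditions fixed ahead of evaluation:

- `lowpass30x` — 20,000 sites, 30X, 1% error;
- `wgs90x` — 20,000 sites, 90X, 0.5% error;
- `training-cohort` — 53,000 sites, 30X, 3% error, 250 somatics
  (VAF 0.16–0.58). Sized from the measured screening rate
  (0.568 artifact candidates per site at these settings) to reproduce
  the reference training scale of ~250 true and ~30,000 false
  candidates;
- `imbalanced-test` — 100,000 sites, 30X, 1% error, 50 somatics
  (VAF 0.10–0.60): severe class imbalance for end-to-end evaluation.

### Simulator scope and limits

Observations are independent per read: there is no read-pair structure,
no shared error haplotypes, no mapping of reads across adjacent sites,
and no indel/homopolymer context. Error signatures are Gaussian and
site-independent, which makes separability configurable but means the
simulator cannot emulate systematic platform artifacts (e.g. motif-
driven errors) or contamination. Depths are independent between tumor
and normal (no shared capture bias). These limits are acceptable
because every feature is per-observation, so the simulator exercises
exactly the statistics the pipeline computes.

## Numerical conventions

- median-ratio epsilon: denominator `max(median, 1e-6)`;
- exact rank-sum enumeration below pooled n = 10, tie-free only;
- neutral imputation: empty rank-sum side → p = 1.0;
- prediction ties → artifact class; class probability ∈ [0.5, 1];
- features-per-node = `floor(log2 M) + 1`;
- PR curve: step-wise average precision; recall-0 endpoint from the
  top score group; ROC: trapezoid (≡ normalized U);
- kappa: 0 when expected agreement is 1;
- all persisted numbers use deterministic formatting; model archives
  and VCFs are byte-reproducible given seeds.

## Problem sizes and runtimes (single CPU)

Training-cohort scale (53,000 sites → ~30,300 candidates, 15 features):
simulation ~4 s, screening + background ~25 s, feature extraction
~30 s, 300-tree training ~9 s, 10-fold CV at 300 trees ~90 s. The
100,000-site imbalanced-test call phase runs in ~45 s. Streaming
screening keeps memory bounded (observations are slot-based and sites
are processed one at a time).

## Known limitations

- Screening requires the matched pair; tumor-only calling is out of
  scope.
- SNVs only; indel candidates are not generated.
- The rank-sum normal approximation is used from pooled n = 10, where
  it is still coarse; p-values there are features, not inferential
  claims.
- The read-length proxy (max observed offset) underestimates true read
  length at low depth, biasing `alt_read_pos_rel` upward slightly.
- Cost weighting changes the operating point, not ranking quality; use
  threshold selection on the class probability when a specific
  precision/recall trade-off is needed.
- Background medians need enough matched positions to be stable; with
  fewer than ~100 sampled positions a warning is logged.
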