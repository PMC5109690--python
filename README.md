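# snvforest

Cost-sensitive random-forest somatic SNV calling from matched
tumor/normal `samtools mpileup` files — built for low-pass sequencing,
where a subclonal variant supported by three reads and a sequencing
artifact supported by three reads look nearly identical.

## The problem and the model

Low-coverage tumor/normal pairs (order 10–30X) defeat purely
statistical somatic callers: at these depths the allele-count evidence
for a real subclonal variant is indistinguishable from recurrent
sequencing or mapping error. `snvforest` treats the problem as
supervised classification:

1. **Screen** candidate variants permissively from paired pileups:
   declared coverage ≥ 8X in both samples and at least one tumor read
   supporting the alternative allele with base quality ≥ 20 and mapping
   quality ≥ 10. Each candidate gets a two-sided Fisher's exact somatic
   p-value on its tumor/normal ref/alt counts. Optional BED tracks
   (known germline sites, blacklists) exclude regions.
2. **Describe** each candidate by 15 features in five groups: quality
   bias (alt base/mapping quality vs. the reference reads by rank-sum
   test, and vs. dataset-wide background medians), coverage and allele
   fraction, within-read position (read-end enrichment is an error
   signature), strand bias (Fisher test on strand counts), and
   site context (the somatic p-value, the number of distinct
   alternative alleles).
3. **Classify** with a bagged ensemble of 300 unpruned entropy decision
   trees, `floor(log2 15) + 1 = 4` candidate features per node.
   Class imbalance (training sets contain order 250 validated variants
   against 30,000 artifacts) is handled by cost-sensitive learning: a
   weighted bootstrap oversamples the class you penalize
   misclassifying. The out-of-bag error estimates generalization;
   stratified 10-fold cross-validation reports ROC/PR AUC and Cohen's
   kappa.
4. **Emit VCF** with the somatic p-value (`SPV`), the vote-fraction
   class probability (`CP` ∈ [0.5, 1]), and `PASS`/`REJ` filter status;
   rejected candidates are retained so downstream consumers can
   re-threshold numerically.

A matched-pileup **simulator** with configurable depth, error rate,
error quality/strand/read-end signatures, planted germline
heterozygotes and planted somatic SNVs (clonal or subclonal VAF)
generates ground-truthed data for every stage, so the full pipeline is
testable without patient data. See `docs/methods.md` for the complete
model description, numerical conventions and limitations.

## Input format

Pileups must be produced with mapping qualities and read positions
included, e.g.

```bash
samtools mpileup -s -O -f ref.fa tumor.bam  > tumor.mpileup
samtools mpileup -s -O -f ref.fa normal.bam > normal.mpileup
```

giving 8 tab-separated columns per line: chromosome, position,
reference base, depth, bases, base qualities, mapping qualities, and
comma-separated within-read positions.

## Worked example

Simulate an 8,000-site 30X pair with 40 planted somatic SNVs and 2%
error, train on it, and call it back:

```bash
$ snvforest simulate --n-sites 8000 --n-somatic 40 --error-rate 0.02 \
      --seed 7 --out-dir demo
wrote tumor.mpileup, normal.mpileup and truth table (40 planted sites)
```

In practice the training labels come from orthogonal validation
(e.g. re-sequencing of candidate loci); here the simulator's truth
table plays that role:

```python
from snvforest import (PipelineConfig, screen_candidates,
                       label_candidates, TruthTable)

truth = TruthTable.read_tsv("demo/truth.tsv")
candidates, _ = screen_candidates("demo/tumor.mpileup",
                                  "demo/normal.mpileup",
                                  PipelineConfig(seed=7))
labels = label_candidates(candidates, truth)   # {(chrom,pos,alt): "TP"/"FP"}
with open("demo/labels.tsv", "w") as fh:
    fh.write("chrom\tpos\talt\tlabel\n")
    for (c, p, a), l in sorted(labels.items()):
        fh.write(f"{c}\t{p}\t{a}\t{l}\n")
```

Train (the curves directory receives ROC/PR TSVs, a metrics JSON and a
plot):

```text
$ snvforest train --tumor demo/tumor.mpileup --normal demo/normal.mpileup \
      --labels demo/labels.tsv --model-out demo/model.json \
      --curves-dir demo/curves --seed 7
INFO snvforest.pipeline: screened 3138 candidate variants from 8000 matched loci
INFO snvforest.pipeline: training on 40 TP and 3098 FP labeled candidates
INFO snvforest.pipeline: oob error 0.0006; 10-fold CV ROC AUC 1.0000, PR AUC 0.9988, kappa 0.9740
model saved to demo/model.json
oob_error=0.0006 roc_auc=1.0000 pr_auc=0.9988 kappa=0.9740
```

Call:

```text
$ snvforest call --model demo/model.json --tumor demo/tumor.mpileup \
      --normal demo/normal.mpileup --vcf-out demo/calls.vcf --seed 7
INFO snvforest.pipeline: screened 3138 candidate variants from 8000 matched loci
wrote 3138 records (40 PASS) to demo/calls.vcf
```

All 40 PASS records are the 40 planted somatic SNVs (recall 1.00,
precision 1.00 on this easy self-call). A PASS record looks like:

```text
chr1  347  .  A  C  .  PASS  SPV=7.77154e-06;CP=1  DP:AD:VAF  41:0:0  38:14:0.368421
```

Both commands accept a YAML config file (`--config`); command-line
flags override file values and the override is logged. Identical
inputs and seeds give byte-identical model archives and VCFs.

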