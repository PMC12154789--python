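# cdhscan

Detection of large **chromosomal drive haplotypes** (CDHs) in maize from
low-coverage genotyping-by-sequencing (GBS) tag data: the Ab10 meiotic
drive haplotype of chromosome 10, its weaker relative K10L2, and the
supernumerary B chromosome. These selfish elements span megabases and
profoundly reshape genome evolution, yet they are invisible to standard
SNP pipelines because they live in repeat-rich, unalignable haplotypes.
`cdhscan` is for population geneticists who have GBS tag tables (e.g.
TASSEL TagsByTaxa output mapped to haplotype-bearing reference
assemblies) plus a panel of characterized control lines, and who want
presence/absence calls, relative copy number, and Ab10 type for
thousands of uncharacterized accessions — with downstream association
statistics against population structure, genetic modifiers and
environment.

## Method

**Tag index.** Counts are normalized to reads per million per sample.
Samples with more missing data than the cleanest blank (no-DNA) well
minus 0.001 are removed, as are tags with mapping quality < 20. In
non-overlapping 1 Mb bins the tag index is

```
index(bin, sample) = sqrt(c) + d
```

where *c* is the number of tags observed in the bin and *d* the sum of
their normalized depths. Each bin is then min/max scaled across samples,
which makes carrier/non-carrier contrast directly comparable between
bins.

**Control-anchored k-means calling.** Clustering is never trusted on
geometry alone. Each round draws roughly equal numbers of positive and
negative control lines, spikes in a small batch of experimental samples
(≤ 25% of controls for chromosome-10 CDHs, ≤ 10% for the B chromosome),
and runs k-means (k = 2) on the scaled diagnostic-bin vectors. A cluster
is named *positive* or *negative* only when ≥ 80% of its control members
share that status; a round in which any control lands in the wrong
cluster is redrawn. Every experimental sample is assayed 125 times, and
receives a final call only when ≥ 95% of its rounds agree — otherwise it
is *ambiguous*. Ab10 is called first and only Ab10-negative samples are
assayed for K10L2 (the K10L2 signal cannot be told apart from Ab10); the
B chromosome runs a high-copy stage before a low-copy stage so many-copy
samples cannot distort the clustering.

**Pseudo copy number.** A sample's mean unscaled tag index over a CDH's
diagnostic bins divided by its mean index over single-copy core-gene
bins (bins built from 1 Mb of cumulative gene *sequence*, not genomic
span). Heterozygous and homozygous chromosome-10 carriers separate at
the midpoint of the control means.

**Ab10 typing.** A 500-tree random forest trained on the scaled
diagnostic bins of typed control lines (70/30 stratified split) types
Ab10-positive samples; a call requires 65% of trees to agree, so
recombinant or novel haplotypes deliberately fall out as ambiguous. The
bins with highest mean decrease in Gini impurity feed a PCA for
exploring type variation.

**Association.** Hard genotype filters (call depth > 3 and < 20, GQ >
60, SNP MAF ≥ 0.05 and missingness ≤ 75%, then samples ≤ 10% missing),
top-10 principal components of the dosage matrix as structure
covariates, per-SNP logistic (presence/absence) or gaussian (log copy
number) regression against a 5×10⁻⁸ threshold, backward stepwise GLM
simplification at α = 0.01 (order-robustness asserted), and deviance
partitioning across structure / genetic / environment variable classes.

## Worked example

Everything is testable without downloads via the bundled simulator,
which emulates the statistical structure of a GBS experiment
(negative-binomial tag counts, log-normal library sizes, dosage-scaled
diagnostic bins, blank wells, characterized controls):

```
cdhscan simulate --out demo --seed 11 --n-experimental 8
cdhscan run --config demo_config.yaml        # or use the library API
```

The call table for the eight uncharacterized samples (excerpt):

```
sample_id   cdh     call  consensus_fraction  n_rounds
  exp_000  Ab10 positive                 1.0        25
  exp_001  Ab10 positive                 1.0        25
  exp_002  Ab10 negative                 1.0        25
  exp_000 K10L2  unknown                 0.0         0
  exp_006 K10L2 positive                 1.0        25
  exp_002     B positive                 1.0        25
```

`exp_000` is Ab10-positive, so it is never assayed for K10L2
(`unknown`): the K10L2 detector would fire on Ab10 as well. Every
decided call reached full consensus (fraction 1.0 over 25 rounds here;
the protocol default is 125).

Pseudo copy number and typing for the same run:

```
sample_id  cdh  pseudo_copy_number zygosity      sample_id call  vote_II
  exp_000 Ab10           13.32          hom        exp_000   II    0.770
  exp_003    B          111.43          n/a
  exp_005    B            0.012         n/a
```

`exp_003` carries many B chromosomes (true copy number 12 in this
simulation; the estimate is relative, not calibrated to absolute
copies), `exp_005` carries none, and `exp_000` is a homozygous Ab10
type II line (77% of trees vote II, clearing the 65% threshold).

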