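# Methods

This note documents the models, parameter choices and numerical
conventions behind `cdhscan`, and what the synthetic benchmarks do and
do not demonstrate.

## The tag index

GBS produces short tags at restriction-site-adjacent loci, so an extra
multi-megabase haplotype shows up two ways: more distinct tag sites, and
more reads over those sites. The per-bin statistic `sqrt(c) + d`
combines both. `d` is the sum of reads-per-million depths of the bin's
tags (RPM is computed per sample before anything else, so library size
cancels); `c` counts tags with nonzero depth in that sample. Counting
only observed tags (rather than all tags located in the bin) matters at
the margins: if `c` counted unobserved tags, a blank well and a true
non-carrier would have identical `c` over a diagnostic region and the
index could not separate low-signal cases. Both choices are exposed
(`count_mode="nonzero" | "all"`).

The square root deliberately compresses the site-count term so that
depth dominates for large signals while presence still registers at low
coverage. `sqrt(c)` is computed only at final bin granularity; `c` and
`d` individually recombine exactly across bin splits (property-tested
against a per-tag brute-force oracle).

Filtering order is: RPM → blank-derived missingness cutoff (minimum
blank missingness − 0.001; blanks carry only sequencing background) →
sample removal → tag removal at mapping quality < 20 (a tag at exactly
20 is kept) → binning → per-bin min/max scaling across samples.
Missingness is computed before the mapq filter (switchable). Scaling is
row-wise (per bin): the caller compares samples within a bin, and
per-sample scaling would erase exactly that contrast. Constant bins
scale to 0, never NaN, so clustering never sees missing values.

Single-copy-gene bins accumulate 1 Mb of covered gene sequence, not
genomic distance, emitting a final partial bin only when at least half
full — this keeps the copy-number denominator comparable across genomic
regions of very different gene density.

## Control-anchored calling

Tunable parameters (defaults = the published protocol):

| parameter | default | meaning |
|---|---|---|
| purity | 0.80 | min fraction of a cluster's controls sharing a status for the cluster to be named |
| rounds | 125 | valid clustering rounds per experimental sample |
| consensus | 0.95 | min majority fraction for a non-ambiguous call |
| spike fraction | 0.25 (chr10) / 0.10 (B) | experimental samples per round, as a fraction of controls drawn |
| retry cap | 50 | control redraws before a round is abandoned |
| k-means restarts | 10 | random initializations per clustering |

Cluster naming uses control members only; experimental samples can
never influence a label. A round is valid only when one cluster is
named positive and the other negative and every control sits in the
cluster named its own status; invalid rounds are redrawn with fresh
controls and do not count toward the 125. "Roughly equal" control
numbers are implemented as `min(n_pos, n_neg)` drawn from each side.
k-means is Euclidean on the scaled diagnostic-bin vectors (scikit-learn,
seeded); none of this is pinned down by the protocol, so all of it is
config-exposed.

Chromosome-10 calling uses low-copy (heterozygous) positive controls by
default, since natural carriers are overwhelmingly heterozygous;
homozygous controls are used for validation and zygosity calibration.
Ab10-ambiguous samples are excluded from the K10L2 stage by default
(switchable): a sample that might carry Ab10 cannot be scored by a
detector that fires on Ab10.

Determinism: one master seed spawns per-stage sub-seeds through
`numpy.random.SeedSequence`, every k-means restart seed is drawn from
the stage stream, and two runs with the same config are byte-identical
(tested on full-pipeline checksums).

## Pseudo copy number and zygosity

Copy number uses the *unscaled* index — min/max scaling destroys ratio
meaning. Both numerator (mean over a CDH's diagnostic bins) and
denominator (mean over single-copy bins) are simple averages; the
estimate is explicitly relative ("pseudo"): B chromosome control copy
numbers are unknown in practice, so no absolute calibration is
attempted, and values are never rounded to integers. A typed Ab10
carrier has signal only in its own type's bins, so its pseudo copy
number sits below the naive dosage expectation by the fraction of
other-type bins in the average; the het/hom ratio is unaffected.
Zygosity thresholds at the midpoint of the het- and hom-control means —
the simplest separator consistent with perfect control classification —
and is reported only for carriers. A sample with a zero single-copy
mean gets NaN and zygosity `unknown` rather than an exception.

## Ab10 typing

Random forest: 500 trees, sqrt-features per split, unlimited depth
(standard defaults; the protocol specifies none), trained on the scaled
Ab10 diagnostic bins of typed controls with a stratified 70/30 split.
Votes are fractions of trees, computed per tree (not averaged
probabilities); the 65% call threshold is inclusive at the boundary and
taken as given rather than optimized. Mixed-signature vectors — the
synthetic analogue of recombinant haplotypes — fall below threshold by
construction, which is the intended behaviour, not a failure mode.
Gini-PCA ranks bins by mean decrease in Gini impurity and takes the top
25 by default (unspecified in the protocol; exposed in config).

## Association statistics

Genotype hard filters follow the published cutoffs with strict
inequalities: a call at depth exactly 3 or 20, or GQ exactly 60, is
removed. MAF is recomputed after sample removal and re-applied. The
homology/transposable-element SNP screen is consumed as a precomputed
exclusion list — recomputing it requires external aligners and genome
assemblies. Imputation is likewise external; the synthetic genotypes
are complete.

Structure PCs come from an SVD of the centered dosage matrix
(mean-imputed for the PCA only). The per-SNP model is
`phenotype ~ dosage + PC1..10` with a Wald test on the dosage term
(Wald rather than likelihood-ratio is the simplest reading of the
protocol; an LRT would be a drop-in change). Monomorphic SNPs are
skipped with a flag; unstable or non-converged fits are flagged, never
silently dropped. Multi-allelic sites are first tested with each
alternate allele as its own term; non-significant minor alternates are
removed and the remainder coded additively.

Stepwise simplification drops the single worst term with p > 0.01 per
refit, ties broken by name-sorted column order so the procedure is
deterministic; complete cases are taken once up front so the null
deviance is identical across refits. Order robustness is asserted by
re-running under shuffled variable orders. Deviance partitioning refits
each variable class alone on the identical sample set; partitions share
variation and are *not* expected to sum to the full model. The GLM
engine is statsmodels IRLS run at a tightened tolerance (1e-12) so
results agree with a textbook Newton–Raphson oracle to 6 decimals.

## The synthetic data model

Counts are Gamma–Poisson (negative binomial, variance m + φm²; default
dispersion φ = 0.3) around a mean combining: baseline depth (20
reads/tag), a log-normal library factor (σ = 0.3), and a dosage factor —
`dosage_effect × copies` (default 10 per copy) inside a carrier's
diagnostic bins, a mis-mapping background of 0.01 for non-carriers
(real negative controls show nonzero diagnostic signal, so the
background is deliberately not exactly zero). GBS depth is
overdispersed in practice, hence the negative binomial; the protocol
itself states no count model. Tag density defaults to 30 tags/Mb — a
configurable, admittedly arbitrary choice, as real GBS density depends
on the restriction enzyme. Random dropout (5%) models unobserved tags;
blanks draw a uniform low-count contaminant at 2% of tags so their
missingness strictly exceeds every real sample's, which guarantees the
blank-derived cutoff removes no real samples by construction.

Haplotype-specific structure: Ab10 carriers also produce signal in the
K10L2 diagnostic bins (shared sequence), which is what forces — and
lets us test — the sequential chromosome-10 workflow. Ab10 types are
encoded as disjoint subsets of diagnostic bins (a dominant shared core
plus one signature group per type), mirroring types that differ in knob
appearance rather than in most of the haplotype span. B copies run 0–14.
Positive control lines are characterized for their own CDH only;
dedicated negative lines are known negative for all.

The association generator draws genotypes from a k-population admixture
model with Balding–Nichols allele-frequency divergence (Fst 0.1),
environment variables correlated with admixture (r ≈ 0.6), and a binary
phenotype from a logistic model over planted effects; causal SNPs get
equal frequency across populations so their effect is not confounded
with structure.

**What passing tests show, and what they do not.** The simulator
produces strong, clean separation (dosage effect 10); perfect control
discrimination and typing on it demonstrate that the machinery is
correct, not that real GBS data of arbitrary quality will separate as
well. It does not model restriction-site polymorphism, GC or enzyme
bias, batch effects between sequencing providers, partial haplotype
recombinants beyond mixed type signatures, or linkage between the SNP
panel and the CDHs. Benchmark problem sizes (e.g. 20+20 controls per
CDH, 100 validation repetitions, 200-sample copy-number cohorts, 50
GWAS power replicates at n = 2000) were chosen as the smallest designs
that exercise every code path with stable statistics.

## Known limitations

- Calling is always anchored to labeled controls; there is no de novo
  discovery of unknown drive haplotypes.
- The K10L2 detector cannot distinguish K10L2 from Ab10; K10L2 status
  of Ab10-positive samples is structurally unknown.
- Pseudo copy number is relative; comparing it across datasets with
  different tag densities or bin definitions is not meaningful.
- No kinship/mixed-model GWAS: structure correction is fixed PCs only.
- Typing is closed-set over types I/II/III; novel or recombinant
  haplotypes are reported as ambiguous by design.
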