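# Methods

## The analysis

`triodnv` analyses whole-genome-sequenced parent–offspring trios in
which the child is affected by a complex disease. The object of
inference is the set of de novo variants (DNVs) — child alleles absent
from both parental genomes — and whether they concentrate in functional
genomic compartments of patients relative to a population control
cohort of healthy-trio DNVs.

### DNV calling and filtering

A candidate is any biallelic site where the child carries an alternate
allele seen in neither parental genotype. Only the child-heterozygous /
parents-homozygous-reference pattern is accepted by default; other
Mendelian-violation patterns (e.g. child hom-alt with hom-ref parents)
are overwhelmingly genotyping artifacts at ~30x short-read coverage and
are tallied but excluded (configurable). Sites with a missing parental
genotype are skipped and counted.

Three filters then apply, each stored as an independent named flag so
their order is irrelevant:

| filter | rule | default |
|---|---|---|
| quality | min genotype-posterior quality over the trio, phred | ≥ Q20 |
| allele balance | child alt reads / total reads, bounds inclusive | 0.30–0.70 |
| score | external per-variant classifier score (optional hook) | ≥ 0.5 |

The score is deliberately an *input column*, not a model: gradient-
boosting DNV classifiers are trained on external trio data and their
features are not part of this package; any score in [0, 1] keyed by
variant can be plugged in, and calls without a score pass.

The allele-balance bounds are taken as inclusive; "between 30 and 70%"
does not determine inclusivity, and the inclusive choice is the one a
threshold on a count ratio naturally implements. Validation FDR is
`100 · (tested − confirmed) / tested` over assays that produced a
result.

### Annotation

Gene-position classes use annotator-style precedence exon > UTR5 > UTR3
> upstream > downstream > intron > intergenic, with "upstream" meaning
within W bp 5′ of a transcription start site respecting strand
(W = 1000 by default; annotator convention, configurable). Chromatin
states (Promoter / Enhancer / Other) come from a segmentation track;
uncovered bases default to Other, and a single Promoter label is used
rather than merging flanking states. DHS overlap is boolean; the TFBS
feature counts how many binding-site intervals stack over the position,
with ≥ 10 as the "TFBS-rich" cutoff used in enrichment.

The GC exclusion removes variants lying in 100 bp tiles (non-
overlapping, anchored at coordinate 0) whose GC fraction is ≥ 0.75 —
"at least 75%" makes the boundary inclusive — or inside a supplied
"difficult promoter" list. It is applied to case and control cohorts
symmetrically before any enrichment test, because GC-rich regions are
differentially accessible to different library preparations. Tiling
(rather than sliding windows) makes the map position→window stable and
reproducible.

Non-synonymous status is computed only when a CDS-bearing gene model
and reference sequence are available: the variant's codon is located
via the exon structure (strand-aware), translated before and after
substitution. Otherwise the column may be supplied precomputed.

Interval queries are vectorised `numpy.searchsorted` operations over
sorted start/end arrays (counting overlaps as
`#starts ≤ pos − #ends ≤ pos`), which keeps thousand-replicate
simulation studies inside a test budget without an interval-tree
dependency.

### Enrichment statistics

For a feature with `a` of `n1` case DNVs and `b` of `n2` control DNVs,
the primary statistic is the **ratio of proportions**
`R = (a/n1)/(b/n2)`. The classical cross-product odds ratio
`(a/(n1−a))/(b/(n2−b))` is emitted alongside; for rare features the two
are nearly identical, and the ratio of proportions is the quantity the
expected-excess formula inverts. Significance is Pearson's chi-squared
test with 1 df on the 2×2 table (Yates' correction available), with
Bonferroni adjustment `min(1, m·p)` over the m = 13 standard feature
tests (five gene-position classes, two chromatin states, nsSNV,
TFBS ≥ 10, DHS, and the three promoter composites).

Two projections translate an enrichment into cohort terms:

* **expected excess** `E = a − a/R`: the number of case DNVs above what
  the control rate predicts (0 at R = 1, increasing in R, bounded by a);
* **occupancy**: distributing k excess variants uniformly at random
  over T patients, each patient carries ≥ 1 with probability
  `1 − (1 − 1/T)^k`, and `T` times that is the expected carrier count.
  Reported counts are rounded to the nearest integer; the unrounded
  frequency is reported as well since the two do not always agree at
  two decimals.

A known caveat: with cohort-scale counts the chi-squared p-values this
package computes can differ in the second significant digit from
previously published analyses of the same printed counts (whose exact
filtered totals are not recoverable); the package reports its own
p-values and makes no attempt to force agreement.

### Parent of origin and paternal age

A DNV is phased through an *informative site*: a child-heterozygous SNV
near the DNV whose alleles map uniquely onto the parents (at least one
parent homozygous, the configuration Mendelian-consistent). Each
sequencing read carrying the de novo allele and covering an informative
site votes for the parent whose transmitted allele it shows. An origin
is assigned only with ≥ 2 votes for one parent and **zero** for the
other — any opposing vote voids the assignment. The strict conflict
rule is a design choice: the published procedure specifies only the
two-read minimum, and strictness matches its evident preference for
specificity. The informative-site search window defaults to 500 bp
(a read-pair span at typical insert sizes); spanning evidence may come
from single reads or read pairs — the evidence table does not
distinguish them.

Per-child DNV counts are regressed on the father's age at conception by
unweighted OLS (the named method), marginally and jointly with the
mother's age; the marginal slope, Pearson r and its t-test p, and the
conditional paternal slope are reported.

### De novo structural variants

Neither germline SV caller emits de novo calls, so de novo SVs are
isolated by four ordered, individually auditable filters on calls
> 10 bp:

1. **consensus** — reported by both callers, same type, ≥ 50% reciprocal
   overlap (both fractions, inclusive). Pairing is greedy by the
   smaller overlap fraction, ties broken by smaller start; each call is
   used once. The caller-A interval (breakpoint-precise assembly-based
   callers give exact coordinates) is the canonical merged interval.
2. **parental subtraction** — any same-type record in either parent at
   the same overlap threshold removes the candidate, counting
   low-confidence candidate-level records as well as confident calls.
3. **annotation** — removal when the covered fraction of the interval
   by any exclusion track (blacklist, low mappability, segmental
   duplication, repeats) exceeds φ = 0.5.
4. **coverage** — the binned read-depth profile over the interval plus
   flanks must not correlate at ρ ≥ 0.9 with either parent's profile; a
   genuine de novo deletion halves the child's interior depth and
   breaks the similarity, while a shared artifact reproduces the same
   pattern in a parent. "Similar pattern" is not defined numerically in
   the source procedure; Pearson correlation of binned depth is this
   package's interpretation, isolated in one function
   (`coverage_similarity_filter`) so it can be replaced. Constant
   profiles make the correlation undefined; such candidates are kept
   with a warning. φ and ρ are explicit configuration, as the original
   filtering thresholds are not published.

Each candidate retains a filter trail; removal is attributable to
exactly one first-failing stage. The trail replaces interactive
genome-browser review with an auditable record.

Coordinates and lengths: intervals are 0-based half-open internally;
the canonical SV length follows the HGVS genomic-deletion convention
(both end bases counted), i.e. `span + 1` for DEL/DUP/INV, which
matches how such variants are reported in clinical notation.

### Multiallelic sites

VCF sites with several ALT alleles are decomposed into biallelic
records (per-allele genotype projection); DNV logic is defined per alt
allele. A config flag skips them instead. This is a package choice —
upstream pipelines differ and the original handling is not recorded.

## The synthetic-data generator

`triodnv.synth` emulates the study design so that every stage is
testable without external data. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_trios | 71 | affected-child trios |
| base_rate λ₀ | 6.7 | DNVs/child at age 0 (see below) |
| age_slope β | 1.56 | DNVs per year of paternal age |
| father ages | uniform 22–45 | mother's age correlated (r ≈ 0.9) |
| paternal_fraction | 0.8 | ~4:1 paternal:maternal origins |
| depth_mean | 30 | sequencing depth; alt count ~ Binomial(depth, ½) |
| control_size | 97,942 | control-cohort DNVs (from a 1548-trio study) |
| genome | 2 Mb, 2 chromosomes, 60 genes | desk-scale layout |

Counts are Poisson with mean `λ₀ + β·father_age`; λ₀ is calibrated so
the cohort mean is ~59 DNVs/child at the mean paternal age — the two
published anchors are the mean count and the slope, not the intercept.
DNV positions are drawn from a per-base weight grid in which each
feature multiplies its bases' weight by a configurable factor. Note
that a multiplier m on a feature of weight-fraction f implies an exact
case:control proportion ratio `m/(1 + (m−1)f)`, slightly below m;
`SyntheticTracks.expected_enrichment_ratio` returns the exact implied
value (optionally conditioned on surviving the GC filter), and recovery
tests target that, not the raw multiplier. Likewise, because alt counts
are Binomial(depth, ½), a computable tail of true DNVs fails the
allele-balance filter; `expected_acceptance_probability` returns the
exact per-variant acceptance probability (≈ 0.97 at the defaults), and
the expected slope of *accepted* counts is β times it.

Phasing evidence is emitted directly as read observations (read id,
sample, position:allele pairs) rather than via simulated FASTQ and
alignment — the pipeline consumes evidence, not raw reads. The ground-
truth ledger records each planted event with its expected pipeline fate
*derived from the emitted data* (e.g. a DNV whose sampled allele
balance landed outside 30–70% is expected to fail that filter), so
ledger-vs-pipeline audits are exact under any noise setting.

What the generator does **not** emulate: sequencing error and base
qualities, mosaic variants, population haplotype structure,
recombination, overlapping genes and alternative transcripts,
GC-dependent coverage bias, and caller-specific error modes beyond
breakpoint jitter and planted decoy categories. Passing tests therefore
demonstrate the pipeline's logic and statistical calibration, not its
robustness to raw-data artifacts.

## Test and simulation sizes

Unit tests run on a reduced genome (600 kb, 18 genes, 8 trios).
Statistical acceptance checks use: 200 cohort replicates of 71 trios
for age-slope CI coverage (nominal 95% coverage asserted at a
three-sigma binomial bound, ≥ 181/200); 100 replicates for paternal-
origin and promoter-enrichment recovery (case 4,000 / control 8,000
positions per replicate — control sets are scaled down from 97,942 for
the replicate loops); and 1,000 simulated null cohorts of 2,000 + 2,000
DNVs for type-I calibration of the chi-squared test (expected ~5%
of tests at p < 0.05). All simulations are seeded and deterministic.

## Known limitations

* The chi-squared test is asymptotic; rare features in small cohorts
  should use the Yates-corrected variant or larger simulated cohorts.
* Nearest-gene assignment uses span distance and one span per gene;
  overlapping or multi-isoform loci are resolved arbitrarily.
* The SV coverage filter assumes depth proportional to copy number in
  clean intervals; heavily noisy or GC-biased coverage will reduce its
  specificity, and the ρ threshold should be tuned on real data.
* Parent-of-origin phasing requires informative sites within the
  search window; its yield on real data depends on heterozygosity and
  insert size, neither of which the generator models in detail.
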