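# Methods

## Data model

Methylation is a sites × samples matrix of percentages in [0, 100] with
a parallel integer coverage matrix; a value is missing (NaN) exactly
when coverage is 0. Genotypes are a SNPs × samples matrix of additive
dosages in {0, 1, 2, NaN}. Samples are organised into father–mother–
child trios; every sample belongs to exactly one trio.

## Methylation states and the epiallele transmission model

Each (CpG, sample) value is categorised as

* **U** (unmethylated): value ≤ 20,
* **M** (methylated): value ≥ 80,
* **I** (intermediate): strictly between.

Each state corresponds to a diploid epiallele pair — M = (m, m),
I = (m, u), U = (u, u) — and the count of methylated epialleles is an
additive dosage in {0, 1, 2}. A child's state is *compatible* with its
parents when it can be assembled from one epiallele drawn from each
parent, exactly Mendelian transmission of a biallelic locus. Brute
enumeration of gametes shows 15 of the 27 ordered
(father, mother, child) state triples are compatible; the package
exposes the full truth table and a fast lookup.

## CpG quality filters

Applied in fixed order, each site attributed to the *first* failing
stage so stage counts sum exactly to the total removed:

1. **non_autosome** — keep chromosomes matching `^(chr)?\d+$`.
2. **snp_overlap** — drop CpGs with a known SNP on either the C or the
   G base.
3. **missing_data** — require ≥ 3 families with complete (all-observed)
   trios at the site.
4. **imprinted** — drop CpGs inside known imprinted regions.
5. **low_coverage** — drop CpGs whose total reads across samples fall
   below 10 × n_samples (120 reads for 12 samples, i.e. mean < 10×).

SNPs are filtered for per-SNP missingness (≤ 2%) and Mendelian
consistency of dosage transmission in every complete family.

## Mendelian CpG selection

A filtered CpG is selected when (a) in at least one family the parents
differ by **more than** 20 percentage points, and (b) the state triple
is compatible in **every** complete family. Criterion (a) ensures the
site is informative (a child of identical parents carries no
transmission signal); criterion (b) is the inheritance test itself.

## mQTL exclusion scan

For every (CpG, SNP) pair the package fits ordinary least squares of
methylation percentage on additive dosage over samples observed for
both, and tests the slope with a t statistic on n − 2 degrees of
freedom. The significance threshold is Bonferroni:
alpha / (n_CpGs × n_SNPs) — e.g. 0.05 over 1,583,717 CpGs ×
6,056,211 SNPs ≈ 5 × 10⁻¹⁵. A pair is **cis** when CpG and SNP share a
chromosome at distance < 1 Mb, otherwise **trans**; a CpG with any cis
hit is labelled cis_explained (cis takes precedence), one with only
trans hits trans_explained, and the remainder are the candidate
**heritable epialleles**. The three verdicts partition the Mendelian
set, so `heritable = mendelian − cis − trans` holds exactly in the
ledger.

The scan is vectorised with masked matrix products over blocks of 512
CpGs. Degeneracy guards are relative — a predictor or response is
untestable when its centred sum of squares falls below 1e-10 × (raw sum
of squares + 1) or fewer than 3 paired observations remain — and a
residual sum of squares ≤ 1e-10 × total sum of squares is treated as a
perfect fit (p = 0). A scalar closed form (t = r·√((n−2)/(1−r²)))
serves as an independent oracle in the tests and agrees to 12
significant digits.

## Genomic annotation

* **Distance to nearest** interval uses covered-base semantics: 0 when
  the position lies inside an interval, otherwise base pairs to the
  closest covered base; NaN when the chromosome has no intervals.
* **Island context**: island (distance 0), shore (0 < d < 2000), shelf
  (2000 ≤ d ≤ 4000), open sea (d > 4000) — a partition of [0, ∞).
* **Gene context** with precedence promoter > exon > intron >
  intergenic; the promoter is the 2 kb upstream of the TSS,
  strand-aware.
* **Chromatin states** are aggregated from 15 segmentation labels into
  7 groups (Promoter, Poised Promoter, Enhancer, Insulator,
  Transcription, Polycomb repressed, Heterochromatin/low
  signal/Repetitive/CNV).

## Flanking scenarios

For each index CpG the package examines flanking CpGs within 1 kb on
each side, using the cross-sample mean state. A side is a *methylated
region* when strictly more than 80% of ≥ 3 observed flanking CpGs are
methylated (symmetrically for unmethylated). Scenarios:

* **A** — methylated index inside a methylated region,
* **B** — unmethylated index inside an unmethylated region,
* **C** — unmethylated index inside a methylated region,
* **D** — methylated index inside an unmethylated region,
* **E** — index at a methylation transition (one side methylated, the
  other unmethylated, any index state),
* **unclassified** otherwise (insufficient flanking CpGs, impure
  flanks, or an intermediate index inside a uniform region).

Flank GC content is counted over the combined two 1 kb windows,
excluding the index base and truncating at chromosome ends.

## Subject clustering

Hierarchical clustering (complete linkage by default) on Euclidean
distances over CpGs observed in all samples, with Newick export using
merge heights as node heights.

## Synthetic cohort generator

Defaults model the target study design: **4 trios** (12 samples),
Poisson mean coverage **12×**, binomially sampled methylated reads,
latent noise SD 5, 1% missing methylation calls, and zero genotype
missingness (genotypes are treated as imputed). Two 3 Mb chromosomes
carry stable CpGs in 20-CpG domains at 100 bp spacing whose kinds cycle
open-sea / island / open-sea / boundary; boundary domains are half
island, half open sea, planting genuine scenario-E transitions.
Islands are GC-rich (0.70 vs 0.40), a CG dinucleotide is stamped at
every CpG position, imprinted regions sit in the chromosome tails, and
genes with exon models are laid out at fixed slots.

Planted classes: **stable** (3% or 95% by island membership),
**cis_mqtl** / **trans_mqtl** (methylation = 50 × dosage of a driver
SNP placed 5–400 kb away on the same chromosome, or on the other
chromosome), **heritable_epiallele** (founders carry two Bernoulli(1/2)
epialleles, children inherit one per parent, methylation = 50 ×
dosage), **non_mendelian** (independent per-sample states) and
**imprinted** (uniform 50%). Background SNPs avoid CpG bases; driver
SNPs are redrawn until polymorphic. The truth table records every
CpG's class, driver SNP and founder epialleles for evaluation.

At the default 12× coverage the pipeline behaves like real shallow WGBS
— binomial noise pushes stable CpGs past the parental-variability
criterion and chance genotype correlations at n = 12 both remove true
heritable CpGs and admit false ones. At ≥ 100× coverage and low noise
it recovers ≥ 95% of planted heritable epialleles and removes 100% of
planted mQTLs (see the acceptance tests). Even in the noiseless limit a
founder epiallele can be collinear with a genotyped SNP by chance, so
perfect sensitivity is not attainable in principle.

## Limitations

* The generator plants ideal additive mQTLs and pure epialleles; no
  partial effects, haplotype structure, linkage disequilibrium or
  cell-composition confounding.
* The mQTL scan assumes independence across tests (Bonferroni) and a
  linear additive model.
* Imprinted regions are removed by annotation, not detected from
  parent-of-origin asymmetry.
* No sex chromosomes are modelled; the autosome filter is exercised
  only through hand-built fixtures.
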