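# Methods

## Scope and data model

The pipeline analyses one case-control cohort at a time (a rare-variant
genotyping chip cohort, an exome cohort, or a combined run restricted to
the variants shared by both platforms). A cohort is a sample × variant
alternate-allele dosage matrix ({0, 1, 2, missing}) joined to a curated
variant annotation (gene, consequence, reference-panel MAFs, pathogenicity
curation class), a phenotype table and gene-level CNV calls. Variant
identity is `chrom:pos:ref:alt` after multi-allelic splitting; rsIDs are
annotation only. Half-calls and non-diploid genotypes map to missing —
the target platforms emit diploid calls, so anything else is treated as a
failed call rather than guessed at.

The gene panel is ten Mendelian PD genes plus *GBA*: dominant *SNCA*,
*LRRK2*, *VPS35*, *EIF4G1*; recessive *PARK2*, *PINK1*, *PARK7*,
*ATP13A2*, *FBXO7*, *PLA2G6*; *GBA* always carries mode `risk` and is
tabulated separately from the Mendelian genes. The panel is configurable,
but *GBA* may not be given a Mendelian mode.

## Filtering

Retained variants satisfy, in fixed order: gene in panel; consequence not
synonymous; MAF < 1% (default) in **every** reference panel where the
variant is observed, with a variant unobserved in all panels treated as
rare; variant missingness ≤ 5%; then samples with > 5% missingness over
the retained variants are removed. One pass each, variant level before
sample level — the two thresholds are stated without iteration, and a
fixed order keeps results deterministic. Sample missingness is computed
over the panel variants only (the genome-wide call rate is not an input).
Cohort-internal allele frequency is deliberately not used for the rarity
filter: only external reference panels define "rare".

Curated pathogenic variants that fail the MAF filter are retained so that
primary-mutation detection does not depend on population frequency, but
they are flagged ineligible for additional-variant counting. CNV calls
spanning fewer than 10 probes are rejected at read time; visual/MLPA
validation flags are carried but not required.

## Classification

A case is **known-mutation PD** iff it carries ≥ 1 curated pathogenic
allele in a dominant-mode gene, or a total pathogenic allele load ≥ 2 in
some recessive-mode gene, where load = pathogenic SNV dosage + CNV loss
alleles (max(0, 2 − copy number)) + CNV gain alleles for genes explicitly
listed in `pathogenic_gains` (default empty — no gain-as-pathogenic rule
is assumed for recessive genes). Two heterozygous pathogenic variants in
one recessive gene are assumed in trans: chip and exome data cannot phase,
and compound heterozygosity is the standard reading of such genotypes in
this setting. A monoallelic pathogenic recessive allele does not confer
known-mutation status, and counts as one additional variant downstream.
Controls are controls regardless of genotype. If a sample carries two
independent qualifying causes, all qualifying alleles are recorded as
primary and excluded from additional counts.

**Additional variants** are counted with the sample's primary alleles
zeroed out: the variant count is the number of eligible sites with dosage
≥ 1, the allele count the dosage sum over them. Both are exposed because
the convention for homozygous unknown variants (once or twice) is
genuinely open; the fixture plans plant additional variants as
heterozygous sites so the two counts coincide there. Mendelian and *GBA*
counts never share a site. CNVs contribute to primary classification
only, not to additional counts. A sample is flagged a GD heterozygote iff
it carries exactly one GD-causing *GBA* allele and no second
pathogenic/GD *GBA* allele.

## Statistics

* Carrier and allele-sum burden: logistic regression of group membership
  on the predictor plus covariates (statsmodels), Wald 95% CI and p.
  Covariates are named phenotype columns: `sex`, `pc1..pcK`,
  `capture1..M` (exome), `platform` (combined runs). The unadjusted
  cross-product OR is always reported; it is left undefined (NA, rendered
  `0 –` in tables) when any cell of the 2×2 table is zero, with no
  continuity correction. Separation, non-convergence and collinearity are
  detected and flagged, never silently corrected (no Firth penalisation).
* Gene-subset enrichment: two-sided Fisher's exact test (scipy) on the
  2×2 carrier table, carrier meaning ≥ 1 additional variant in any gene
  of the subset. Tests confirm exact agreement with a full hypergeometric
  enumeration oracle on small tables.
* AAO: OLS of age at onset on the carrier indicator plus covariates,
  within one case group. With no covariates the coefficient equals the
  difference of group means exactly. Samples missing AAO are excluded and
  counted. An allele-count predictor is available behind a flag.
* FDR: Benjamini–Hochberg step-up across the family of comparisons
  requested in one run — the analysis does not enumerate a canonical
  family, so the family is whatever the config asks for, which matches
  reporting an adjusted p next to each raw p.
* Sensitivity re-runs drop listed variant keys from additional-variant
  eligibility and recompute the requested analyses; primary
  classification is untouched.

## Synthetic cohorts

`simulate` draws genotypes per variant as Binomial(2, f) with f the
annotated MAF, log-uniform on [10⁻⁴, 10⁻²) by default — a plausible
rare-variant spectrum below the 1% filter. Primary mutations are planted
in a configured number of cases (dominant het alleles; biallelic
recessive genotypes alternating homozygous/compound-het, with a
configurable number via SNV + CNV loss to exercise that path). For
known-mutation cases the per-allele odds of each unknown Mendelian-gene
variant are multiplied by the enrichment OR (default 1.70, the chip
cohort's allele-sum estimate). *GBA* carriage is controlled per group
(defaults 7.9% / 8.6% / 4.6% for known / other cases / controls, the chip
cohort's carrier rates) by converting the target carrier probability p
into a per-variant allele frequency q with 1 − (1 − q)^(2m) = p. AAO is
Normal(61.5, 10) years plus additive carrier shifts (defaults −3.78 y for
Mendelian carriers and −2.10 y for *GBA* carriers, the two reported
coefficients); sexes are Bernoulli draws and PCs pure noise. The
simulator therefore emulates marginal carrier structure, not LD,
population substructure or per-gene mutation spectra — passing recovery
tests shows the estimators are unbiased and calibrated under the assumed
sampling model, not that real cohorts meet those assumptions.

`build_fixture` is randomness-free: a plan lists blocks of identical
samples (group, primary cause, additional-variant genes, *GBA* alleles,
AAO), and the builder materialises minimal heterozygous genotypes so the
full pipeline reproduces the planned tallies exactly. `oligopd.plans`
encodes the published count distributions of both study cohorts and the
combined G2019S subset. Where the publication leaves a choice open (gene
assignment of unlabelled carriers, which samples lack AAO), the plans make
an arbitrary deterministic assignment that preserves every printed margin;
AAO cells that overlap between the Mendelian and *GBA* categories cannot
all be exact simultaneously, so the plans keep the two carrier sets
disjoint and make the headline cells exact (known-mutation Mendelian
with/without, other-case *GBA* with/without).

## Numerical choices and problem sizes

Wald CIs use z = 1.96; logistic fits run Newton iterations to 200 with
non-convergence flagged; a carrier-coefficient SE above 50 is treated as
separation. BH adjustment passes NaN p-values through without counting
them toward the family size. Determinism: all randomness flows from a
single integer seed through `numpy.random.default_rng`; the same seed
gives byte-identical simulated cohorts, and a pipeline re-run on identical
inputs gives a byte-identical result bundle (the manifest hashes config
and inputs and carries no timestamps).

Simulation studies in the tests and acceptance script use 100 replicates
at 10,000 + 10,000 samples for enrichment-OR recovery, 30 replicates of
5,000 cases for AAO-shift recovery, and 1,000 null replicates at
1,000 + 1,000 samples for type-I calibration — sizes chosen so
Monte-Carlo error is small relative to the tolerances being checked while
a full run stays in the minutes range on one CPU.

## Known limitations

No Hardy–Weinberg or batch-effect QC, no imputation, no phasing, no
region-based (SKAT-style) tests, no penetrance or pedigree modelling. PCA
computation and CNV calling are out of scope: PCs and CNV calls are
consumed as inputs. Adjusted ORs and p-values depend on the covariate
distributions of the underlying individual-level data; on fixture cohorts
(which carry null covariates) they numerically approach the unadjusted
estimates, and only the unadjusted quantities and printed proportions are
treated as reproduction targets.
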