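# oligopd

Oligogenic rare-variant burden analysis in Mendelian Parkinson's disease
(PD) genes and *GBA*.

A small fraction of PD cases carry a recognised high-penetrance primary
cause — a pathogenic dominant allele (e.g. *LRRK2* G2019S) or biallelic
recessive alleles/CNVs (e.g. *PARK2*). The question this package addresses
is whether such **known-mutation PD** cases carry an excess of *additional*
rare variants in the other Mendelian PD genes, separate from their primary
mutation — evidence for oligogenic inheritance — and whether those
additional variants modify age at onset (AAO). *GBA*, whose heterozygous
variants raise PD risk without being a Mendelian cause, is tracked
separately throughout.

The pipeline is aimed at statistical geneticists working with case-control
genotype panels (rare-variant genotyping chips or exome sequencing): it
consumes VCF genotypes, a curated variant-annotation panel, a phenotype
table and gene-level CNV calls, and produces carrier-count distributions,
burden tests, gene-subset enrichments and AAO regressions.

## Model

For each sample *i*, after restricting to rare (reference-panel MAF < 1%),
non-synonymous variants in the gene panel and excluding the sample's
primary-mutation alleles, let *c*ᵢ = 1 if the sample carries ≥ 1 additional
variant and *s*ᵢ the sum of its additional allele dosages. Group membership
*y*ᵢ (e.g. known-mutation case vs control) is modelled by logistic
regression

  logit P(*y*ᵢ = 1) = α + β·*x*ᵢ + γᵀ**z**ᵢ,  *x*ᵢ ∈ {*c*ᵢ, *s*ᵢ},

with covariates **z** (sex, principal components, capture metrics for
exomes, platform for combined runs); OR = e^β with Wald 95% CI. The
unadjusted cross-product OR from the 2×2 carrier table is always reported
alongside. AAO within a case group is modelled by OLS on the same carrier
indicator. Gene-subset enrichment (e.g. additional variants within
recessive PD genes among G2019S carriers) uses two-sided Fisher's exact
tests, and p-values are Benjamini–Hochberg FDR-adjusted within the
requested family.

A recessive primary cause requires total pathogenic allele load ≥ 2 in one
gene, where load = pathogenic SNV dosage + CNV loss alleles
(max(0, 2 − copy number)); two heterozygous pathogenic variants in the same
recessive gene are assumed in trans.

Because the study genotypes this design comes from are access-controlled,
the package includes a seeded synthetic-cohort simulator and deterministic
fixture builders (`oligopd.plans`) that reconstruct cohorts exactly
matching the published marginal counts, so every stage is testable end to
end.

## Worked example

```sh
python analysis/01_fixture_cohorts.py
```

rebuilds both study-shaped cohorts from their published counts and runs the
pipeline; for the chip cohort it prints

```
== neurox: 12340 samples, 17 variants retained ==
  known_mutation_pd      15/89 (16.9%) carry additional variants
  no_known_mutation_pd   677/6558 (10.3%) carry additional variants
  control                524/5693 (9.2%) carry additional variants
  known_mutation_pd vs control [mendelian/carrier]: unadjusted OR 2.00
```

i.e. cases with a recognised primary mutation are about twice as likely as
controls to carry an additional rare Mendelian-gene variant. The remaining
drivers probe where those variants fall and how the method behaves:

```sh
python analysis/02_g2019s_subsets.py      # enrichment in G2019S carriers
python analysis/03_parameter_recovery.py  # simulator: planted OR / AAO shift recovered
python analysis/04_null_calibration.py    # type-I error of the carrier test
python analysis/05_sensitivity_exclusion.py  # single-variant exclusion re-runs
```

`02` shows the G2019S subset signal concentrating in recessive genes
(14.7% vs 5.7% of controls on the chip) and in *ATP13A2* in particular
(combined platforms: 8.5% vs 2.4%, Fisher p ≈ 0.004); `03` reports
`planted per-allele OR 1.7: mean estimate 1.717 over 50 reps, CI coverage
100%` and `planted AAO shift -2.1 y: mean estimate -2.15 y`; `04` reports
`type-I error at alpha=0.05: 0.049`.

There is also a CLI (`oligopd run|simulate|classify|burden|aao|tables`) for
driving the same steps from a YAML config; see `oligopd --help`.

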