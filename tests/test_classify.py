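"""Primary-mutation classification and additional-variant counting."""

import itertools

import numpy as np
import pytest

from oligopd.classify import (
    GROUP_CONTROL,
    GROUP_KNOWN,
    GROUP_NO_KNOWN,
    classify_cohort,
    classify_variant,
    count_additional,
)
from oligopd.cohort_io import CnvCall, CohortValidationError

from conftest import make_cohort, make_variant


def path_var(gene, pos, chrom):
    return make_variant(gene, pos, chrom, curation="pathogenic")


class TestClassifyVariant:
    def test_curation_returned_verbatim(self):
        assert classify_variant(path_var("LRRK2", 10, "12")) == "pathogenic"
        assert classify_variant(make_variant("GBA", 60, "1", curation="risk")) == "risk"
        assert classify_variant(make_variant("PARK2", 30, "6")) == "unknown"


class TestAssignGroup:
    def test_dominant_het_is_known(self, panel):
        cohort = make_cohort([path_var("LRRK2", 10, "12")], [[1]])
        c = classify_cohort(cohort, panel)[0]
        assert c.group == GROUP_KNOWN
        assert c.primary_mutations[0].gene == "LRRK2"

    def test_compound_het_recessive_is_known(self, panel):
        cohort = make_cohort(
            [path_var("PARK2", 30, "6"), path_var("PARK2", 40, "6")], [[1, 1]]
        )
        assert classify_cohort(cohort, panel)[0].group == GROUP_KNOWN

    def test_monoallelic_recessive_is_not_known(self, panel):
        cohort = make_cohort([path_var("PARK2", 30, "6")], [[1]])
        c = classify_cohort(cohort, panel)[0]
        assert c.group == GROUP_NO_KNOWN
        # ... but the allele counts as one additional variant
        assert c.n_additional_mendelian_variants == 1

    def test_snv_plus_cnv_loss_is_known(self, panel):
        cohort = make_cohort(
            [path_var("PARK2", 30, "6")], [[1]],
            cnvs=[CnvCall("s0", "PARK2", copy_number=1, n_probes=15)],
        )
        c = classify_cohort(cohort, panel)[0]
        assert c.group == GROUP_KNOWN
        assert {m.zygosity for m in c.primary_mutations} == {"het", "cnv_loss"}

    def test_controls_stay_controls_regardless_of_genotype(self, panel):
        cohort = make_cohort([path_var("LRRK2", 10, "12")], [[1]], statuses=["control"])
        assert classify_cohort(cohort, panel)[0].group == GROUP_CONTROL

    def test_conflicting_cnv_calls_rejected(self, panel):
        cohort = make_cohort([path_var("PARK2", 30, "6")], [[0]])
        cohort.cnvs.extend([
            CnvCall("s0", "PARK2", copy_number=1, n_probes=15),
            CnvCall("s0", "PARK2", copy_number=3, n_probes=15),
        ])
        with pytest.raises(CohortValidationError, match="conflicting CNV"):
            classify_cohort(cohort, panel)

    def test_truth_table_matches_brute_force(self, panel):
        """Recessive classification over all SNV dosage x copy-number combos."""
        for dosage, cn in itertools.product((0, 1, 2), (0, 1, 2, 3)):
            cnvs = [] if cn == 2 else [CnvCall("s0", "PARK2", copy_number=cn, n_probes=15)]
            cohort = make_cohort([path_var("PARK2", 30, "6")], [[dosage]], cnvs=cnvs)
            got = classify_cohort(cohort, panel)[0].group
            # oracle: pathogenic allele load = dosage + loss alleles
            load = dosage + max(0, 2 - cn)
            expected = GROUP_KNOWN if load >= 2 else GROUP_NO_KNOWN
            assert got == expected, (dosage, cn)


class TestCountAdditional:
    def two_gene_cohort(self):
        variants = [
            path_var("LRRK2", 10, "12"),  # primary
            make_variant("ATP13A2", 20, "1"),
            make_variant("GBA", 60, "1", curation="risk"),
        ]
        return make_cohort(variants, [[1, 1, 1]])

    def test_primary_excluded_from_additional(self, panel):
        cohort = make_cohort([path_var("LRRK2", 10, "12")], [[1]])
        c = classify_cohort(cohort, panel)[0]
        assert c.group == GROUP_KNOWN
        assert c.n_additional_mendelian_variants == 0
        assert c.n_additional_mendelian_alleles == 0

    def test_additional_in_other_gene_counts(self, panel):
        c = classify_cohort(self.two_gene_cohort(), panel)[0]
        assert c.group == GROUP_KNOWN
        assert c.n_additional_mendelian_variants == 1
        assert c.genes_hit == {"ATP13A2": 1}
        assert c.n_gba_variants == 1

    def test_homozygous_unknown_counts_one_variant_two_alleles(self, panel):
        cohort = make_cohort([make_variant("PINK1", 20, "1")], [[2]])
        c = classify_cohort(cohort, panel)[0]
        assert c.n_additional_mendelian_variants == 1
        assert c.n_additional_mendelian_alleles == 2

    def test_mendelian_and_gba_counts_disjoint(self, panel):
        c = classify_cohort(self.two_gene_cohort(), panel)[0]
        assert c.n_additional_mendelian_variants + c.n_gba_variants == 2
        # GBA sites never leak into Mendelian counts
        cohort = make_cohort([make_variant("GBA", 60, "1")], [[2]])
        c2 = classify_cohort(cohort, panel)[0]
        assert c2.n_additional_mendelian_variants == 0
        assert c2.n_gba_variants == 1 and c2.n_gba_alleles == 2

    def test_exclusion_is_effective(self, panel):
        """Zeroing the primary alleles and re-counting changes nothing."""
        cohort = self.two_gene_cohort()
        c = classify_cohort(cohort, panel)[0]
        zeroed = cohort.genotypes.copy()
        idx = cohort.variant_index()
        for m in c.primary_mutations:
            zeroed[0, idx[m.key]] = 0
        cohort2 = make_cohort(cohort.variants, zeroed.tolist())
        c2 = classify_cohort(cohort2, panel)[0]
        assert (
            c.n_additional_mendelian_variants,
            c.n_additional_mendelian_alleles,
            c.n_gba_variants,
        ) == (
            c2.n_additional_mendelian_variants,
            c2.n_additional_mendelian_alleles,
            c2.n_gba_variants,
        )

    def test_ineligible_variant_not_counted(self, panel):
        import dataclasses

        v = dataclasses.replace(make_variant("PINK1", 20, "1"), additional_eligible=False)
        cohort = make_cohort([v], [[1]])
        c = classify_cohort(cohort, panel)[0]
        assert c.n_additional_mendelian_variants == 0

    def test_per_sample_wrapper_agrees_with_batch(self, panel):
        cohort = self.two_gene_cohort()
        assert count_additional("s0", cohort, panel) == classify_cohort(cohort, panel)[0]


class TestGdFlag:
    def gba_cohort(self, genotypes):
        variants = [
            make_variant("GBA", 60, "1", curation="gd_causing"),
            make_variant("GBA", 70, "1", curation="risk"),
        ]
        return make_cohort(variants, genotypes)

    def test_single_gd_het_flagged(self, panel):
        c = classify_cohort(self.gba_cohort([[1, 0]]), panel)[0]
        assert c.gd_het_carrier
        assert c.n_gba_variants == 1

    def test_risk_only_carrier_not_flagged(self, panel):
        assert not classify_cohort(self.gba_cohort([[0, 1]]), panel)[0].gd_het_carrier

    def test_homozygous_gd_not_flagged(self, panel):
        # biallelic GD genotype is not a heterozygous carrier
        assert not classify_cohort(self.gba_cohort([[2, 0]]), panel)[0].gd_het_carrier


def test_order_invariance(panel):
    """Classification is unchanged under sample and variant permutations."""
    rng = np.random.default_rng(0)
    variants = [
        path_var("LRRK2", 10, "12"),
        path_var("PARK2", 30, "6"),
        path_var("PARK2", 40, "6"),
        make_variant("ATP13A2", 20, "1"),
        make_variant("GBA", 60, "1", curation="gd_causing"),
    ]
    G = rng.integers(0, 3, size=(20, 5)).tolist()
    statuses = ["case"] * 10 + ["control"] * 10
    base = {c.sample_id: c for c in classify_cohort(make_cohort(variants, G, statuses), panel)}
    perm = rng.permutation(20)
    shuffled = make_cohort(
        variants, [G[i] for i in perm], [statuses[i] for i in perm]
    )
    # sample ids are positional in make_cohort; map back through genotype rows
    for row, i in enumerate(perm):
        got = classify_cohort(shuffled, panel)[row]
        expect = base[f"s{i}"]
        assert got.group == expect.group
        assert got.n_additional_mendelian_variants == expect.n_additional_mendelian_variants
        assert got.n_gba_alleles == expect.n_gba_alleles
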