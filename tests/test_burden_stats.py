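"""Burden statistics: distributions, logistic models, Fisher, BH-FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligopd.burden_stats import (
    AnalysisRequest,
    allele_burden,
    bh_fdr,
    carrier_burden,
    carrier_distribution,
    cross_product_or,
    gd_subset,
    primary_gene_filter,
    sensitivity_rerun,
    subset_enrichment,
)
from oligopd.classify import SampleClassification, classify_cohort
from oligopd.cohort_io import SampleRecord

from conftest import make_cohort, make_variant


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def bh_oracle(pvals):
    """Step-up BH by the hand formula: q(i) = min_{j>=i} p(j)*m/j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def cls(sample_id, group, mendelian=0, gba=0, alleles=None, genes_hit=None, gd=False):
    return SampleClassification(
        sample_id=sample_id,
        group=group,
        n_additional_mendelian_variants=mendelian,
        n_additional_mendelian_alleles=alleles if alleles is not None else mendelian,
        n_gba_variants=gba,
        n_gba_alleles=gba,
        gd_het_carrier=gd,
        genes_hit=genes_hit or {},
    )


def plain_samples(classifications):
    return [
        SampleRecord(
            id=c.sample_id,
            status="control" if c.group == "control" else "case",
            aao=None,
            sex="M" if i % 2 else "F",
            pcs=(0.0,),
        )
        for i, c in enumerate(classifications)
    ]


class TestCarrierDistribution:
    def test_direct_tally(self):
        group = [cls(f"s{i}", "control", k) for i, k in enumerate((0, 0, 1, 2))]
        d = carrier_distribution(group, "control", "mendelian")
        assert d.counts == {0: 2, 1: 1, 2: 1}
        assert d.freqs == {0: 0.5, 1: 0.25, 2: 0.25}

    def test_empty_group(self):
        d = carrier_distribution([], "control", "mendelian")
        assert d.counts == {} and d.freqs == {} and d.n == 0

    def test_freqs_sum_to_one(self, neurox):
        _, classifications, _ = neurox
        for group in ("known_mutation_pd", "no_known_mutation_pd", "control"):
            for cat in ("mendelian", "gba"):
                d = carrier_distribution(classifications, group, cat)
                assert abs(sum(d.freqs.values()) - 1) < 1e-9
                assert sum(d.counts.values()) == d.n


class TestCarrierBurden:
    def test_null_effect(self):
        groups = [cls(f"a{i}", "known_mutation_pd", int(i < 20)) for i in range(100)]
        groups += [cls(f"b{i}", "control", int(i < 20)) for i in range(100)]
        r = carrier_burden(groups, plain_samples(groups), "known_mutation_pd", "control")
        assert r.or_unadjusted == 1.0
        assert abs(r.or_adj - 1.0) < 1e-6

    def test_cross_product_from_published_counts(self, neurox):
        """Chip-cohort known-mutation vs control carrier table gives OR ~ 2.00."""
        cohort, classifications, _ = neurox
        r = carrier_burden(classifications, cohort.samples,
                           "known_mutation_pd", "control", "mendelian")
        assert r.carriers_a == 15 and r.n_a == 89
        assert r.carriers_b == 524 and r.n_b == 5693
        assert r.or_unadjusted == pytest.approx((15 * 5169) / (74 * 524))
        assert r.or_unadjusted == pytest.approx(2.00, abs=0.005)

    def test_zero_carriers_undefined(self, exome):
        """Exome known-mutation group has no GBA carriers: OR undefined."""
        cohort, classifications = exome
        r = carrier_burden(classifications, cohort.samples,
                           "known_mutation_pd", "control", "gba")
        assert r.carriers_a == 0
        assert r.or_adj is None and r.or_unadjusted is None
        assert "zero_carriers" in r.flags

    def test_logistic_converges_to_cross_product(self):
        """Without covariates, exp(beta) ~ the unadjusted OR at large n."""
        rng = np.random.default_rng(5)
        n = 10_000
        groups = [cls(f"a{i}", "known_mutation_pd", int(rng.random() < 0.3)) for i in range(n)]
        groups += [cls(f"b{i}", "control", int(rng.random() < 0.18)) for i in range(n)]
        r = carrier_burden(groups, plain_samples(groups), "known_mutation_pd", "control")
        assert r.or_adj == pytest.approx(r.or_unadjusted, rel=0.01)

    def test_collinear_covariate_flagged(self):
        groups = [cls(f"a{i}", "known_mutation_pd", int(i < 5)) for i in range(10)]
        groups += [cls(f"b{i}", "control", int(i < 5)) for i in range(10)]
        samples = [
            SampleRecord(id=c.sample_id,
                         status="control" if c.group == "control" else "case",
                         aao=None, sex="M",
                         pcs=(1.0 if c.group == "control" else 0.0,))
            for c in groups
        ]
        # sex constant -> collinear with the intercept
        r = carrier_burden(groups, samples, "known_mutation_pd", "control",
                           covariates=("sex",))
        assert "collinear" in r.flags and r.or_adj is None

    def test_degenerate_allele_predictor_flagged(self):
        groups = [cls(f"a{i}", "known_mutation_pd", 1, alleles=1) for i in range(5)]
        groups += [cls(f"b{i}", "control", 1, alleles=1) for i in range(5)]
        r = allele_burden(groups, plain_samples(groups), "known_mutation_pd", "control")
        assert "degenerate_predictor" in r.flags


class TestSubsetEnrichment:
    def test_hand_enumerated_table(self):
        """[[3,1],[1,3]] has two-sided Fisher p = 0.4857 by enumeration."""
        cases = [cls(f"a{i}", "known_mutation_pd",
                     genes_hit={"ATP13A2": 1} if i < 3 else {}) for i in range(4)]
        controls = [cls(f"b{i}", "control",
                        genes_hit={"ATP13A2": 1} if i < 1 else {}) for i in range(4)]
        r = subset_enrichment(cases, ["ATP13A2"], lambda c: True, controls)
        assert r.p_raw == pytest.approx(0.4857, abs=1e-4)
        assert r.p_raw == pytest.approx(fisher_two_sided_oracle(3, 1, 1, 3), rel=1e-9)

    def test_empty_subset_gives_p_one(self):
        cases = [cls("a0", "known_mutation_pd", genes_hit={"PINK1": 1})]
        controls = [cls("b0", "control")]
        r = subset_enrichment(cases, [], lambda c: True, controls)
        assert r.carriers_a == 0 and r.p_raw == 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_enumeration_oracle_on_small_tables(self, table):
        a, b, c, d = table
        cases = [cls(f"a{i}", "known_mutation_pd",
                     genes_hit={"PINK1": 1} if i < a else {}) for i in range(a + b)]
        controls = [cls(f"b{i}", "control",
                        genes_hit={"PINK1": 1} if i < c else {}) for i in range(c + d)]
        r = subset_enrichment(cases, ["PINK1"], lambda c_: True, controls)
        if a + b + c + d == 0:
            assert r.p_raw == 1.0
        else:
            assert r.p_raw == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7)

    def test_case_filter_selects_by_primary_gene(self, neurox, panel):
        cohort, classifications, _ = neurox
        controls = [c for c in classifications if c.group == "control"]
        g2019s = primary_gene_filter("LRRK2", "12:40734202:G:A")
        r = subset_enrichment(classifications, panel.recessive_genes, g2019s,
                              controls, "recessive")
        assert r.n_a == 75  # G2019S-positive cases
        assert r.carriers_a == 11 and r.carriers_b == 323


class TestGdSubset:
    def test_known_group_fraction(self, neurox):
        _, classifications, _ = neurox
        r = gd_subset(classifications, "known_mutation_pd")
        assert (r.n_flagged, r.n_carriers) == (5, 7)
        assert r.proportion == pytest.approx(5 / 7)

    def test_no_carriers_is_na(self):
        r = gd_subset([cls("a0", "control")], "control")
        assert r.proportion is None

    def test_all_flagged_is_one(self):
        group = [cls(f"a{i}", "control", gba=1, gd=True) for i in range(3)]
        assert gd_subset(group, "control").proportion == 1.0


class TestBhFdr:
    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_equal_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_adjusted_never_below_raw(self):
        p = [0.001, 0.04, 0.2, 0.9, 0.013]
        assert np.all(bh_fdr(p) >= np.asarray(p) - 1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_hand_formula_and_permutation_invariant(self, pvals):
        got = bh_fdr(pvals)
        assert got == pytest.approx(bh_oracle(pvals), rel=1e-12, abs=1e-12)
        perm = np.random.default_rng(0).permutation(len(pvals))
        shuffled = bh_fdr([pvals[i] for i in perm])
        assert np.asarray(shuffled) == pytest.approx(got[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSensitivityRerun:
    def setup_cohort(self):
        variants = [
            make_variant("LRRK2", 10, "12", curation="pathogenic"),
            make_variant("ATP13A2", 20, "1"),
            make_variant("PINK1", 30, "1"),
            make_variant("PARK7", 40, "1"),  # carried by no one
        ]
        G = [
            [1, 1, 0, 0],  # known-mutation case, one additional
            [0, 0, 1, 0],  # case with one additional
            [0, 0, 0, 0],  # control
            [0, 1, 0, 0],  # control carrier
        ]
        return make_cohort(variants, G, ["case", "case", "control", "control"])

    def request(self):
        return [AnalysisRequest(kind="carrier", label="x", group_a="all_pd",
                                group_b="control")]

    def test_empty_exclusion_is_identity(self, panel):
        cohort = self.setup_cohort()
        base = sensitivity_rerun(cohort, [], self.request(), panel)[0]
        classifications = classify_cohort(cohort, panel)
        direct = carrier_burden(classifications, cohort.samples, "all_pd", "control")
        assert (base.carriers_a, base.carriers_b) == (direct.carriers_a, direct.carriers_b)

    def test_excluding_uncarried_variant_is_identity(self, panel):
        cohort = self.setup_cohort()
        base = sensitivity_rerun(cohort, [], self.request(), panel)[0]
        same = sensitivity_rerun(cohort, ["1:40:A:G"], self.request(), panel)[0]
        assert (same.carriers_a, same.carriers_b) == (base.carriers_a, base.carriers_b)

    def test_excluding_only_variant_flips_carrier(self, panel):
        cohort = self.setup_cohort()
        base = sensitivity_rerun(cohort, [], self.request(), panel)[0]
        excl = sensitivity_rerun(cohort, ["1:20:A:G"], self.request(), panel)[0]
        assert excl.carriers_a == base.carriers_a - 1
        assert excl.carriers_b == base.carriers_b - 1
        # primary classification untouched
        assert excl.n_a == base.n_a

    def test_unknown_key_rejected(self, panel):
        with pytest.raises(ValueError, match="unknown exclusion key"):
            sensitivity_rerun(self.setup_cohort(), ["9:9:A:G"], self.request(), panel)


def test_carriers_match_distribution_mass(neurox):
    """Burden carrier counts equal the k>=1 mass of the distribution."""
    cohort, classifications, _ = neurox
    for cat in ("mendelian", "gba"):
        d = carrier_distribution(classifications, "known_mutation_pd", cat)
        r = carrier_burden(classifications, cohort.samples,
                           "known_mutation_pd", "control", cat)
        assert r.carriers_a == sum(n for k, n in d.counts.items() if k >= 1)
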