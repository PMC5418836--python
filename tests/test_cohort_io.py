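"""Cohort input parsing, validation and table writing."""

import numpy as np
import pytest

from oligopd.burden_stats import BurdenResult, CarrierDistribution
from oligopd.cohort_io import (
    CohortValidationError,
    SampleRecord,
    VariantRecord,
    fmt_freq,
    fmt_or_ci,
    read_cnvs,
    read_cohort,
    read_table,
    write_table,
)
from oligopd.panel import default_panel
from oligopd.synth_cohort import write_cohort_inputs

from conftest import make_cohort, make_variant


def write_inputs(tmp_path, cohort):
    return write_cohort_inputs(cohort, tmp_path / "inputs")


class TestReadCohort:
    def test_round_trip_identity(self, tmp_path, panel):
        cohort = make_cohort(
            [make_variant("LRRK2", 10, "12"), make_variant("PARK2", 20, "6")],
            [[0, 1], [1, 2], [0, 0]],
            statuses=["case", "case", "control"],
            aaos=[55.0, None, None],
        )
        paths = write_inputs(tmp_path, cohort)
        back = read_cohort(paths["vcf"], paths["annotation"], paths["phenotypes"],
                           paths["cnvs"], panel)
        assert back.n_samples == 3 and back.n_variants == 2
        assert np.array_equal(back.genotypes, cohort.genotypes)
        assert back.samples == cohort.samples
        assert [v.key for v in back.variants] == [v.key for v in cohort.variants]

    def test_unannotated_site_dropped(self, tmp_path, panel):
        cohort = make_cohort(
            [make_variant("LRRK2", 10, "12"), make_variant("PARK2", 20, "6")],
            [[0, 1]],
        )
        paths = write_inputs(tmp_path, cohort)
        # remove the second annotation row
        lines = paths["annotation"].read_text().splitlines()
        paths["annotation"].write_text("\n".join(lines[:2]) + "\n")
        back = read_cohort(paths["vcf"], paths["annotation"], paths["phenotypes"],
                           paths["cnvs"], panel)
        assert back.n_variants == 1
        assert back.variants[0].gene == "LRRK2"

    def test_missing_genotype_maps_to_minus_one(self, tmp_path, panel):
        cohort = make_cohort([make_variant("LRRK2", 10, "12")], [[-1], [1]])
        paths = write_inputs(tmp_path, cohort)
        assert "./." in paths["vcf"].read_text()
        back = read_cohort(paths["vcf"], paths["annotation"], paths["phenotypes"],
                           paths["cnvs"], panel)
        assert back.genotypes[0, 0] == -1 and back.genotypes[1, 0] == 1

    def test_multiallelic_split(self, tmp_path, panel):
        # hand-written VCF with one multi-allelic record
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=12>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
            "12\t10\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        )
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "key\trsid\tgene\tconsequence\tmaf_1000g\tmaf_esp\tcuration\n"
            "12:10:A:G\t\tLRRK2\tmissense\t0.001\t0.001\tunknown\n"
            "12:10:A:T\t\tLRRK2\tmissense\t0.001\t0.001\tunknown\n"
        )
        ph = tmp_path / "ph.tsv"
        ph.write_text(
            "id\tstatus\taao\tsex\tplatform\ns0\tcase\t\tM\tneurox\ns1\tcase\t\tF\tneurox\n"
        )
        back = read_cohort(vcf, ann, ph, None, panel)
        assert back.n_variants == 2
        idx = back.variant_index()
        assert back.genotypes[0, idx["12:10:A:G"]] == 1
        assert back.genotypes[1, idx["12:10:A:G"]] == 1
        assert back.genotypes[0, idx["12:10:A:T"]] == 0
        assert back.genotypes[1, idx["12:10:A:T"]] == 1

    def test_cnv_probe_filter(self, tmp_path):
        p = tmp_path / "cnv.tsv"
        p.write_text(
            "sample_id\tgene\tcopy_number\tn_probes\tvalidated\n"
            "s0\tPARK2\t1\t9\ttrue\n"
            "s0\tPARK2\t1\t10\ttrue\n"
        )
        calls = read_cnvs(p)
        assert len(calls) == 1 and calls[0].n_probes == 10

    def test_duplicate_sample_id_rejected(self, tmp_path, panel):
        cohort = make_cohort([make_variant("LRRK2", 10, "12")], [[0], [1]])
        paths = write_inputs(tmp_path, cohort)
        text = paths["phenotypes"].read_text().replace("s1", "s0")
        paths["phenotypes"].write_text(text)
        with pytest.raises(CohortValidationError, match="duplicate sample ID"):
            read_cohort(paths["vcf"], paths["annotation"], paths["phenotypes"],
                        paths["cnvs"], panel)


class TestDomainTypes:
    def test_variant_invariants(self):
        with pytest.raises(CohortValidationError):
            make_variant("LRRK2", pos=0)
        with pytest.raises(CohortValidationError):
            VariantRecord(key="1:5:A:A", gene="LRRK2", consequence="missense")
        with pytest.raises(CohortValidationError, match="gd_causing"):
            VariantRecord(key="1:5:A:G", gene="LRRK2", consequence="missense",
                          curation="gd_causing")

    def test_aao_only_for_cases(self):
        with pytest.raises(CohortValidationError):
            SampleRecord(id="x", status="control", aao=60.0, sex="M")

    def test_genotype_matrix_entries_validated(self):
        with pytest.raises(CohortValidationError, match="invalid entries"):
            make_cohort([make_variant("LRRK2", 10, "12")], [[3]])


class TestTableWriting:
    def test_carrier_distribution_rendering(self, tmp_path):
        dist = CarrierDistribution(
            group="known_mutation_pd", category="mendelian",
            counts={0: 74, 1: 15}, freqs={0: 74 / 89, 1: 15 / 89}, n=89,
        )
        out = tmp_path / "t.tsv"
        write_table(dist, out)
        lines = out.read_text().splitlines()
        assert "0\t74\t0.8315" in lines[1]
        assert "1\t15\t0.1685" in lines[2]

    def test_or_ci_rendering(self):
        assert fmt_or_ci(1.7012, (1.0184, 2.8472)) == "1.70 (1.02–2.85)"
        assert fmt_or_ci(None, None) == "0 –"
        assert fmt_freq(None) == "–"

    def test_empty_result_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_table([], out)
        assert out.read_text().strip() == ""

    def test_json_round_trip(self, tmp_path):
        results = [
            BurdenResult(label="a vs b", category="mendelian", model="carrier_logistic",
                         n_a=89, n_b=5693, carriers_a=15, carriers_b=524,
                         or_adj=1.7012, ci95=(1.0184, 2.8472), p_raw=0.043,
                         or_unadjusted=2.0, covariates=("sex",)),
            CarrierDistribution(group="control", category="gba",
                                counts={0: 10, 1: 2}, freqs={0: 10 / 12, 1: 2 / 12}, n=12),
        ]
        out = tmp_path / "r.json"
        write_table(results, out, "json")
        assert read_table(out) == results
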