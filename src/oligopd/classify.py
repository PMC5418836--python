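"""Primary-mutation classification and additional-variant counting.

Each sample is assigned one of three groups:

* ``known_mutation_pd`` — a case carrying a recognised high-penetrance
  primary cause: at least one curated pathogenic allele in a dominant-mode
  gene, or, in some recessive-mode gene, a total pathogenic allele load of
  at least two.  The recessive load sums pathogenic SNV dosage, CNV loss
  alleles (``max(0, 2 - copy_number)``) and, for genes explicitly flagged,
  CNV gain alleles.  Two heterozygous pathogenic variants in the same
  recessive gene are assumed in trans (no phase information is available
  on these platforms).
* ``no_known_mutation_pd`` — any other case.  A monoallelic pathogenic
  recessive allele does not confer known-mutation status (and counts as
  one additional variant downstream).
* ``control`` — every control, regardless of genotype.

"Additional" variants are then counted with the sample's primary-mutation
alleles excluded: the variant count is the number of eligible sites with
dosage >= 1 and the allele count is the dosage sum over those sites.
Mendelian genes and GBA are tracked separately and never share a site.
A GD-heterozygote flag marks samples carrying exactly one GD-causing GBA
allele and no second GBA pathogenic/GD allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CnvCall, CohortData, CohortValidationError, VariantRecord
from .panel import GBA, GenePanel

GROUP_KNOWN = "known_mutation_pd"
GROUP_NO_KNOWN = "no_known_mutation_pd"
GROUP_CONTROL = "control"
GROUPS = (GROUP_KNOWN, GROUP_NO_KNOWN, GROUP_CONTROL)

_ZYGOSITY = {1: "het", 2: "hom"}


@dataclass(frozen=True)
class PrimaryMutation:
    """One allele (SNV key or CNV) contributing to a sample's primary cause."""

    key: str  # variant key, or "CNV:<gene>:cn=<n>"
    gene: str
    zygosity: str  # het | hom | cnv_loss | cnv_gain


@dataclass
class SampleClassification:
    sample_id: str
    group: str
    primary_mutations: tuple[PrimaryMutation, ...] = ()
    n_additional_mendelian_variants: int = 0
    n_additional_mendelian_alleles: int = 0
    n_gba_variants: int = 0
    n_gba_alleles: int = 0
    gd_het_carrier: bool = False
    genes_hit: dict[str, int] = field(default_factory=dict)

    @property
    def primary_genes(self) -> set[str]:
        return {m.gene for m in self.primary_mutations}

    def count(self, category: str) -> int:
        if category == "mendelian":
            return self.n_additional_mendelian_variants
        if category == "gba":
            return self.n_gba_variants
        raise ValueError(f"unknown category {category!r}")

    def alleles(self, category: str) -> int:
        if category == "mendelian":
            return self.n_additional_mendelian_alleles
        if category == "gba":
            return self.n_gba_alleles
        raise ValueError(f"unknown category {category!r}")


def classify_variant(variant: VariantRecord) -> str:
    """Curation class, verbatim from the annotation (never inferred)."""
    return variant.curation


def _cnv_by_sample_gene(cnvs: list[CnvCall]) -> dict[tuple[str, str], CnvCall]:
    table: dict[tuple[str, str], CnvCall] = {}
    for c in cnvs:
        key = (c.sample_id, c.gene)
        if key in table and table[key].copy_number != c.copy_number:
            raise CohortValidationError(
                f"conflicting CNV calls for sample {c.sample_id} gene {c.gene}"
            )
        table[key] = c
    return table


def classify_cohort(
    cohort: CohortData,
    panel: GenePanel,
    pathogenic_gains: frozenset[str] | set[str] = frozenset(),
) -> list[SampleClassification]:
    """Classify every sample and populate its additional-variant counts.

    The computation is independent of sample and variant iteration order;
    per-sample results depend only on (genotypes, CNVs, annotations).
    """
    n_s, n_v = cohort.genotypes.shape
    genes = np.array([v.gene for v in cohort.variants])
    curation = np.array([v.curation for v in cohort.variants])
    eligible = np.array([v.additional_eligible for v in cohort.variants], dtype=bool)
    is_gba = genes == GBA
    is_case = np.array([s.status == "case" for s in cohort.samples], dtype=bool)

    G = np.clip(cohort.genotypes, 0, 2).astype(np.int16)  # missing -> 0 for counting

    pathogenic = curation == "pathogenic"
    dom_cols = np.flatnonzero(
        pathogenic & np.array([v.gene in panel and panel.mode(v.gene) == "dominant"
                               for v in cohort.variants])
    )
    dominant_hit = G[:, dom_cols] > 0 if dom_cols.size else np.zeros((n_s, 0), dtype=bool)

    cnv_table = _cnv_by_sample_gene(cohort.cnvs)
    sample_idx = cohort.sample_index()
    # recessive pathogenic load per (sample, recessive gene)
    rec_genes = [g for g in panel.recessive_genes]
    rec_load = np.zeros((n_s, len(rec_genes)), dtype=np.int16)
    rec_cols: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(rec_genes):
        cols = np.flatnonzero(pathogenic & (genes == gene))
        rec_cols[gene] = cols
        if cols.size:
            rec_load[:, gi] = G[:, cols].sum(axis=1)
    for (sid, gene), call in cnv_table.items():
        if gene not in rec_cols:
            continue
        gi = rec_genes.index(gene)
        si = sample_idx.get(sid)
        if si is None:
            continue
        loss = max(0, 2 - call.copy_number)
        gain = max(0, call.copy_number - 2) if gene in pathogenic_gains else 0
        rec_load[si, gi] += loss + gain

    biallelic = rec_load >= 2
    is_known = is_case & (dominant_hit.any(axis=1) | biallelic.any(axis=1))

    # primary mutation lists and an exclusion copy of the matrix
    Gx = G.copy()
    primaries: dict[int, tuple[PrimaryMutation, ...]] = {}
    for si in np.flatnonzero(is_known):
        muts: list[PrimaryMutation] = []
        for j in dom_cols:
            if G[si, j] > 0:
                muts.append(
                    PrimaryMutation(cohort.variants[j].key, genes[j], _ZYGOSITY[int(G[si, j])])
                )
                Gx[si, j] = 0
        for gi, gene in enumerate(rec_genes):
            if not biallelic[si, gi]:
                continue
            for j in rec_cols[gene]:
                if G[si, j] > 0:
                    muts.append(
                        PrimaryMutation(
                            cohort.variants[j].key, gene, _ZYGOSITY[int(G[si, j])]
                        )
                    )
                    Gx[si, j] = 0
            call = cnv_table.get((cohort.samples[si].id, gene))
            if call is not None:
                if call.copy_number < 2:
                    muts.append(
                        PrimaryMutation(
                            f"CNV:{gene}:cn={call.copy_number}", gene, "cnv_loss"
                        )
                    )
                elif call.copy_number > 2 and gene in pathogenic_gains:
                    muts.append(
                        PrimaryMutation(
                            f"CNV:{gene}:cn={call.copy_number}", gene, "cnv_gain"
                        )
                    )
        primaries[si] = tuple(muts)

    # additional-variant counting on the exclusion matrix
    mend_elig = eligible & ~is_gba & np.array([v.gene in panel for v in cohort.variants])
    gba_elig = eligible & is_gba
    Gm = Gx[:, mend_elig]
    Gg = Gx[:, gba_elig]
    n_mend_var = (Gm > 0).sum(axis=1)
    n_mend_all = Gm.sum(axis=1)
    n_gba_var = (Gg > 0).sum(axis=1)
    n_gba_all = Gg.sum(axis=1)

    # GD heterozygote flag: exactly one GD-causing allele, no second
    # pathogenic/GD GBA allele
    gd_cols = np.flatnonzero(is_gba & (curation == "gd_causing"))
    gba_path_cols = np.flatnonzero(is_gba & np.isin(curation, ("gd_causing", "pathogenic")))
    gd_alleles = G[:, gd_cols].sum(axis=1) if gd_cols.size else np.zeros(n_s, dtype=np.int16)
    gba_path_alleles = (
        G[:, gba_path_cols].sum(axis=1) if gba_path_cols.size else np.zeros(n_s, dtype=np.int16)
    )
    gd_het = (gd_alleles == 1) & (gba_path_alleles == 1)

    # per-gene hit counts (Mendelian genes only, eligible sites)
    gene_hits: dict[str, np.ndarray] = {}
    for gene in panel.mendelian_genes:
        cols = np.flatnonzero(mend_elig & (genes == gene))
        if cols.size:
            gene_hits[gene] = (Gx[:, cols] > 0).sum(axis=1)

    out: list[SampleClassification] = []
    for si, s in enumerate(cohort.samples):
        if s.status == "control":
            group = GROUP_CONTROL
        elif is_known[si]:
            group = GROUP_KNOWN
        else:
            group = GROUP_NO_KNOWN
        hits = {g: int(h[si]) for g, h in gene_hits.items() if h[si] > 0}
        out.append(
            SampleClassification(
                sample_id=s.id,
                group=group,
                primary_mutations=primaries.get(si, ()),
                n_additional_mendelian_variants=int(n_mend_var[si]),
                n_additional_mendelian_alleles=int(n_mend_all[si]),
                n_gba_variants=int(n_gba_var[si]),
                n_gba_alleles=int(n_gba_all[si]),
                gd_het_carrier=bool(gd_het[si]),
                genes_hit=hits,
            )
        )
    return out


def assign_group(
    sample_id: str,
    cohort: CohortData,
    panel: GenePanel,
    pathogenic_gains: frozenset[str] | set[str] = frozenset(),
) -> SampleClassification:
    """Classify a single sample (group and primary mutations, counts zeroed)."""
    full = count_additional(sample_id, cohort, panel, pathogenic_gains)
    return SampleClassification(
        sample_id=full.sample_id,
        group=full.group,
        primary_mutations=full.primary_mutations,
    )


def count_additional(
    sample_id: str,
    cohort: CohortData,
    panel: GenePanel,
    pathogenic_gains: frozenset[str] | set[str] = frozenset(),
) -> SampleClassification:
    """Full classification (group + counts) for a single sample."""
    si = cohort.sample_index()[sample_id]
    sub = cohort.subset_samples(np.array([si]))
    return classify_cohort(sub, panel, pathogenic_gains)[0]


def classification_frame(classifications: list[SampleClassification]) -> pd.DataFrame:
    """Per-sample classification table."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "sample_id": c.sample_id,
                "group": c.group,
                "primary_mutations": ";".join(
                    f"{m.key}|{m.gene}|{m.zygosity}" for m in c.primary_mutations
                ),
                "n_additional_mendelian_variants": c.n_additional_mendelian_variants,
                "n_additional_mendelian_alleles": c.n_additional_mendelian_alleles,
                "n_gba_variants": c.n_gba_variants,
                "n_gba_alleles": c.n_gba_alleles,
                "gd_het_carrier": c.gd_het_carrier,
                "genes_hit": ";".join(f"{g}:{n}" for g, n in sorted(c.genes_hit.items())),
            }
        )
    return pd.DataFrame(rows)
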