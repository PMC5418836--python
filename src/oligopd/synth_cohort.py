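"""Synthetic cohorts: a seeded simulator and a deterministic fixture builder.

The simulator (:func:`simulate`) draws cohorts with the statistical
structure the analysis assumes — planted primary mutations in dominant and
recessive genes (including an SNV+CNV biallelic route), rare
unknown-significance variants with log-uniform MAFs, a configurable
carrier-enrichment odds ratio for known-mutation cases, per-group GBA
carrier probabilities, and an AAO model with additive carrier shifts —
and returns the cohort together with an explicit truth record.

The fixture builder (:func:`build_fixture`) is randomness-free: it
materialises a cohort from a plan of sample blocks (group, primary cause,
additional-variant genes, GBA alleles, AAO) such that classification and
counting reproduce the plan exactly.  Planted additional variants are
heterozygous, so variant and allele counts coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import (
    ANNOTATION_COLUMNS,
    MISSING,
    CnvCall,
    CohortData,
    SampleRecord,
    VariantRecord,
)
from .panel import GBA, GenePanel, default_panel

GROUP_KNOWN = "known_mutation_pd"
GROUP_NO_KNOWN = "no_known_mutation_pd"
GROUP_CONTROL = "control"


class ConfigError(ValueError):
    """Raised for an infeasible simulation or fixture plan."""


# representative loci for synthesising variant keys (chrom, base position)
GENE_LOCI: dict[str, tuple[str, int]] = {
    "PINK1": ("1", 20633000),
    "PARK7": ("1", 8021000),
    "ATP13A2": ("1", 17312000),
    GBA: ("1", 155204000),
    "EIF4G1": ("3", 184032000),
    "SNCA": ("4", 90645000),
    "PARK2": ("6", 161771000),
    "LRRK2": ("12", 40618000),
    "VPS35": ("16", 46693000),
    "FBXO7": ("22", 32870000),
    "PLA2G6": ("22", 38508000),
}

#: named pathogenic / curated alleles used by both the simulator and fixtures
NAMED_ALLELES: dict[tuple[str, str], tuple[str, str | None, str]] = {
    # (gene, label) -> (key, rsid, curation)
    ("LRRK2", "G2019S"): ("12:40734202:G:A", "rs34637584", "pathogenic"),
    ("LRRK2", "R1441C"): ("12:40704236:C:T", "rs33939927", "pathogenic"),
    ("VPS35", "D620N"): ("16:46696364:C:T", "rs188286943", "pathogenic"),
    ("SNCA", "A53T"): ("4:90749321:G:A", "rs104893877", "pathogenic"),
    ("PARK2", "pathA"): ("6:161771219:C:T", None, "pathogenic"),
    ("PARK2", "pathB"): ("6:161807855:G:A", None, "pathogenic"),
    ("PINK1", "pathA"): ("1:20644549:G:A", None, "pathogenic"),
    ("PINK1", "pathB"): ("1:20645000:C:T", None, "pathogenic"),
    (GBA, "gd"): ("1:155205043:A:G", "rs421016", "gd_causing"),
    (GBA, "risk"): ("1:155205634:T:C", "rs76763715", "risk"),
}


def _unknown_variant(gene: str, i: int, maf: float = 0.001) -> VariantRecord:
    chrom, base = GENE_LOCI[gene]
    return VariantRecord(
        key=f"{chrom}:{base + 7 * i + 1}:C:T",
        gene=gene,
        consequence="missense",
        maf_refs={"1000g": maf, "esp": maf},
        curation="unknown",
    )


def _named_variant(gene: str, label: str) -> VariantRecord:
    if (gene, label) in NAMED_ALLELES:
        key, rsid, curation = NAMED_ALLELES[(gene, label)]
    else:
        # generic pathogenic allele for panel genes without a named entry
        chrom, base = GENE_LOCI[gene]
        offset = {"pathA": 501, "pathB": 502}.get(label, 500)
        key, rsid, curation = f"{chrom}:{base + offset}:G:A", None, "pathogenic"
    return VariantRecord(
        key=key,
        gene=gene,
        consequence="missense",
        rsid=rsid,
        maf_refs={"1000g": 0.0005, "esp": 0.0005},
        curation=curation,
    )


def _sorted_variant_order(variants: list[VariantRecord]) -> list[VariantRecord]:
    def sort_key(v: VariantRecord):
        chrom, pos, _, _ = v.key.split(":")
        return (int(chrom) if chrom.isdigit() else 99, int(pos), v.key)

    return sorted(variants, key=sort_key)


# ---------------------------------------------------------------------------
# deterministic fixture builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimarySpec:
    """One planted primary cause: a dominant allele or a biallelic genotype."""

    gene: str
    kind: str  # dominant | hom | chet | snv_cnv
    allele: str = ""  # named-allele label for dominant causes


@dataclass(frozen=True)
class SampleBlock:
    """``n`` identical samples of one group within a fixture plan."""

    group: str
    n: int
    primary: tuple[PrimarySpec, ...] = ()
    #: gene symbols; each entry is one distinct heterozygous
    #: unknown-significance variant in that gene
    additional: tuple[str, ...] = ()
    #: GBA alleles carried: labels among {"gd", "risk", "u1", "u2", ...}
    gba: tuple[str, ...] = ()
    aao: float | None = None


@dataclass(frozen=True)
class FixturePlan:
    platform: str
    blocks: tuple[SampleBlock, ...]

    def group_size(self, group: str) -> int:
        return sum(b.n for b in self.blocks if b.group == group)


def build_fixture(plan: FixturePlan, panel: GenePanel | None = None) -> CohortData:
    """Materialise a cohort whose classification reproduces the plan exactly."""
    panel = panel or default_panel()
    for b in plan.blocks:
        if b.n < 0:
            raise ConfigError(f"block with negative n: {b}")
        if b.group == GROUP_KNOWN and not b.primary:
            raise ConfigError(f"known_mutation_pd block without a primary cause: {b}")
        if b.group != GROUP_KNOWN and b.primary:
            raise ConfigError(f"primary cause planned outside known_mutation_pd: {b}")

    # variant pool: per gene, enough distinct unknown variants for the
    # largest within-sample multiplicity in any block
    need_unknown: dict[str, int] = {}
    named_needed: set[tuple[str, str]] = set()
    gba_unknown_needed = 0
    for b in plan.blocks:
        for gene in set(b.additional):
            need_unknown[gene] = max(need_unknown.get(gene, 0), b.additional.count(gene))
        for p in b.primary:
            if p.kind == "dominant":
                named_needed.add((p.gene, p.allele))
            else:
                named_needed.add((p.gene, "pathA"))
                if p.kind == "chet":
                    named_needed.add((p.gene, "pathB"))
        for label in b.gba:
            if label in ("gd", "risk"):
                named_needed.add((GBA, label))
            else:
                gba_unknown_needed = max(gba_unknown_needed, int(label[1:]))

    variants: list[VariantRecord] = []
    unknown_cols: dict[tuple[str, int], VariantRecord] = {}
    for gene, count in sorted(need_unknown.items()):
        for i in range(count):
            rec = _unknown_variant(gene, i)
            unknown_cols[(gene, i)] = rec
            variants.append(rec)
    for i in range(gba_unknown_needed):
        rec = _unknown_variant(GBA, i)
        unknown_cols[(GBA, i)] = rec
        variants.append(rec)
    named_cols: dict[tuple[str, str], VariantRecord] = {}
    for gene, label in sorted(named_needed):
        rec = _named_variant(gene, label)
        named_cols[(gene, label)] = rec
        variants.append(rec)

    variants = _sorted_variant_order(variants)
    col = {v.key: j for j, v in enumerate(variants)}

    n_total = sum(b.n for b in plan.blocks)
    G = np.zeros((n_total, len(variants)), dtype=np.int8)
    samples: list[SampleRecord] = []
    cnvs: list[CnvCall] = []
    si = 0
    for b in plan.blocks:
        for _ in range(b.n):
            sid = f"{plan.platform}-{si:05d}"
            for p in b.primary:
                if p.kind == "dominant":
                    G[si, col[named_cols[(p.gene, p.allele)].key]] = 1
                elif p.kind == "hom":
                    G[si, col[named_cols[(p.gene, "pathA")].key]] = 2
                elif p.kind == "chet":
                    G[si, col[named_cols[(p.gene, "pathA")].key]] = 1
                    G[si, col[named_cols[(p.gene, "pathB")].key]] = 1
                elif p.kind == "snv_cnv":
                    G[si, col[named_cols[(p.gene, "pathA")].key]] = 1
                    cnvs.append(
                        CnvCall(sample_id=sid, gene=p.gene, copy_number=1, n_probes=15,
                                validated=True)
                    )
                else:
                    raise ConfigError(f"unknown primary kind {p.kind!r}")
            seen: dict[str, int] = {}
            for gene in b.additional:
                i = seen.get(gene, 0)
                seen[gene] = i + 1
                G[si, col[unknown_cols[(gene, i)].key]] = 1
            for label in b.gba:
                if label in ("gd", "risk"):
                    G[si, col[named_cols[(GBA, label)].key]] = 1
                else:
                    G[si, col[unknown_cols[(GBA, int(label[1:]) - 1)].key]] = 1
            samples.append(
                SampleRecord(
                    id=sid,
                    status="control" if b.group == GROUP_CONTROL else "case",
                    aao=b.aao if b.group != GROUP_CONTROL else None,
                    sex="F" if si % 2 else "M",
                    pcs=(0.0, 0.0),
                    capture=(1.0,) if plan.platform == "exome" else (),
                    platform=plan.platform,
                )
            )
            si += 1
    return CohortData(variants=variants, genotypes=G, samples=samples, cnvs=cnvs,
                      platform=plan.platform)


# ---------------------------------------------------------------------------
# seeded simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimaryGenePlan:
    """Planted primary-mutation counts for one gene."""

    n_dominant: int = 0
    n_biallelic: int = 0
    n_cnv: int = 0  # of the biallelic carriers, how many via SNV + CNV loss

    def __post_init__(self) -> None:
        if self.n_cnv > self.n_biallelic:
            raise ConfigError("n_cnv exceeds n_biallelic")


def _default_primary_plan() -> dict[str, PrimaryGenePlan]:
    # primary-mutation composition of the larger (genotyping-chip) cohort:
    # 78 LRRK2 + 1 VPS35 dominant, 10 biallelic PARK2 (one via SNV+CNV)
    return {
        "LRRK2": PrimaryGenePlan(n_dominant=78),
        "VPS35": PrimaryGenePlan(n_dominant=1),
        "PARK2": PrimaryGenePlan(n_biallelic=10, n_cnv=1),
    }


def _default_gba_probs() -> dict[str, float]:
    return {GROUP_KNOWN: 0.0787, GROUP_NO_KNOWN: 0.0858, GROUP_CONTROL: 0.0464}


@dataclass
class SimulationConfig:
    """All parameters of the synthetic cohort generator (seed mandatory)."""

    seed: int
    n_cases: int = 6647
    n_controls: int = 5693
    platform: str = "neurox"
    n_variants_per_gene: int = 3
    maf_range: tuple[float, float] = (1e-4, 1e-2)
    primary_plan: dict[str, PrimaryGenePlan] = field(default_factory=_default_primary_plan)
    #: per-allele odds multiplier for unknown Mendelian-gene variants in
    #: known-mutation cases relative to everyone else
    enrichment_or: float = 1.70
    gba_carrier_prob: dict[str, float] = field(default_factory=_default_gba_probs)
    gd_fraction: float = 0.64
    aao_mean: float = 61.5
    aao_sd: float = 10.0
    aao_shift_mendelian: float = -3.78
    aao_shift_gba: float = -2.10
    sex_female_prob: float = 0.40
    n_pcs: int = 2
    genotype_missing_rate: float = 0.0

    def validate(self, panel: GenePanel) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] < 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 0.5")
        if self.enrichment_or <= 0:
            raise ConfigError("enrichment_or must be > 0")
        for p in list(self.gba_carrier_prob.values()) + [
            self.gd_fraction, self.sex_female_prob, self.genotype_missing_rate
        ]:
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        n_planted = sum(
            g.n_dominant + g.n_biallelic for g in self.primary_plan.values()
        )
        if n_planted > self.n_cases:
            raise ConfigError(
                f"primary plan places {n_planted} carriers among {self.n_cases} cases"
            )
        for gene, g in self.primary_plan.items():
            if gene not in panel:
                raise ConfigError(f"primary plan gene {gene} not in panel")
            mode = panel.mode(gene)
            if g.n_dominant and mode != "dominant":
                raise ConfigError(f"{gene}: dominant primaries in a {mode} gene")
            if g.n_biallelic and mode != "recessive":
                raise ConfigError(f"{gene}: biallelic primaries in a {mode} gene")


@dataclass
class SimulationResult:
    cohort: CohortData
    truth: dict


def simulate(config: SimulationConfig, panel: GenePanel | None = None) -> SimulationResult:
    """Draw one synthetic cohort; same seed gives byte-identical output."""
    panel = panel or default_panel()
    config.validate(panel)
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls

    # variant pool
    variants: list[VariantRecord] = []
    log_lo, log_hi = np.log(config.maf_range[0]), np.log(config.maf_range[1])
    unknown_mend: list[VariantRecord] = []
    for gene in panel.mendelian_genes:
        for i in range(config.n_variants_per_gene):
            maf = float(np.exp(rng.uniform(log_lo, log_hi)))
            unknown_mend.append(_unknown_variant(gene, i, maf=round(maf, 6)))
    gba_vars: list[VariantRecord] = []
    n_gd = int(round(config.gd_fraction * config.n_variants_per_gene))
    for i in range(config.n_variants_per_gene):
        chrom, base = GENE_LOCI[GBA]
        curation = "gd_causing" if i < n_gd else "risk"
        gba_vars.append(
            VariantRecord(
                key=f"{chrom}:{base + 7 * i + 1}:C:T",
                gene=GBA,
                consequence="missense",
                maf_refs={"1000g": 0.001, "esp": 0.001},
                curation=curation,
            )
        )
    path_vars: dict[tuple[str, str], VariantRecord] = {}
    dom_label: dict[str, str] = {}
    for gene, gplan in config.primary_plan.items():
        if gplan.n_dominant:
            labels = [lab for (g, lab) in NAMED_ALLELES if g == gene
                      and lab not in ("pathA", "pathB")]
            dom_label[gene] = labels[0] if labels else "dom"
            path_vars[(gene, dom_label[gene])] = _named_variant(gene, dom_label[gene])
        if gplan.n_biallelic:
            path_vars[(gene, "pathA")] = _named_variant(gene, "pathA")
            path_vars[(gene, "pathB")] = _named_variant(gene, "pathB")
    variants = _sorted_variant_order(unknown_mend + gba_vars + list(path_vars.values()))
    col = {v.key: j for j, v in enumerate(variants)}

    # planted primaries among the cases
    plan_items = sorted(config.primary_plan.items())
    n_planted = sum(g.n_dominant + g.n_biallelic for _, g in plan_items)
    planted_idx = rng.choice(config.n_cases, size=n_planted, replace=False)
    planted_gene = np.full(n, "", dtype=object)
    cursor = 0
    cnvs: list[CnvCall] = []
    G = np.zeros((n, len(variants)), dtype=np.int8)
    sample_ids = [f"sim-{i:06d}" for i in range(n)]
    for gene, gplan in plan_items:
        for _ in range(gplan.n_dominant):
            si = planted_idx[cursor]
            cursor += 1
            G[si, col[path_vars[(gene, dom_label[gene])].key]] = 1
            planted_gene[si] = gene
        for bi in range(gplan.n_biallelic):
            si = planted_idx[cursor]
            cursor += 1
            planted_gene[si] = gene
            if bi < gplan.n_cnv:
                G[si, col[path_vars[(gene, "pathA")].key]] = 1
                cnvs.append(
                    CnvCall(sample_id=sample_ids[si], gene=gene, copy_number=1,
                            n_probes=15, validated=True)
                )
            elif bi % 2 == 0:
                G[si, col[path_vars[(gene, "pathA")].key]] = 1
                G[si, col[path_vars[(gene, "pathB")].key]] = 1
            else:
                G[si, col[path_vars[(gene, "pathA")].key]] = 2
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    is_known = planted_gene != ""

    # unknown Mendelian-gene variants: per-allele Bernoulli, odds tilted for
    # known-mutation cases
    base_f = np.array([v.maf_refs["1000g"] for v in unknown_mend])
    odds = base_f / (1 - base_f)
    enr_f = config.enrichment_or * odds / (1 + config.enrichment_or * odds)
    P = np.tile(base_f, (n, 1))
    P[is_known, :] = enr_f
    G_unknown = rng.binomial(2, P).astype(np.int8)
    for j, v in enumerate(unknown_mend):
        G[:, col[v.key]] = G_unknown[:, j]

    # GBA variants: per-group carrier probability converted to a per-variant
    # allele frequency q with 1 - (1 - q)^(2m) = p
    m = len(gba_vars)
    group = np.where(~is_case, GROUP_CONTROL, np.where(is_known, GROUP_KNOWN, GROUP_NO_KNOWN))
    q = np.zeros(n)
    for gname, p_carrier in config.gba_carrier_prob.items():
        q[group == gname] = 1.0 - (1.0 - p_carrier) ** (1.0 / (2 * m))
    G_gba = rng.binomial(2, np.tile(q[:, None], (1, m))).astype(np.int8)
    for j, v in enumerate(gba_vars):
        G[:, col[v.key]] = G_gba[:, j]

    mend_carrier = (G_unknown > 0).any(axis=1)
    gba_carrier = (G_gba > 0).any(axis=1)

    if config.genotype_missing_rate > 0:
        miss = rng.random(G.shape) < config.genotype_missing_rate
        G[miss] = MISSING

    # phenotypes
    sex = np.where(rng.random(n) < config.sex_female_prob, "F", "M")
    pcs = rng.normal(0.0, 1.0, size=(n, config.n_pcs))
    capture = rng.normal(1.0, 0.05, size=(n, 1)) if config.platform == "exome" else None
    aao = rng.normal(config.aao_mean, config.aao_sd, size=n)
    aao += config.aao_shift_mendelian * mend_carrier + config.aao_shift_gba * gba_carrier
    aao = np.clip(aao, 5.0, None)

    samples = [
        SampleRecord(
            id=sample_ids[i],
            status="case" if is_case[i] else "control",
            aao=round(float(aao[i]), 2) if is_case[i] else None,
            sex=str(sex[i]),
            pcs=tuple(round(float(x), 4) for x in pcs[i]),
            capture=tuple(round(float(x), 4) for x in capture[i]) if capture is not None else (),
            platform=config.platform,
        )
        for i in range(n)
    ]
    cohort = CohortData(variants=variants, genotypes=G, samples=samples, cnvs=cnvs,
                        platform=config.platform)
    truth = {
        "seed": config.seed,
        "group": group.tolist(),
        "planted_primary_gene": [g or None for g in planted_gene],
        "mendelian_additional_carrier": mend_carrier.tolist(),
        "gba_carrier": gba_carrier.tolist(),
        "enrichment_or": config.enrichment_or,
        "aao_shift_mendelian": config.aao_shift_mendelian,
        "aao_shift_gba": config.aao_shift_gba,
        "n_known_planted": int(is_known.sum()),
    }
    return SimulationResult(cohort=cohort, truth=truth)


# ---------------------------------------------------------------------------
# writing simulated inputs to the four on-disk artifacts
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort_inputs(cohort: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, annotation, phenotype and CNV files for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "annotation": outdir / "annotation.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "cnvs": outdir / "cnvs.tsv",
    }

    # VCF 4.2
    chroms: list[str] = []
    for v in cohort.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.id for s in cohort.samples)
    )
    for j, v in enumerate(cohort.variants):
        chrom, pos, ref, alt = v.key.split(":")
        gts = "\t".join(_GT[int(d)] for d in cohort.genotypes[:, j])
        lines.append(f"{chrom}\t{pos}\t{v.rsid or '.'}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    paths["vcf"].write_text("\n".join(lines) + "\n")

    # annotation
    ann = ["\t".join(ANNOTATION_COLUMNS)]
    for v in cohort.variants:
        ann.append(
            "\t".join(
                [
                    v.key,
                    v.rsid or "",
                    v.gene,
                    v.consequence,
                    f"{v.maf_refs['1000g']:.6f}" if "1000g" in v.maf_refs else "",
                    f"{v.maf_refs['esp']:.6f}" if "esp" in v.maf_refs else "",
                    v.curation,
                ]
            )
        )
    paths["annotation"].write_text("\n".join(ann) + "\n")

    # phenotypes
    n_pcs = len(cohort.samples[0].pcs) if cohort.samples else 0
    n_cap = max((len(s.capture) for s in cohort.samples), default=0)
    header = (
        ["id", "status", "aao", "sex"]
        + [f"pc{i+1}" for i in range(n_pcs)]
        + [f"capture{i+1}" for i in range(n_cap)]
        + ["platform"]
    )
    ph = ["\t".join(header)]
    for s in cohort.samples:
        row = [s.id, s.status, "" if s.aao is None else f"{s.aao}", s.sex]
        row += [f"{x}" for x in s.pcs]
        row += [f"{s.capture[i]}" if i < len(s.capture) else "" for i in range(n_cap)]
        row.append(s.platform)
        ph.append("\t".join(row))
    paths["phenotypes"].write_text("\n".join(ph) + "\n")

    # CNVs
    cv = ["sample_id\tgene\tcopy_number\tn_probes\tvalidated"]
    for c in cohort.cnvs:
        cv.append(f"{c.sample_id}\t{c.gene}\t{c.copy_number}\t{c.n_probes}\t{str(c.validated).lower()}")
    paths["cnvs"].write_text("\n".join(cv) + "\n")
    return paths
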