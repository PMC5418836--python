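"""Reading and validation of cohort inputs; writing of result tables.

A cohort is assembled from four artifacts:

* genotypes as VCF 4.x (read through cyvcf2; multi-allelic records are
  split into biallelic records before annotation matching),
* a tab-delimited variant annotation panel (key, rsid, gene, consequence,
  reference-panel MAFs, pathogenicity curation class),
* a tab-delimited phenotype table (sample id, case/control status, age at
  onset, sex, principal components, capture metrics, platform),
* tab-delimited gene-level CNV calls (PennCNV-style; calls spanning fewer
  than 10 probes are rejected at read time).

Variant identity is the string ``chrom:pos:ref:alt`` with 1-based
positions; rsIDs are annotation only.  Genotypes are stored as an
``int8`` sample x variant alternate-allele dosage matrix with ``-1`` for
missing; half-calls and non-diploid genotypes map to missing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GBA, GenePanel

logger = logging.getLogger(__name__)

MISSING = -1

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "inframe_indel",
    "synonymous",
    "other",
)
CURATIONS = ("pathogenic", "gd_causing", "risk", "unknown")

ANNOTATION_COLUMNS = ["key", "rsid", "gene", "consequence", "maf_1000g", "maf_esp", "curation"]
CNV_COLUMNS = ["sample_id", "gene", "copy_number", "n_probes", "validated"]
MIN_CNV_PROBES = 10


class CohortValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic variant site."""

    key: str
    gene: str
    consequence: str
    rsid: str | None = None
    maf_refs: dict[str, float] = field(default_factory=dict)
    curation: str = "unknown"
    platform_set: frozenset[str] = frozenset()
    #: eligible to be counted as an "additional" (modifier) variant; the
    #: variant filter clears this for curated pathogenic sites that are kept
    #: for primary-mutation detection despite failing the MAF filter.
    additional_eligible: bool = True

    def __post_init__(self) -> None:
        chrom, pos, ref, alt = parse_key(self.key)
        if pos < 1:
            raise CohortValidationError(f"{self.key}: position must be >= 1")
        if ref == alt:
            raise CohortValidationError(f"{self.key}: ref equals alt")
        if self.consequence not in CONSEQUENCES:
            raise CohortValidationError(f"{self.key}: unknown consequence {self.consequence!r}")
        if self.curation not in CURATIONS:
            raise CohortValidationError(f"{self.key}: unknown curation {self.curation!r}")
        if self.curation == "gd_causing" and self.gene != GBA:
            raise CohortValidationError(
                f"{self.key}: gd_causing curation is only valid for {GBA} (gene={self.gene})"
            )

    @property
    def chrom(self) -> str:
        return self.key.split(":", 1)[0]

    @property
    def pos(self) -> int:
        return int(self.key.split(":")[1])


def parse_key(key: str) -> tuple[str, int, str, str]:
    parts = key.split(":")
    if len(parts) != 4:
        raise CohortValidationError(f"malformed variant key {key!r} (want chrom:pos:ref:alt)")
    chrom, pos, ref, alt = parts
    try:
        pos_i = int(pos)
    except ValueError as exc:
        raise CohortValidationError(f"malformed variant key {key!r}: non-integer position") from exc
    return chrom, pos_i, ref, alt


@dataclass(frozen=True)
class SampleRecord:
    """One sample's phenotype row."""

    id: str
    status: str  # "case" | "control"
    aao: float | None
    sex: str  # "M" | "F"
    pcs: tuple[float, ...] = ()
    capture: tuple[float, ...] = ()
    platform: str = "neurox"

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise CohortValidationError(f"sample {self.id}: status must be case/control")
        if self.aao is not None:
            if self.status != "case":
                raise CohortValidationError(f"sample {self.id}: AAO present for a control")
            if self.aao <= 0:
                raise CohortValidationError(f"sample {self.id}: AAO must be > 0")


@dataclass(frozen=True)
class CnvCall:
    """One gene-level copy-number call."""

    sample_id: str
    gene: str
    copy_number: int
    n_probes: int
    validated: bool = False

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise CohortValidationError(f"CNV {self.sample_id}/{self.gene}: copy_number < 0")


@dataclass
class CohortData:
    """Genotypes, annotations, phenotypes and CNV calls for one platform."""

    variants: list[VariantRecord]
    genotypes: np.ndarray  # int8 (n_samples, n_variants); -1 = missing
    samples: list[SampleRecord]
    cnvs: list[CnvCall]
    platform: str

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        n_s, n_v = self.genotypes.shape if self.genotypes.ndim == 2 else (0, 0)
        if self.genotypes.ndim != 2:
            raise CohortValidationError("genotype matrix must be 2-D")
        if n_s != len(self.samples) or n_v != len(self.variants):
            raise CohortValidationError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = np.unique(self.genotypes)
        bad = set(vals.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise CohortValidationError(f"genotype matrix contains invalid entries {sorted(bad)}")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate sample IDs")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise CohortValidationError("duplicate variant keys")
        id_set = set(ids)
        for c in self.cnvs:
            if c.sample_id not in id_set:
                raise CohortValidationError(f"CNV call for unknown sample {c.sample_id}")
        pc_lens = {len(s.pcs) for s in self.samples}
        if len(pc_lens) > 1:
            raise CohortValidationError("inconsistent PC vector lengths across samples")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.key: i for i, v in enumerate(self.variants)}

    def sample_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.samples)}

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotypes as a DataFrame (covariate columns pc1.., capture1..)."""
        rows = []
        for s in self.samples:
            row: dict = {
                "id": s.id,
                "status": s.status,
                "aao": np.nan if s.aao is None else s.aao,
                "sex": s.sex,
                "platform": s.platform,
            }
            for i, v in enumerate(s.pcs, 1):
                row[f"pc{i}"] = v
            for i, v in enumerate(s.capture, 1):
                row[f"capture{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows).set_index("id", drop=False)

    def subset_variants(self, indices: np.ndarray | list[int]) -> "CohortData":
        indices = np.asarray(indices, dtype=int)
        return CohortData(
            variants=[self.variants[i] for i in indices],
            genotypes=self.genotypes[:, indices].copy(),
            samples=list(self.samples),
            cnvs=list(self.cnvs),
            platform=self.platform,
        )

    def subset_samples(self, mask: np.ndarray) -> "CohortData":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        keep = [self.samples[i] for i in idx]
        keep_ids = {s.id for s in keep}
        return CohortData(
            variants=list(self.variants),
            genotypes=self.genotypes[idx, :].copy(),
            samples=keep,
            cnvs=[c for c in self.cnvs if c.sample_id in keep_ids],
            platform=self.platform,
        )

    def with_variants(self, variants: list[VariantRecord]) -> "CohortData":
        """Same cohort with replaced variant records (e.g. eligibility flags)."""
        if len(variants) != self.n_variants:
            raise CohortValidationError("variant list length mismatch")
        return CohortData(
            variants=variants,
            genotypes=self.genotypes,
            samples=self.samples,
            cnvs=self.cnvs,
            platform=self.platform,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, platform: str | None = None) -> dict[str, VariantRecord]:
    """Read the variant annotation panel TSV into key -> VariantRecord."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise CohortValidationError(f"{path}: failed to parse annotation TSV: {exc}") from exc
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"{path}: annotation missing columns {sorted(missing_cols)}")
    records: dict[str, VariantRecord] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        key = row.key
        if key in records:
            raise CohortValidationError(f"{path} line {line_no}: annotation key collision {key}")
        maf_refs = {}
        for panel_name, raw in (("1000g", row.maf_1000g), ("esp", row.maf_esp)):
            if raw not in ("", "NA", "."):
                try:
                    maf_refs[panel_name] = float(raw)
                except ValueError as exc:
                    raise CohortValidationError(
                        f"{path} line {line_no}: bad MAF value {raw!r}"
                    ) from exc
        try:
            records[key] = VariantRecord(
                key=key,
                rsid=row.rsid or None,
                gene=row.gene,
                consequence=row.consequence,
                maf_refs=maf_refs,
                curation=row.curation or "unknown",
                platform_set=frozenset([platform] if platform else []),
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} line {line_no}: {exc}") from exc
    return records


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read the phenotype TSV (id, status, aao, sex, pc*, capture*, platform)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise CohortValidationError(f"{path}: failed to parse phenotype TSV: {exc}") from exc
    for col in ("id", "status", "sex", "platform"):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: phenotype table missing column {col!r}")
    pc_cols = sorted((c for c in df.columns if c.startswith("pc") and c[2:].isdigit()),
                     key=lambda c: int(c[2:]))
    cap_cols = sorted((c for c in df.columns if c.startswith("capture") and c[7:].isdigit()),
                      key=lambda c: int(c[7:]))
    samples = []
    seen: set[str] = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if d["id"] in seen:
            raise CohortValidationError(f"{path} line {line_no}: duplicate sample ID {d['id']}")
        seen.add(d["id"])
        aao_raw = d.get("aao", "")
        aao = None if aao_raw in ("", "NA", ".") else float(aao_raw)
        try:
            samples.append(
                SampleRecord(
                    id=d["id"],
                    status=d["status"],
                    aao=aao,
                    sex=d["sex"],
                    pcs=tuple(float(d[c]) for c in pc_cols),
                    capture=tuple(float(d[c]) for c in cap_cols if d[c] not in ("", "NA")),
                    platform=d["platform"],
                )
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path} line {line_no}: {exc}") from exc
    return samples


def read_cnvs(path: str | Path, min_probes: int = MIN_CNV_PROBES) -> list[CnvCall]:
    """Read CNV calls, rejecting calls spanning fewer than ``min_probes`` probes."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise CohortValidationError(f"{path}: failed to parse CNV TSV: {exc}") from exc
    missing_cols = set(CNV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"{path}: CNV table missing columns {sorted(missing_cols)}")
    calls = []
    n_rejected = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        n_probes = int(row.n_probes)
        if n_probes < min_probes:
            n_rejected += 1
            continue
        calls.append(
            CnvCall(
                sample_id=row.sample_id,
                gene=row.gene,
                copy_number=int(row.copy_number),
                n_probes=n_probes,
                validated=str(row.validated).lower() in ("1", "true", "yes"),
            )
        )
    if n_rejected:
        logger.info("%s: rejected %d CNV call(s) with < %d probes", path, n_rejected, min_probes)
    return calls


def _dosages_from_genotype(alleles: list[int], alt_index: int) -> int:
    """Alternate-allele dosage for one split allele; -1 for missing/half calls."""
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return MISSING
    return sum(1 for a in alleles if a == alt_index)


def read_vcf_genotypes(
    vcf_path: str | Path, annotation: dict[str, VariantRecord]
) -> tuple[list[VariantRecord], np.ndarray, list[str], int]:
    """Read a VCF, split multi-allelic records, and match sites to the annotation.

    Returns (matched variant records, dosage matrix, VCF sample ids,
    number of unmatched sites dropped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    matched: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(rec.ALT, start=1):
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            ann = annotation.get(key)
            if ann is None:
                n_dropped += 1
                continue
            col = np.fromiter(
                (_dosages_from_genotype(list(g[:-1]), alt_index) for g in gts),
                dtype=np.int8,
                count=len(sample_ids),
            )
            matched.append(ann)
            columns.append(col)
    if n_dropped:
        logger.info("%s: dropped %d VCF site(s) absent from the annotation", vcf_path, n_dropped)
    if columns:
        matrix = np.stack(columns, axis=1)
    else:
        matrix = np.zeros((len(sample_ids), 0), dtype=np.int8)
    keys_seen: set[str] = set()
    for v in matched:
        if v.key in keys_seen:
            raise CohortValidationError(f"{vcf_path}: duplicate variant key {v.key} after splitting")
        keys_seen.add(v.key)
    return matched, matrix, sample_ids, n_dropped


def read_cohort(
    vcf_path: str | Path,
    annotation_path: str | Path,
    phenotype_path: str | Path,
    cnv_path: str | Path | None,
    panel: GenePanel,
    platform: str | None = None,
) -> CohortData:
    """Assemble a validated :class:`CohortData` from the four input artifacts."""
    samples = read_phenotypes(phenotype_path)
    if platform is None:
        platforms = {s.platform for s in samples}
        platform = platforms.pop() if len(platforms) == 1 else "mixed"
    annotation = read_annotation(annotation_path, platform=platform)
    for rec in annotation.values():
        if rec.curation != "unknown" and rec.gene not in panel:
            raise CohortValidationError(
                f"curated variant {rec.key} in gene {rec.gene} outside the panel"
            )
    variants, matrix, vcf_sample_ids, _ = read_vcf_genotypes(vcf_path, annotation)
    by_id = {s.id: s for s in samples}
    missing_pheno = [sid for sid in vcf_sample_ids if sid not in by_id]
    if missing_pheno:
        raise CohortValidationError(
            f"{len(missing_pheno)} VCF sample(s) missing from the phenotype table "
            f"(first: {missing_pheno[0]})"
        )
    ordered = [by_id[sid] for sid in vcf_sample_ids]
    cnvs = read_cnvs(cnv_path) if cnv_path else []
    return CohortData(
        variants=variants, genotypes=matrix, samples=ordered, cnvs=cnvs, platform=platform
    )


# ---------------------------------------------------------------------------
# result-table writing
# ---------------------------------------------------------------------------


def fmt_freq(x: float | None) -> str:
    """Frequencies to 4 decimals; absent values as an en-dash."""
    return "–" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"


def fmt_or_ci(or_value: float | None, ci: tuple[float, float] | None) -> str:
    """Odds ratio with 95% CI to 2 decimals, e.g. ``1.70 (1.02–2.85)``.

    An undefined OR (a zero carrier cell) renders as ``0 –``.
    """
    if or_value is None or (isinstance(or_value, float) and math.isnan(or_value)):
        return "0 –"
    if ci is None:
        return f"{or_value:.2f}"
    return f"{or_value:.2f} ({ci[0]:.2f}–{ci[1]:.2f})"


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
        d["__type__"] = type(obj).__name__
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_table(result, path: str | Path, format: str = "tsv") -> None:
    """Write a result object (or list of results) as TSV or JSON.

    The JSON form is full precision and round-trips through
    :func:`read_table`; the TSV form follows the printed-table rendering
    conventions (frequencies to 4 decimals, ORs/CIs to 2 decimals).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = _jsonable(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown table format {format!r}")
    frame = result_frame(result)
    frame.to_csv(path, sep="\t", index=False)


def result_frame(result) -> pd.DataFrame:
    """Render one result object (or a homogeneous list) as a DataFrame."""
    from .aao_model import AaoResult
    from .burden_stats import BurdenResult, CarrierDistribution, GdSubsetResult

    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, list):
        if not result:
            return pd.DataFrame()
        frames = [result_frame(r) for r in result]
        return pd.concat(frames, ignore_index=True)
    if isinstance(result, CarrierDistribution):
        rows = [
            {
                "group": result.group,
                "category": result.category,
                "n_additional_variants": k,
                "n": result.counts[k],
                "freq": fmt_freq(result.freqs.get(k)),
            }
            for k in sorted(result.counts)
        ]
        return pd.DataFrame(rows)
    if isinstance(result, BurdenResult):
        return pd.DataFrame(
            [
                {
                    "comparison": result.label,
                    "category": result.category,
                    "model": result.model,
                    "n_a": result.n_a,
                    "n_b": result.n_b,
                    "carriers_a": result.carriers_a,
                    "carriers_b": result.carriers_b,
                    "or_ci": fmt_or_ci(result.or_adj, result.ci95),
                    "or_unadjusted": (
                        "NA" if result.or_unadjusted is None else f"{result.or_unadjusted:.2f}"
                    ),
                    "p": "NA" if result.p_raw is None else f"{result.p_raw:.3g}",
                    "p_fdr": "NA" if result.p_fdr is None else f"{result.p_fdr:.3g}",
                    "covariates": ";".join(result.covariates),
                    "flags": ";".join(result.flags),
                }
            ]
        )
    if isinstance(result, AaoResult):
        return pd.DataFrame(
            [
                {
                    "group": result.group,
                    "category": result.category,
                    "mean_with": "NA" if result.mean_with is None else f"{result.mean_with:.1f}",
                    "mean_without": (
                        "NA" if result.mean_without is None else f"{result.mean_without:.1f}"
                    ),
                    "coeff_ci": (
                        "NA"
                        if result.coeff is None
                        else f"{result.coeff:.2f} ({result.ci95[0]:.2f}; {result.ci95[1]:.2f})"
                    ),
                    "p": "NA" if result.p_raw is None else f"{result.p_raw:.3g}",
                    "p_fdr": "NA" if result.p_fdr is None else f"{result.p_fdr:.3g}",
                    "n_with": result.n_with,
                    "n_without": result.n_without,
                    "n_missing_aao": result.n_missing_aao,
                    "flags": ";".join(result.flags),
                }
            ]
        )
    if isinstance(result, GdSubsetResult):
        return pd.DataFrame(
            [
                {
                    "group": result.group,
                    "n_gd_het": result.n_flagged,
                    "n_gba_carriers": result.n_carriers,
                    "proportion": fmt_freq(result.proportion),
                }
            ]
        )
    raise TypeError(f"cannot render result of type {type(result).__name__}")


def read_table(path: str | Path):
    """Read back a JSON table written by :func:`write_table`."""
    from .aao_model import AaoResult
    from .burden_stats import BurdenResult, CarrierDistribution, GdSubsetResult

    types = {t.__name__: t for t in (AaoResult, BurdenResult, CarrierDistribution, GdSubsetResult)}

    def revive(obj):
        if isinstance(obj, list):
            return [revive(v) for v in obj]
        if isinstance(obj, dict) and "__type__" in obj:
            cls = types[obj.pop("__type__")]
            kwargs = {}
            for f in dataclasses.fields(cls):
                v = obj[f.name]
                if f.name in ("counts", "freqs") and isinstance(v, dict):
                    v = {int(k): val for k, val in v.items()}
                elif f.name in ("ci95",) and isinstance(v, list):
                    v = tuple(v)
                elif f.name in ("covariates", "flags") and isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return cls(**kwargs)
        return obj

    return revive(json.loads(Path(path).read_text()))
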