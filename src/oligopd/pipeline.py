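"""End-to-end orchestration: read -> filter -> classify -> burden -> AAO -> report.

A single :class:`RunConfig` (loadable from YAML) drives a full run.  The
result bundle contains the carrier-distribution, burden, AAO and
subset-enrichment tables, the per-sample classification table, the filter
report, and a manifest with the config hash and input checksums.  Output
depends only on inputs and config: re-running with identical inputs gives
a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .aao_model import AaoResult, aao_regression
from .burden_stats import (
    GROUP_ALL_PD,
    AnalysisRequest,
    apply_fdr,
    bh_fdr,
    carrier_distribution,
    gd_subset,
    run_analyses,
)
from .classify import GROUPS, classification_frame, classify_cohort
from .cohort_io import read_cohort, write_table
from .panel import GenePanel, default_panel
from .variant_filter import DEFAULT_MAF, DEFAULT_MISS, filter_variants

logger = logging.getLogger(__name__)

_VALID_GROUPS = set(GROUPS) | {GROUP_ALL_PD}


def _default_comparisons() -> list[dict]:
    out = []
    for category in ("mendelian", "gba"):
        for a, b in (
            ("known_mutation_pd", "control"),
            ("no_known_mutation_pd", "control"),
            ("known_mutation_pd", "no_known_mutation_pd"),
        ):
            for kind in ("carrier", "allele"):
                out.append(
                    {"kind": kind, "group_a": a, "group_b": b, "category": category,
                     "label": f"{a} vs {b} [{category}/{kind}]"}
                )
    return out


def _default_aao() -> list[dict]:
    return [
        {"group": g, "category": c}
        for g in (GROUP_ALL_PD, "known_mutation_pd", "no_known_mutation_pd")
        for c in ("mendelian", "gba")
    ]


@dataclass
class RunConfig:
    vcf: str
    annotation: str
    phenotypes: str
    cnvs: str | None = None
    platform: str | None = None
    panel: dict[str, str] | None = None
    maf_threshold: float = DEFAULT_MAF
    miss_threshold: float = DEFAULT_MISS
    covariates: list[str] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=_default_comparisons)
    subsets: list[dict] = field(default_factory=list)
    aao: list[dict] = field(default_factory=_default_aao)
    pathogenic_gains: list[str] = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def gene_panel(self) -> GenePanel:
        return GenePanel(self.panel) if self.panel else default_panel()

    def validate(self) -> None:
        panel = self.gene_panel()
        for comp in self.comparisons:
            for side in ("group_a", "group_b"):
                g = comp.get(side)
                if g not in _VALID_GROUPS:
                    raise ValueError(f"comparison references unknown group {g!r}")
        for sub in self.subsets:
            for gene in sub.get("genes", ()):
                if gene not in panel:
                    raise ValueError(f"subset references unknown gene {gene!r}")
            if sub.get("case_gene") and sub["case_gene"] not in panel:
                raise ValueError(f"subset case_gene {sub['case_gene']!r} not in panel")
        for a in self.aao:
            if a.get("group") not in _VALID_GROUPS:
                raise ValueError(f"aao analysis references unknown group {a.get('group')!r}")

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # hash the analysis, not where it lands
        return json.dumps(d, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _requests(config: RunConfig) -> list[AnalysisRequest]:
    reqs = []
    for comp in config.comparisons:
        reqs.append(
            AnalysisRequest(
                kind=comp["kind"],
                label=comp.get("label", f"{comp['group_a']} vs {comp['group_b']}"),
                group_a=comp["group_a"],
                group_b=comp["group_b"],
                category=comp.get("category", "mendelian"),
                covariates=tuple(comp.get("covariates", config.covariates)),
            )
        )
    for sub in config.subsets:
        reqs.append(
            AnalysisRequest(
                kind="subset",
                label=sub.get("label", f"subset {'+'.join(sub['genes'])}"),
                group_b=sub.get("group_b", "control"),
                gene_subset=tuple(sub["genes"]),
                case_gene=sub.get("case_gene"),
                case_variant=sub.get("case_variant"),
            )
        )
    return reqs


def run_pipeline(config: RunConfig, cohort=None) -> dict:
    """Execute a full run; returns the result bundle and writes ``out_dir``.

    ``cohort`` may be supplied directly (e.g. a fixture) to skip file input.
    """
    config.validate()
    panel = config.gene_panel()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        if cohort is None:
            cohort = read_cohort(
                config.vcf, config.annotation, config.phenotypes, config.cnvs, panel,
                platform=config.platform,
            )
        stage = "filter"
        filtered, report = filter_variants(
            cohort, panel, config.maf_threshold, config.miss_threshold
        )
        stage = "classify"
        classifications = classify_cohort(
            filtered, panel, frozenset(config.pathogenic_gains)
        )
        samples = filtered.samples

        stage = "tabulate"
        distributions = [
            carrier_distribution(classifications, group, category)
            for group in GROUPS
            for category in ("mendelian", "gba")
        ]
        stage = "burden"
        burden_results = run_analyses(classifications, samples, _requests(config))
        stage = "aao"
        aao_results: list[AaoResult] = []
        for spec in config.aao:
            aao_results.append(
                aao_regression(
                    classifications,
                    samples,
                    spec["group"],
                    spec.get("category", "mendelian"),
                    tuple(spec.get("covariates", config.covariates)),
                )
            )
        aao_p = [r.p_raw if r.p_raw is not None else float("nan") for r in aao_results]
        for r, q in zip(aao_results, bh_fdr(aao_p)):
            r.p_fdr = None if q != q else float(q)
        stage = "gd"
        gd_results = [gd_subset(classifications, g) for g in GROUPS]

        stage = "write"
        write_table(distributions, out / "table1_carrier_distributions.tsv", "tsv")
        write_table(distributions, out / "table1_carrier_distributions.json", "json")
        write_table(burden_results, out / "table2_burden.tsv", "tsv")
        write_table(burden_results, out / "table2_burden.json", "json")
        write_table(aao_results, out / "table3_aao.tsv", "tsv")
        write_table(aao_results, out / "table3_aao.json", "json")
        write_table(gd_results, out / "gd_subset.tsv", "tsv")
        classification_frame(classifications).to_csv(
            out / "classifications.tsv", sep="\t", index=False
        )
        report.to_json(out / "filter_report.json")
        manifest = {
            "tool": "oligopd",
            "version": __version__,
            "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
            "inputs": {
                name: _sha256(p)
                for name, p in (
                    ("vcf", config.vcf),
                    ("annotation", config.annotation),
                    ("phenotypes", config.phenotypes),
                    ("cnvs", config.cnvs),
                )
                if p and Path(p).exists()
            },
            "n_variants": report.n_variants_out,
            "n_samples": report.n_samples_out,
            "outputs": sorted(
                p.name for p in out.iterdir() if p.name != "manifest.json"
            ),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "cohort": filtered,
        "filter_report": report,
        "classifications": classifications,
        "distributions": distributions,
        "burden": burden_results,
        "aao": aao_results,
        "gd": gd_results,
    }
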