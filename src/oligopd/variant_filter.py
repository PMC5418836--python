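"""QC and rare-variant filtering.

The analysis set keeps rare (MAF < 1% in every reference panel where the
variant is observed; unobserved counts as rare), non-synonymous variants
in panel genes, then applies call-rate thresholds: variants with > 5%
missing calls are removed first, then samples with > 5% missing calls
over the retained variants.  The order is fixed (variant-level then
sample-level, one pass each) so results are deterministic.

Curated pathogenic variants that fail the MAF filter are retained so that
primary-mutation detection does not depend on population frequency, but
they are marked ineligible for additional-variant counting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import MISSING, CohortData
from .panel import GenePanel

logger = logging.getLogger(__name__)

DEFAULT_MAF = 0.01
DEFAULT_MISS = 0.05


@dataclass
class FilterReport:
    """Per-filter removal accounting for one cohort."""

    n_variants_in: int = 0
    n_variants_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    #: order in which filters were applied
    filter_order: tuple[str, ...] = (
        "off_panel",
        "synonymous",
        "maf",
        "missingness_variant",
        "missingness_sample",
    )
    #: curated pathogenic variants kept despite failing the MAF filter
    n_pathogenic_rescued: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def check(self) -> None:
        assert all(v >= 0 for v in self.removed.values())
        n_var_removed = sum(
            self.removed.get(k, 0) for k in ("off_panel", "synonymous", "maf", "missingness_variant")
        )
        assert self.n_variants_in - n_var_removed == self.n_variants_out
        assert self.n_samples_in - self.removed.get("missingness_sample", 0) == self.n_samples_out


def is_rare(variant, maf_threshold: float = DEFAULT_MAF) -> bool:
    """Rare iff MAF < threshold in every reference panel where observed."""
    return all(f < maf_threshold for f in variant.maf_refs.values())


def filter_variants(
    cohort: CohortData,
    panel: GenePanel,
    maf_threshold: float = DEFAULT_MAF,
    miss_threshold: float = DEFAULT_MISS,
) -> tuple[CohortData, FilterReport]:
    """Apply the QC and rare-variant filters; returns the filtered cohort and report."""
    report = FilterReport(
        n_variants_in=cohort.n_variants,
        n_samples_in=cohort.n_samples,
        removed={k: 0 for k in FilterReport().filter_order},
    )
    G = cohort.genotypes
    keep = np.ones(cohort.n_variants, dtype=bool)
    new_variants = list(cohort.variants)
    for j, v in enumerate(cohort.variants):
        if v.gene not in panel:
            keep[j] = False
            report.removed["off_panel"] += 1
            continue
        if v.consequence == "synonymous":
            keep[j] = False
            report.removed["synonymous"] += 1
            continue
        if not is_rare(v, maf_threshold):
            if v.curation == "pathogenic":
                # kept for primary-mutation detection only
                new_variants[j] = dataclasses.replace(v, additional_eligible=False)
                report.n_pathogenic_rescued += 1
            else:
                keep[j] = False
                report.removed["maf"] += 1

    # variant-level missingness over all samples, on the surviving set
    if cohort.n_samples:
        var_miss = (G == MISSING).mean(axis=0)
        for j in np.flatnonzero(keep):
            if var_miss[j] > miss_threshold:
                keep[j] = False
                report.removed["missingness_variant"] += 1

    kept_idx = np.flatnonzero(keep)
    filtered = CohortData(
        variants=[new_variants[i] for i in kept_idx],
        genotypes=G[:, kept_idx].copy(),
        samples=list(cohort.samples),
        cnvs=list(cohort.cnvs),
        platform=cohort.platform,
    )

    # sample-level missingness over the retained variants only
    if filtered.n_variants:
        sample_miss = (filtered.genotypes == MISSING).mean(axis=1)
        sample_keep = sample_miss <= miss_threshold
    else:
        sample_keep = np.ones(filtered.n_samples, dtype=bool)
    report.removed["missingness_sample"] = int((~sample_keep).sum())
    if not sample_keep.all():
        filtered = filtered.subset_samples(sample_keep)

    report.n_variants_out = filtered.n_variants
    report.n_samples_out = filtered.n_samples
    report.check()
    if filtered.n_variants == 0:
        logger.warning("variant filter retained zero variants")
    return filtered, report


def intersect_platforms(
    cohort_a: CohortData, cohort_b: CohortData
) -> tuple[CohortData, CohortData]:
    """Restrict both cohorts to the variants common to both platforms.

    Variant order in both outputs follows cohort_a's order over the shared
    keys; sample sets are unchanged.
    """
    keys_b = set(cohort_b.variant_keys)
    shared = [k for k in cohort_a.variant_keys if k in keys_b]
    if not shared:
        logger.warning("platform intersection is empty")
    idx_a = cohort_a.variant_index()
    idx_b = cohort_b.variant_index()
    a = cohort_a.subset_variants([idx_a[k] for k in shared])
    b = cohort_b.subset_variants([idx_b[k] for k in shared])
    return a, b
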