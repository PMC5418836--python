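import numpy as np
import pytest

from oligopd.classify import classify_cohort
from oligopd.cohort_io import CohortData, SampleRecord, VariantRecord
from oligopd.panel import default_panel
from oligopd.plans import combined_g2019s_plan, exome_plan, neurox_plan
from oligopd.synth_cohort import build_fixture
from oligopd.variant_filter import filter_variants


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_variant(
    gene: str,
    pos: int = 100,
    chrom: str = "1",
    consequence: str = "missense",
    curation: str = "unknown",
    mafs: dict | None = None,
    ref: str = "A",
    alt: str = "G",
) -> VariantRecord:
    return VariantRecord(
        key=f"{chrom}:{pos}:{ref}:{alt}",
        gene=gene,
        consequence=consequence,
        curation=curation,
        maf_refs={"1000g": 0.001, "esp": 0.001} if mafs is None else mafs,
    )


def make_cohort(
    variants: list[VariantRecord],
    genotypes: list[list[int]],
    statuses: list[str] | None = None,
    aaos: list[float | None] | None = None,
    cnvs: list | None = None,
    platform: str = "neurox",
) -> CohortData:
    """Compact toy-cohort builder for unit tests."""
    G = np.asarray(genotypes, dtype=np.int8)
    if G.ndim == 1:
        G = G.reshape(1, -1)
    n = G.shape[0]
    statuses = statuses or ["case"] * n
    aaos = aaos or [None] * n
    samples = [
        SampleRecord(
            id=f"s{i}",
            status=statuses[i],
            aao=aaos[i] if statuses[i] == "case" else None,
            sex="M" if i % 2 == 0 else "F",
            pcs=(0.0,),
            platform=platform,
        )
        for i in range(n)
    ]
    return CohortData(
        variants=variants, genotypes=G, samples=samples, cnvs=list(cnvs or []),
        platform=platform,
    )


@pytest.fixture(scope="session")
def neurox(panel):
    """Filtered chip-cohort fixture with classifications."""
    cohort = build_fixture(neurox_plan())
    filtered, report = filter_variants(cohort, panel)
    return filtered, classify_cohort(filtered, panel), report


@pytest.fixture(scope="session")
def exome(panel):
    cohort = build_fixture(exome_plan())
    filtered, _ = filter_variants(cohort, panel)
    return filtered, classify_cohort(filtered, panel)


@pytest.fixture(scope="session")
def combined(panel):
    cohort = build_fixture(combined_g2019s_plan())
    filtered, _ = filter_variants(cohort, panel)
    return filtered, classify_cohort(filtered, panel)
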