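"""Published-count fixture plans.

These factories encode, as :class:`~oligopd.synth_cohort.FixturePlan`
blocks, the published per-group carrier-count distributions, primary
mutation composition, GD-heterozygote counts and group AAO summaries of
the two study cohorts (a NeuroX genotyping-chip cohort of 6,647 cases /
5,693 controls and an exome-sequencing cohort of 1,253 cases / 473
controls), plus the combined-platform LRRK2 G2019S subset.  Running the
full pipeline over these cohorts reproduces the published proportions
exactly.

The raw study genotypes are access-controlled; these plans are synthetic
reconstructions consistent with the printed marginal counts, not the
original data.  Where the publication leaves a choice open (which genes
the additional variants of the unlabelled groups fall in, which samples
lack AAO), the assignment here is an arbitrary deterministic one that
leaves every printed margin intact.
"""

from __future__ import annotations

from .synth_cohort import (
    GROUP_CONTROL,
    GROUP_KNOWN,
    GROUP_NO_KNOWN,
    ConfigError,
    FixturePlan,
    PrimarySpec,
    SampleBlock,
)

G2019S = PrimarySpec("LRRK2", "dominant", "G2019S")
LRRK2_OTHER = PrimarySpec("LRRK2", "dominant", "R1441C")
VPS35_D620N = PrimarySpec("VPS35", "dominant", "D620N")
SNCA_A53T = PrimarySpec("SNCA", "dominant", "A53T")
PARK2_HOM = PrimarySpec("PARK2", "hom")
PARK2_CHET = PrimarySpec("PARK2", "chet")
PARK2_SNV_CNV = PrimarySpec("PARK2", "snv_cnv")


def _check_totals(plan: FixturePlan, expected: dict[str, int]) -> FixturePlan:
    for group, n in expected.items():
        got = plan.group_size(group)
        if got != n:
            raise ConfigError(f"{plan.platform}: group {group} totals {got}, expected {n}")
    return plan


def neurox_plan() -> FixturePlan:
    """Chip cohort: 89 known-mutation cases, 6,558 other cases, 5,693 controls."""
    B = SampleBlock
    blocks = (
        # known-mutation cases: 75 G2019S + 3 other LRRK2 + 1 VPS35 + 10 PARK2
        B(GROUP_KNOWN, 6, (G2019S,), additional=("ATP13A2",), aao=56.8),
        B(GROUP_KNOWN, 5, (G2019S,), additional=("PINK1",), aao=56.8),
        B(GROUP_KNOWN, 2, (G2019S,), additional=("SNCA",), aao=56.8),
        B(GROUP_KNOWN, 5, (G2019S,), gba=("gd",), aao=62.7),
        B(GROUP_KNOWN, 2, (G2019S,), gba=("risk",), aao=62.7),
        B(GROUP_KNOWN, 54, (G2019S,), aao=62.7),
        B(GROUP_KNOWN, 1, (G2019S,), aao=None),
        B(GROUP_KNOWN, 1, (LRRK2_OTHER,), additional=("SNCA",), aao=None),
        B(GROUP_KNOWN, 2, (LRRK2_OTHER,), aao=None),
        B(GROUP_KNOWN, 1, (VPS35_D620N,), aao=None),
        B(GROUP_KNOWN, 1, (PARK2_CHET,), additional=("FBXO7",), aao=None),
        B(GROUP_KNOWN, 4, (PARK2_HOM,), aao=None),
        B(GROUP_KNOWN, 4, (PARK2_CHET,), aao=None),
        B(GROUP_KNOWN, 1, (PARK2_SNV_CNV,), aao=None),
        # other cases: additional-variant carriers (disjoint from GBA carriers)
        B(GROUP_NO_KNOWN, 634, additional=("PARK7",), aao=61.5),
        B(GROUP_NO_KNOWN, 38, additional=("PARK7", "PLA2G6"), aao=61.5),
        B(GROUP_NO_KNOWN, 5, additional=("PARK7", "PLA2G6", "FBXO7"), aao=61.5),
        B(GROUP_NO_KNOWN, 330, gba=("gd",), aao=59.2),
        B(GROUP_NO_KNOWN, 31, gba=("gd",), aao=None),
        B(GROUP_NO_KNOWN, 158, gba=("risk",), aao=59.2),
        B(GROUP_NO_KNOWN, 32, gba=("risk",), aao=None),
        B(GROUP_NO_KNOWN, 12, gba=("u1", "u2"), aao=59.2),
        B(GROUP_NO_KNOWN, 4536, aao=61.5),
        B(GROUP_NO_KNOWN, 782, aao=None),
        # controls
        B(GROUP_CONTROL, 163, additional=("ATP13A2",)),
        B(GROUP_CONTROL, 160, additional=("PINK1",)),
        B(GROUP_CONTROL, 176, additional=("SNCA",)),
        B(GROUP_CONTROL, 24, additional=("SNCA", "EIF4G1")),
        B(GROUP_CONTROL, 1, additional=("SNCA", "EIF4G1", "LRRK2")),
        B(GROUP_CONTROL, 164, gba=("gd",)),
        B(GROUP_CONTROL, 98, gba=("risk",)),
        B(GROUP_CONTROL, 2, gba=("u1", "u2")),
        B(GROUP_CONTROL, 4905),
    )
    return _check_totals(
        FixturePlan(platform="neurox", blocks=blocks),
        {GROUP_KNOWN: 89, GROUP_NO_KNOWN: 6558, GROUP_CONTROL: 5693},
    )


def exome_plan() -> FixturePlan:
    """Exome cohort: 18 known-mutation cases, 1,235 other cases, 473 controls."""
    B = SampleBlock
    blocks = (
        # known-mutation cases: 7 G2019S + 2 other LRRK2 + 6 PARK2 + 2 SNCA + 1 VPS35
        B(GROUP_KNOWN, 1, (G2019S,), additional=("ATP13A2",), aao=38.3),
        B(GROUP_KNOWN, 1, (G2019S,), additional=("PARK7",), aao=38.3),
        B(GROUP_KNOWN, 4, (G2019S,), aao=42.3),
        B(GROUP_KNOWN, 1, (G2019S,), aao=None),
        B(GROUP_KNOWN, 1, (LRRK2_OTHER,), aao=42.3),
        B(GROUP_KNOWN, 1, (LRRK2_OTHER,), aao=None),
        B(GROUP_KNOWN, 1, (PARK2_CHET,), additional=("PLA2G6",), aao=38.3),
        B(GROUP_KNOWN, 1, (PARK2_CHET,), additional=("PLA2G6",), aao=None),
        B(GROUP_KNOWN, 3, (PARK2_HOM,), aao=42.3),
        B(GROUP_KNOWN, 1, (PARK2_CHET,), aao=42.3),
        B(GROUP_KNOWN, 1, (SNCA_A53T,), additional=("PINK1",), aao=38.3),
        B(GROUP_KNOWN, 1, (SNCA_A53T,), aao=42.3),
        B(GROUP_KNOWN, 1, (VPS35_D620N,), additional=("PARK7", "FBXO7"), aao=38.3),
        # other cases
        B(GROUP_NO_KNOWN, 181, additional=("PARK7",), aao=41.9),
        B(GROUP_NO_KNOWN, 20, additional=("PARK7", "PLA2G6"), aao=41.9),
        B(GROUP_NO_KNOWN, 2, additional=("PARK7", "PLA2G6", "FBXO7"), aao=41.9),
        B(GROUP_NO_KNOWN, 1, additional=("PARK7", "PLA2G6", "FBXO7", "PINK1"), aao=41.9),
        B(GROUP_NO_KNOWN, 50, gba=("risk",), aao=42.4),
        B(GROUP_NO_KNOWN, 76, gba=("risk",), aao=None),
        B(GROUP_NO_KNOWN, 1, gba=("u1", "u2"), aao=None),
        B(GROUP_NO_KNOWN, 876, aao=43.3),
        B(GROUP_NO_KNOWN, 28, aao=None),
        # controls
        B(GROUP_CONTROL, 8, additional=("ATP13A2",)),
        B(GROUP_CONTROL, 34, additional=("PINK1",)),
        B(GROUP_CONTROL, 27, additional=("SNCA",)),
        B(GROUP_CONTROL, 4, additional=("SNCA", "EIF4G1")),
        B(GROUP_CONTROL, 22, gba=("risk",)),
        B(GROUP_CONTROL, 378),
    )
    return _check_totals(
        FixturePlan(platform="exome", blocks=blocks),
        {GROUP_KNOWN: 18, GROUP_NO_KNOWN: 1235, GROUP_CONTROL: 473},
    )


def combined_g2019s_plan() -> FixturePlan:
    """Combined-platform G2019S subset: 82 G2019S cases vs 6,166 controls.

    Encodes the published combined column as given (its control counts
    reflect the platform-intersection variant set, not per-cohort sums).
    """
    B = SampleBlock
    blocks = (
        B(GROUP_KNOWN, 7, (G2019S,), additional=("ATP13A2",)),
        B(GROUP_KNOWN, 6, (G2019S,), additional=("PINK1",)),
        B(GROUP_KNOWN, 2, (G2019S,), additional=("SNCA",)),
        B(GROUP_KNOWN, 67, (G2019S,)),
        B(GROUP_CONTROL, 146, additional=("ATP13A2",)),
        B(GROUP_CONTROL, 233, additional=("PINK1",)),
        B(GROUP_CONTROL, 5787),
    )
    return _check_totals(
        FixturePlan(platform="combined", blocks=blocks),
        {GROUP_KNOWN: 82, GROUP_CONTROL: 6166},
    )
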