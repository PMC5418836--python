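"""Case-control burden and enrichment statistics.

Implements the comparative analyses over sample classifications:

* carrier-count distributions per group (how many samples carry 0, 1, 2,
  ... additional variants),
* logistic-regression burden tests of group membership on carrier status
  (>= 1 additional variant) or on the per-sample additional-allele sum,
  with configurable covariates, Wald CIs and p-values; the unadjusted
  cross-product odds ratio from the 2x2 carrier table is always reported
  alongside,
* gene-subset enrichment by two-sided Fisher's exact test (e.g. additional
  variants within recessive genes among LRRK2 G2019S carriers),
* the GD-heterozygote fraction among GBA carriers of a group,
* Benjamini-Hochberg FDR adjustment across a configurable family,
* sensitivity re-runs with listed variants removed from additional-variant
  eligibility (primary classification unchanged).

Separation and collinearity are detected and flagged, never silently
corrected; undefined odds ratios (a zero carrier cell) propagate as NA and
render as ``0 –`` only in the table writer.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classify import GROUP_CONTROL, GROUP_KNOWN, GROUP_NO_KNOWN, SampleClassification
from .cohort_io import CohortData, SampleRecord
from .panel import GenePanel

CATEGORIES = ("mendelian", "gba")

#: pseudo-group: union of both case groups
GROUP_ALL_PD = "all_pd"


@dataclass
class CarrierDistribution:
    group: str
    category: str
    counts: dict[int, int] = field(default_factory=dict)
    freqs: dict[int, float] = field(default_factory=dict)
    n: int = 0


@dataclass
class BurdenResult:
    label: str
    category: str
    model: str  # carrier_logistic | allele_sum_logistic | fisher
    n_a: int
    n_b: int
    carriers_a: int
    carriers_b: int
    or_adj: float | None = None
    ci95: tuple[float, float] | None = None
    p_raw: float | None = None
    p_fdr: float | None = None
    or_unadjusted: float | None = None
    covariates: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


@dataclass
class GdSubsetResult:
    group: str
    n_flagged: int
    n_carriers: int
    proportion: float | None


def in_group(classification: SampleClassification, group: str) -> bool:
    if group == GROUP_ALL_PD:
        return classification.group in (GROUP_KNOWN, GROUP_NO_KNOWN)
    return classification.group == group


def _select(classifications: Sequence[SampleClassification], group: str):
    return [c for c in classifications if in_group(c, group)]


def carrier_distribution(
    classifications: Sequence[SampleClassification], group: str, category: str
) -> CarrierDistribution:
    """Tabulate additional-variant counts per sample for one group."""
    members = _select(classifications, group)
    counts: dict[int, int] = {}
    for c in members:
        k = c.count(category)
        counts[k] = counts.get(k, 0) + 1
    n = len(members)
    freqs = {k: v / n for k, v in counts.items()} if n else {}
    return CarrierDistribution(group=group, category=category, counts=counts, freqs=freqs, n=n)


def cross_product_or(a1: int, a0: int, b1: int, b0: int) -> float | None:
    """Unadjusted OR (a1*b0)/(a0*b1); None if any cell is zero."""
    if min(a1, a0, b1, b0) <= 0:
        return None
    return (a1 * b0) / (a0 * b1)


def _covariate_matrix(
    samples: Sequence[SampleRecord], ids: Sequence[str], covariates: Sequence[str]
) -> pd.DataFrame:
    by_id = {s.id: s for s in samples}
    rows = []
    for sid in ids:
        s = by_id[sid]
        row: dict[str, float] = {}
        for name in covariates:
            if name == "sex":
                row["sex"] = 1.0 if s.sex == "F" else 0.0
            elif name == "platform":
                row["platform"] = 1.0 if s.platform == "exome" else 0.0
            elif name.startswith("pc"):
                i = int(name[2:]) - 1
                row[name] = s.pcs[i] if i < len(s.pcs) else 0.0
            elif name.startswith("capture"):
                i = int(name[7:]) - 1
                row[name] = s.capture[i] if i < len(s.capture) else 0.0
            else:
                raise ValueError(f"unknown covariate {name!r}")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(covariates), dtype=float)


def _fit_logistic(
    y: np.ndarray, predictor: np.ndarray, covar: pd.DataFrame
) -> tuple[float | None, tuple[float, float] | None, float | None, tuple[str, ...]]:
    """Fit logit(y) ~ predictor + covariates; returns (OR, CI, p, flags)."""
    flags: list[str] = []
    X = pd.DataFrame({"x": predictor.astype(float)})
    for c in covar.columns:
        X[c] = covar[c].to_numpy()
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        return None, None, None, ("collinear",)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence issues surface as flags
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, None, None, ("separation",)
    if not fit.mle_retvals.get("converged", False):
        flags.append("nonconvergence")
        return None, None, None, tuple(flags)
    beta = float(fit.params["x"])
    se = float(fit.bse["x"])
    if not np.isfinite(se) or se > 50:
        return None, None, None, ("separation",)
    or_adj = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    p = float(fit.pvalues["x"])
    return or_adj, ci, p, tuple(flags)


def _burden(
    classifications: Sequence[SampleClassification],
    samples: Sequence[SampleRecord],
    group_a: str,
    group_b: str,
    category: str,
    covariates: Sequence[str],
    predictor_kind: str,
    label: str | None,
) -> BurdenResult:
    a = _select(classifications, group_a)
    b = _select(classifications, group_b)
    if not a or not b:
        raise ValueError(f"empty group in comparison {group_a} vs {group_b}")
    carriers_a = sum(1 for c in a if c.count(category) >= 1)
    carriers_b = sum(1 for c in b if c.count(category) >= 1)
    label = label or f"{group_a} vs {group_b}"
    model = "carrier_logistic" if predictor_kind == "carrier" else "allele_sum_logistic"
    result = BurdenResult(
        label=label,
        category=category,
        model=model,
        n_a=len(a),
        n_b=len(b),
        carriers_a=carriers_a,
        carriers_b=carriers_b,
        or_unadjusted=cross_product_or(
            carriers_a, len(a) - carriers_a, carriers_b, len(b) - carriers_b
        ),
        covariates=tuple(covariates),
    )
    if carriers_a == 0 or carriers_b == 0:
        result.flags = ("zero_carriers",)
        return result
    members = a + b
    y = np.array([1.0] * len(a) + [0.0] * len(b))
    if predictor_kind == "carrier":
        x = np.array([float(c.count(category) >= 1) for c in members])
    else:
        x = np.array([float(c.alleles(category)) for c in members])
    if np.all(x == x[0]):
        result.flags = ("degenerate_predictor",)
        return result
    covar = _covariate_matrix(samples, [c.sample_id for c in members], covariates)
    or_adj, ci, p, flags = _fit_logistic(y, x, covar)
    result.or_adj, result.ci95, result.p_raw, result.flags = or_adj, ci, p, flags
    return result


def carrier_burden(
    classifications: Sequence[SampleClassification],
    samples: Sequence[SampleRecord],
    group_a: str,
    group_b: str,
    category: str = "mendelian",
    covariates: Sequence[str] = (),
    label: str | None = None,
) -> BurdenResult:
    """Logistic regression of group membership on carrier status (>= 1 variant)."""
    return _burden(classifications, samples, group_a, group_b, category, covariates,
                   "carrier", label)


def allele_burden(
    classifications: Sequence[SampleClassification],
    samples: Sequence[SampleRecord],
    group_a: str,
    group_b: str,
    category: str = "mendelian",
    covariates: Sequence[str] = (),
    label: str | None = None,
) -> BurdenResult:
    """Logistic regression of group membership on the additional-allele sum."""
    return _burden(classifications, samples, group_a, group_b, category, covariates,
                   "alleles", label)


def primary_gene_filter(gene: str, variant_key: str | None = None) -> Callable[[SampleClassification], bool]:
    """Case filter: primary mutation in ``gene`` (optionally a specific variant)."""

    def pred(c: SampleClassification) -> bool:
        for m in c.primary_mutations:
            if m.gene == gene and (variant_key is None or m.key == variant_key):
                return True
        return False

    return pred


def subset_enrichment(
    classifications: Sequence[SampleClassification],
    gene_subset: Iterable[str],
    case_filter: Callable[[SampleClassification], bool],
    controls: Sequence[SampleClassification],
    label: str | None = None,
) -> BurdenResult:
    """Two-sided Fisher's exact test on carriage of additional variants in a gene subset.

    A carrier has >= 1 additional variant in any gene of ``gene_subset``.
    Cases are the classifications passing ``case_filter`` (typically
    selected by primary-mutation gene/variant); ``controls`` is the
    comparison group's classifications.
    """
    subset = set(gene_subset)

    def is_carrier(c: SampleClassification) -> bool:
        return any(c.genes_hit.get(g, 0) >= 1 for g in subset)

    cases = [c for c in classifications if case_filter(c)]
    ca = sum(1 for c in cases if is_carrier(c))
    cb = sum(1 for c in controls if is_carrier(c))
    na, nb = len(cases), len(controls)
    table = np.array([[ca, na - ca], [cb, nb - cb]])
    if table.sum() == 0 or not subset:
        p = 1.0
    else:
        p = float(fisher_exact(table, alternative="two-sided")[1])
    return BurdenResult(
        label=label or f"subset {'+'.join(sorted(subset))}",
        category="mendelian",
        model="fisher",
        n_a=na,
        n_b=nb,
        carriers_a=ca,
        carriers_b=cb,
        or_unadjusted=cross_product_or(ca, na - ca, cb, nb - cb),
        p_raw=p,
    )


def gd_subset(
    classifications: Sequence[SampleClassification], group: str
) -> GdSubsetResult:
    """Fraction of a group's GBA carriers heterozygous for a GD-causing allele."""
    carriers = [c for c in _select(classifications, group) if c.n_gba_variants >= 1]
    flagged = sum(1 for c in carriers if c.gd_het_carrier)
    prop = flagged / len(carriers) if carriers else None
    return GdSubsetResult(group=group, n_flagged=flagged, n_carriers=len(carriers),
                          proportion=prop)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries pass through as NaN and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        vals = p[mask]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def apply_fdr(results: Sequence[BurdenResult]) -> None:
    """Populate ``p_fdr`` across one family of results (in place)."""
    ps = [np.nan if r.p_raw is None else r.p_raw for r in results]
    adj = bh_fdr(ps)
    for r, q in zip(results, adj):
        r.p_fdr = None if np.isnan(q) else float(q)


# ---------------------------------------------------------------------------
# analysis requests (shared by the pipeline and sensitivity re-runs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisRequest:
    """One requested comparison.

    kind: "carrier" | "allele" | "subset".
    For carrier/allele: group_a vs group_b on ``category`` with covariates.
    For subset: carriage in ``gene_subset`` among cases with a primary
    mutation in ``case_gene`` (optionally ``case_variant``) vs ``group_b``.
    """

    kind: str
    label: str
    group_a: str = GROUP_KNOWN
    group_b: str = GROUP_CONTROL
    category: str = "mendelian"
    covariates: tuple[str, ...] = ()
    gene_subset: tuple[str, ...] = ()
    case_gene: str | None = None
    case_variant: str | None = None


def run_analyses(
    classifications: Sequence[SampleClassification],
    samples: Sequence[SampleRecord],
    requests: Sequence[AnalysisRequest],
    fdr: bool = True,
) -> list[BurdenResult]:
    results = []
    for req in requests:
        if req.kind == "carrier":
            r = carrier_burden(classifications, samples, req.group_a, req.group_b,
                               req.category, req.covariates, req.label)
        elif req.kind == "allele":
            r = allele_burden(classifications, samples, req.group_a, req.group_b,
                              req.category, req.covariates, req.label)
        elif req.kind == "subset":
            controls = _select(classifications, req.group_b)
            r = subset_enrichment(
                classifications,
                req.gene_subset,
                primary_gene_filter(req.case_gene, req.case_variant),
                controls,
                req.label,
            )
        else:
            raise ValueError(f"unknown analysis kind {req.kind!r}")
        results.append(r)
    if fdr:
        apply_fdr(results)
    return results


def sensitivity_rerun(
    cohort: CohortData,
    exclusion_keys: Sequence[str],
    analysis_spec: Sequence[AnalysisRequest],
    panel: GenePanel,
    pathogenic_gains: frozenset[str] | set[str] = frozenset(),
) -> list[BurdenResult]:
    """Re-run analyses with listed variants removed from additional-variant
    eligibility; primary-mutation classification is unchanged."""
    from .classify import classify_cohort

    index = cohort.variant_index()
    bad = [k for k in exclusion_keys if k not in index]
    if bad:
        raise ValueError(f"unknown exclusion key(s): {bad}")
    excluded = set(exclusion_keys)
    variants = [
        dataclasses.replace(v, additional_eligible=False) if v.key in excluded else v
        for v in cohort.variants
    ]
    modified = cohort.with_variants(variants)
    classifications = classify_cohort(modified, panel, pathogenic_gains)
    return run_analyses(classifications, modified.samples, analysis_spec)
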