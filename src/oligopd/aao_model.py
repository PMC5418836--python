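"""Age-at-onset (AAO) modifier regression.

Within a case group, AAO in years is regressed on carriage of additional
variants (binary: >= 1 additional variant of the chosen category) plus
covariates, by ordinary least squares.  With no covariates the carrier
coefficient equals the difference of group means exactly.  Samples with
missing AAO never enter the fit and are reported in ``n_missing_aao``.
An allele-count predictor is available behind ``predictor="alleles"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .burden_stats import _covariate_matrix, _select
from .classify import SampleClassification
from .cohort_io import SampleRecord


@dataclass
class AaoResult:
    group: str
    category: str
    mean_with: float | None = None
    mean_without: float | None = None
    coeff: float | None = None
    ci95: tuple[float, float] | None = None
    p_raw: float | None = None
    p_fdr: float | None = None
    n_with: int = 0
    n_without: int = 0
    n_missing_aao: int = 0
    covariates: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def aao_regression(
    classifications: Sequence[SampleClassification],
    samples: Sequence[SampleRecord],
    group: str,
    category: str = "mendelian",
    covariates: Sequence[str] = (),
    predictor: str = "carrier",
) -> AaoResult:
    """OLS of AAO on additional-variant carriage within one case group."""
    members = _select(classifications, group)
    by_id = {s.id: s for s in samples}
    aao = np.array([
        np.nan if by_id[c.sample_id].aao is None else by_id[c.sample_id].aao for c in members
    ])
    if predictor == "carrier":
        x_all = np.array([float(c.count(category) >= 1) for c in members])
    elif predictor == "alleles":
        x_all = np.array([float(c.alleles(category)) for c in members])
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    have = np.isfinite(aao)
    result = AaoResult(
        group=group,
        category=category,
        n_missing_aao=int((~have).sum()),
        covariates=tuple(covariates),
    )
    y = aao[have]
    x = x_all[have]
    carrier = np.array([c.count(category) >= 1 for c in members], dtype=bool)[have]
    result.n_with = int(carrier.sum())
    result.n_without = int((~carrier).sum())
    if result.n_with:
        result.mean_with = float(y[carrier].mean())
    if result.n_without:
        result.mean_without = float(y[~carrier].mean())
    if result.n_with == 0 or result.n_without == 0:
        result.flags = ("degenerate_contrast",)
        return result
    if result.n_with < 2 or result.n_without < 2:
        result.flags = ("underpowered",)
    ids = [c.sample_id for c, keep in zip(members, have) if keep]
    covar = _covariate_matrix(samples, ids, covariates)
    X = pd.DataFrame({"x": x})
    for col in covar.columns:
        X[col] = covar[col].to_numpy()
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        result.flags = result.flags + ("collinear",)
        return result
    fit = sm.OLS(y, X).fit()
    result.coeff = float(fit.params["x"])
    lo, hi = fit.conf_int().loc["x"]
    result.ci95 = (float(lo), float(hi))
    result.p_raw = float(fit.pvalues["x"])
    return result
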