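"""Multivariate regression: does a miRNA-drug association survive subtype adjustment?

Breast cancer cell lines fall into transcriptome-defined subtypes (basal,
luminal, normal-like) that differ in drug response, so an apparent miRNA-drug
association can be an echo of subtype.  Each significant pair is refit in
three ordinary least-squares models, one per binary contrast (basal vs rest,
luminal vs rest, normal-like vs rest):

    -log10 IC50 ~ intercept + miRNA + subtype indicator

A subtype is recorded as confounding the pair when, in its model, the subtype
coefficient is significant (p < alpha) while the miRNA coefficient is not
(p >= alpha) -- i.e. the subtype, not the miRNA, carries the association.  A
pair is *retained* (subtype-independent) iff no contrast confounds it.  This
explicit rule is one deterministic reading of "subtype associated stronger
than the drug"; alpha is configurable and the per-contrast coefficients are
reported so the call can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import AssociationResult
from .core_io import SUBTYPES, SubtypeLabels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OLSFit:
    """Classical least-squares fit: coefficients, SEs, t and p per predictor."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_var: float
    n: int


@dataclass(frozen=True)
class MultivariateResult:
    drug: str
    mirna: str
    fits: dict[str, OLSFit | None]  # per contrast; None = contrast not evaluable
    confounded_by: tuple[str, ...]
    retained: bool


def _first_dependent_column(X: pd.DataFrame) -> str:
    """Name the first column linearly dependent on the ones before it."""
    arr = X.to_numpy(dtype=float)
    for j in range(arr.shape[1]):
        if np.linalg.matrix_rank(arr[:, : j + 1]) <= np.linalg.matrix_rank(arr[:, :j]):
            return str(X.columns[j])
    return str(X.columns[-1])


def ols_fit(y: np.ndarray, X: pd.DataFrame) -> OLSFit:
    """OLS of y on a named design matrix (caller includes the intercept column).

    Errors on rank deficiency, naming the collinear column, and requires
    n >= p + 2 so the residual t-tests have at least one degree of freedom to
    spare.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise ValueError("y and design matrix must have matching length")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < p:
        col = _first_dependent_column(X)
        raise ValueError(f"design matrix is rank deficient: column {col!r} is collinear")
    fit = sm.OLS(y, X).fit()
    return OLSFit(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        resid_var=float(fit.scale),
        n=n,
    )


def confounding_check(
    assoc: AssociationResult,
    mirna_row: np.ndarray,
    drug_values: np.ndarray,
    subtypes: SubtypeLabels,
    sample_ids: list[str],
    alpha: float = 0.05,
) -> MultivariateResult:
    """Fit the three binary-contrast models for one significant association.

    ``drug_values`` are -log10 IC50 and ``mirna_row`` log10 expression, aligned
    to ``sample_ids``; missing responses are dropped pairwise.  A contrast
    whose indicator is constant among the used samples (no such subtype drawn)
    is recorded as not evaluable rather than aborting.
    """
    y = np.asarray(drug_values, dtype=float)
    x = np.asarray(mirna_row, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    used = [s for s, k in zip(sample_ids, keep) if k]
    fits: dict[str, OLSFit | None] = {}
    confounded: list[str] = []
    for subtype in SUBTYPES:
        ind = subtypes.indicator(subtype, used)
        if np.ptp(ind) == 0:
            logger.warning(
                "%s x %s: contrast %s vs rest not evaluable (indicator constant)",
                assoc.drug, assoc.mirna, subtype,
            )
            fits[subtype] = None
            continue
        X = pd.DataFrame({"intercept": np.ones_like(y), "mirna": x, "subtype": ind})
        fit = ols_fit(y, X)
        fits[subtype] = fit
        if fit.pvalues["subtype"] < alpha and fit.pvalues["mirna"] >= alpha:
            confounded.append(subtype)
    return MultivariateResult(
        drug=assoc.drug,
        mirna=assoc.mirna,
        fits=fits,
        confounded_by=tuple(confounded),
        retained=not confounded,
    )
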