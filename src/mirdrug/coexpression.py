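"""Spearman co-expression among miRNAs hitting the same drug.

When several miRNAs associate with one drug, their expression may itself be
correlated (shared regulation), which changes how the hits should be read.
This module computes the pairwise Spearman matrix over a chosen set of miRNAs
with unadjusted two-sided p-values and a significance mask at p < alpha
(raw p-values, matching how such supplementary matrices are reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import spearman_assoc
from .core_io import ExpressionMatrix


@dataclass(frozen=True)
class CoexpressionMatrix:
    mirna_ids: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask, p < alpha
    alpha: float


def coexpression(
    mirna: ExpressionMatrix, ids: list[str], alpha: float = 0.05
) -> CoexpressionMatrix:
    """Pairwise Spearman correlation matrix over ``ids`` (symmetric, unit diagonal)."""
    if mirna.n_samples < 4:
        raise ValueError("need >= 4 samples for co-expression analysis")
    rows = {i: mirna.row(i) for i in ids}  # KeyError names any unknown id
    k = len(ids)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            r, pv = spearman_assoc(rows[ids[a]], rows[ids[b]])
            rho[a, b] = rho[b, a] = r
            p[a, b] = p[b, a] = pv
    rho_df = pd.DataFrame(rho, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    return CoexpressionMatrix(
        mirna_ids=tuple(ids),
        rho=rho_df,
        p=p_df,
        significant=p_df < alpha,
        alpha=alpha,
    )
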