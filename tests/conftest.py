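"""Shared fixtures and independent oracles used across the suite.

The oracle functions here deliberately re-derive each statistic by the most
direct route available (full enumeration, the textbook formula, dense linear
algebra) and stay independent of the library code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import mirdrug as md


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_panel():
    """A reduced synthetic panel for plumbing tests (fast, planted effects intact)."""
    cfg = md.SyntheticConfig(
        n_samples=36,
        n_mirnas=60,
        n_drugs=12,
        planted_assocs=(
            md.PlantedAssoc("miR-0001", "drug-01", 0.75, 1),
            md.PlantedAssoc("miR-0002", "drug-02", 0.75, -1),
        ),
        confounded_assocs=(md.ConfoundedAssoc("miR-0003", "drug-03", "basal"),),
        censor_quantile=tuple([0.05] * 8 + [0.4] * 2 + [0.85] * 2),
        n_genes=120,
        planted_sets=(md.PlantedSet("SET_planted_1", "miR-0001", 1.0),),
        n_null_sets=4,
        seed=20260921,
    )
    return md.generate_panel(cfg)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def mannwhitney_enumeration_p(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every group labeling.

    Returns (U for group1, p).  Two-sided p doubles the smaller tail
    probability of U (capped at 1), the convention of exact wilcox.test.
    """
    pooled = np.concatenate([group1, group2])
    n1, n2 = len(group1), len(group2)
    n = n1 + n2

    def u_of(indices: tuple[int, ...]) -> float:
        g1 = pooled[list(indices)]
        g2 = np.delete(pooled, list(indices))
        # U = #{(i, j): g1_i > g2_j} + 0.5 #ties
        diff = g1[:, None] - g2[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    us = np.array([u_of(idx) for idx in combinations(range(n), n1)])
    u_obs = u_of(tuple(range(n1)))
    p_low = np.mean(us <= u_obs + 1e-12)
    p_high = np.mean(us >= u_obs - 1e-12)
    return u_obs, float(min(1.0, 2 * min(p_low, p_high)))


def storey_q_oracle(p: np.ndarray, pi0: float) -> np.ndarray:
    """O(m^2) double loop over the defining min formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            pi0 * m * t / np.sum(p <= t) for t in p if t >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """Coefficients, SEs and t p-values straight from (X'X)^-1 X'y."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    return beta, se, pvals, s2


def global_test_q_oracle(X: np.ndarray, y: np.ndarray) -> float:
    """Dense quadratic-form evaluation y_c' (X_c' X_c / m) y_c / s^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m, n = X.shape
    y_c = y - y.mean()
    s2 = (y_c @ y_c) / n
    X_c = X - X.mean(axis=1, keepdims=True)
    A = X_c.T @ X_c / m
    return float(y_c @ A @ y_c / s2)


def permutation_p_enumeration(X: np.ndarray, y: np.ndarray) -> float:
    """Exact tail probability of Q over every distinct arrangement of binary y."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    g = int((y == np.unique(y)[1]).sum())
    lo, hi = np.unique(y)
    q_obs = global_test_q_oracle(X, y)
    qs = []
    for idx in combinations(range(n), g):
        perm = np.full(n, lo)
        perm[list(idx)] = hi
        qs.append(global_test_q_oracle(X, perm))
    qs = np.array(qs)
    return float(np.mean(qs >= q_obs - 1e-12))
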