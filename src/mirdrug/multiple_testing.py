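"""Benjamini-Hochberg adjustment and Storey q-values, pooled per analysis branch.

Each analysis branch (Spearman, 2-step, Mann-Whitney) forms its own pool of
p-values over all of its drugs; q-values are computed within the pool and a
pair is significant at q <= 0.3.  The 2-step pool contains the step-2
(confirmation) p-values of screened pairs only; unscreened pairs carry no
q-value and are never significant.

The q-value machinery follows the standard smoother recipe: the proportion of
true nulls pi0 is estimated from the flat right tail of the p-value histogram,
pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid, smoothed
by a cubic spline and read off at the largest lambda; q_i is the minimum of
pi0 * m * t / #{p <= t} over observed thresholds t >= p_i.  With pi0 = 1 the
q-values coincide with BH-adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .association import AssociationResult
from .profile_classifier import Branch

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)
PI0_FLOOR = 1e-8
MIN_P_FOR_SPLINE = 20


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _check_p(p)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Smoother estimate of the proportion of true null hypotheses.

    Falls back to the conservative pi0 = 1 (with a logged warning) when fewer
    than 20 p-values are available, where the spline is unstable.  The result
    is clamped to [1e-8, 1].
    """
    p = _check_p(p)
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any(lam <= 0) or np.any(lam >= 1):
        raise ValueError("lambda grid must lie in (0, 1)")
    m = len(p)
    if m < MIN_P_FOR_SPLINE:
        logger.warning("estimate_pi0: only %d p-values; falling back to pi0 = 1", m)
        return 1.0
    pi0_hat = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    # default smoothing target makes the spline an essentially least-squares
    # cubic trend through (lambda, pi0_hat), read off at the largest lambda
    spline = UnivariateSpline(lam, pi0_hat, k=3)
    pi0 = float(spline(lam.max()))
    return float(np.clip(pi0, PI0_FLOOR, 1.0))


def storey_q(p: np.ndarray, pi0: float) -> np.ndarray:
    """q_i = min over observed t >= p_i of pi0 * m * t / #{p <= t} (sorted sweep)."""
    p = _check_p(p)
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    # #{p <= p_(i)} with ties counted fully
    counts = np.searchsorted(p_sorted, p_sorted, side="right")
    q_sorted = pi0 * m * p_sorted / counts
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class QValueResult:
    p_values: np.ndarray
    pi0: float
    q_values: np.ndarray
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())


def qvalues(p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> QValueResult:
    """Convenience wrapper: estimate pi0, then compute q-values."""
    p = _check_p(p)
    pi0 = estimate_pi0(p, lambda_grid)
    return QValueResult(p_values=p, pi0=pi0, q_values=storey_q(p, pi0),
                        lambda_grid=np.asarray(lambda_grid, dtype=float))


def attach_q_by_branch(
    results: list[AssociationResult], q_threshold: float = 0.3
) -> list[AssociationResult]:
    """Fill in q-values per branch pool and flag significance at q <= threshold.

    Pools: all Spearman-branch p-values together; all Mann-Whitney-branch
    p-values together; the step-2 p-values of *screened* 2-step pairs together.
    Unscreened 2-step pairs keep q = None / significant = False.  Each pool is
    independent: results of one branch never affect another's q-values.
    """
    pools: dict[Branch, list[AssociationResult]] = {b: [] for b in Branch}
    for r in results:
        if r.branch.branch is Branch.TWO_STEP and not r.screened:
            r.q_value = None
            r.significant = False
            continue
        pools[r.branch.branch].append(r)
    for branch, members in pools.items():
        if not members:
            continue
        qr = qvalues(np.array([r.p_value for r in members]))
        logger.info("branch %s: m=%d, pi0=%.3f", branch.name, len(members), qr.pi0)
        for r, q in zip(members, qr.q_values):
            r.q_value = float(q)
            r.significant = bool(q <= q_threshold)
    return results
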