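"""Quartile grouping and a global-test gene-set screen with a dual significance rule.

For each miRNA of interest, cell lines are split into the top and bottom 25%
of that miRNA's expression (floor(0.25 n) per group; ties broken by sample id)
and each gene set is tested for a joint expression difference between the two
groups with a global-test-style statistic

    Q = (1/m) * sum_j (x_j . y_c)^2 / s^2,

where x_j is gene j centered across the included samples, y_c the centered
binary group label and s^2 = (y_c . y_c)/n its null variance.  Q is the
quadratic form y_c' (X_c' X_c / m) y_c / s^2: large when set genes co-vary
with the grouping, zero when every gene is constant.

Two tail probabilities accompany Q:

* ``permutation_p`` -- Monte-Carlo with the add-one estimator over uniformly
  permuted labels (the selection criterion applied at 1000 permutations);
* ``approx_p`` -- the analytic stand-in to which BH adjustment is applied:
  the exact permutation tail by full enumeration when the number of distinct
  label arrangements C(n, g) is small enough, otherwise a scaled chi-square
  matched to the closed-form permutation mean and variance of Q (derived from
  the inclusion probabilities of sampling the ``g`` group-1 positions without
  replacement; the doubly-centered structure of the quadratic form makes the
  trace identities short).

A set is significant iff its BH-adjusted approx p (pooled across all sets for
that miRNA) is below 0.1 *and* its permutation p is below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix, GeneSetCollection
from .multiple_testing import bh_adjust

logger = logging.getLogger(__name__)

#: enumerate the exact permutation null when C(n, g) is at most this
MAX_ENUMERATION = 100_000


@dataclass(frozen=True)
class QuartileGroups:
    mirna_id: str
    top_ids: tuple[str, ...]  # highest expression
    bottom_ids: tuple[str, ...]  # lowest expression
    group_size: int


@dataclass
class PathwayResult:
    mirna_id: str
    set_name: str
    Q: float
    p_approx: float
    p_perm: float
    p_bh: float
    significant: bool
    n_genes_used: int


def quartile_groups(
    mirna_row: np.ndarray,
    sample_ids: Sequence[str],
    fraction: float = 0.25,
    mirna_id: str = "",
) -> QuartileGroups:
    """Top and bottom ``fraction`` of samples by one miRNA's expression."""
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    x = np.asarray(mirna_row, dtype=float)
    n = len(x)
    if n != len(sample_ids):
        raise ValueError("expression vector and sample ids differ in length")
    if n < 8:
        raise ValueError(f"need >= 8 samples, got {n}")
    g = int(np.floor(fraction * n))
    if g < 1:
        raise ValueError("group size would be 0")
    order = sorted(range(n), key=lambda i: (x[i], sample_ids[i]))
    bottom = tuple(sample_ids[i] for i in order[:g])
    top = tuple(sample_ids[i] for i in order[-g:])
    return QuartileGroups(mirna_id=mirna_id, top_ids=top, bottom_ids=bottom, group_size=g)


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(y):
        raise ValueError("gene matrix and labels differ in sample count")
    if X.shape[0] < 1:
        raise ValueError("no genes in the set are present in the matrix")
    y_c = y - y.mean()
    s2 = float(y_c @ y_c) / len(y)
    if s2 == 0:
        raise ValueError("group labels are constant (one group is empty)")
    X_c = X - X.mean(axis=1, keepdims=True)
    return X_c, y_c, s2


def global_test_q(X: np.ndarray, y: np.ndarray) -> float:
    """The set statistic Q for gene-by-sample matrix ``X`` and binary labels ``y``."""
    X_c, y_c, s2 = _center(X, y)
    m = X_c.shape[0]
    return float(np.sum((X_c @ y_c) ** 2) / (m * s2))


def _q_for_label_matrix(X_c: np.ndarray, Y_c: np.ndarray, s2: float) -> np.ndarray:
    """Q for every column of centered label matrix ``Y_c`` at once."""
    m = X_c.shape[0]
    return np.sum((X_c @ Y_c) ** 2, axis=0) / (m * s2)


def permutation_p(
    X: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo tail probability (1 + #{Q_perm >= Q_obs}) / (1 + n_perm)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X_c, y_c, s2 = _center(X, y)
    q_obs = float(np.sum((X_c @ y_c) ** 2) / (X_c.shape[0] * s2))
    perms = np.stack([rng.permutation(y_c) for _ in range(n_perm)], axis=1)
    q_perm = _q_for_label_matrix(X_c, perms, s2)
    # tolerance so re-drawing the observed arrangement counts despite float noise
    hits = int(np.sum(q_perm >= q_obs * (1 - 1e-12) - 1e-300))
    return (1 + hits) / (1 + n_perm)


_COMB_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _indicator_combinations(n: int, g: int) -> np.ndarray:
    """All C(n, g) indicator vectors as an (n, C) 0/1 matrix (cached)."""
    key = (n, g)
    if key not in _COMB_CACHE:
        z = np.zeros((n, comb(n, g)))
        for j, idx in enumerate(combinations(range(n), g)):
            z[list(idx), j] = 1.0
        _COMB_CACHE[key] = z
    return _COMB_CACHE[key]


def _binary_groups(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError("approx_p needs binary group labels")
    return y == levels[1]


def _permutation_moments(A: np.ndarray, n: int, g: int) -> tuple[float, float]:
    """Exact permutation mean and variance of z'Az for a random g-subset indicator z.

    ``A`` must be symmetric and doubly centered (A 1 = 0), which holds for
    A = X_c' X_c with row-centered genes.  Derived from the inclusion
    probabilities p_k = g(g-1)...(g-k+1) / (n(n-1)...(n-k+1)).
    """
    d = np.diag(A)
    D1 = float(d.sum())  # tr A
    D2 = float((d**2).sum())
    F = float((A**2).sum()) - D2  # sum of squared off-diagonals
    p1 = g / n
    p2 = p1 * (g - 1) / (n - 1)
    p3 = p2 * (g - 2) / (n - 2) if n > 2 else 0.0
    p4 = p3 * (g - 3) / (n - 3) if n > 3 else 0.0
    mean = (p1 - p2) * D1
    second = (
        p1 * D2
        + p2 * (D1**2 - D2)
        + 2 * (-2 * p2 * D2 + p3 * (2 * D2 - D1**2))
        + 2 * F * p2
        + 4 * p3 * (D2 - F)
        + p4 * (D1**2 + 2 * F - 4 * D2)
    )
    return mean, second - mean**2


def approx_p(X: np.ndarray, y: np.ndarray, max_enum: int = MAX_ENUMERATION) -> float:
    """Right-tail probability of Q under label exchangeability (binary labels).

    Exact by enumeration of all C(n, g) arrangements when feasible; otherwise a
    scaled chi-square matched to the exact permutation mean and variance.
    """
    z = _binary_groups(y)
    X_c, y_c, s2 = _center(X, np.asarray(y, dtype=float))
    m, n = X_c.shape
    g = int(z.sum())
    q_obs = float(np.sum((X_c @ y_c) ** 2) / (m * s2))
    # Q depends on the labels only through the group-1 indicator: with binary
    # y = v0 + (v1 - v0) z and A 1 = 0, y_c' A y_c = (v1 - v0)^2 z' A z.
    if comb(n, g) <= max_enum:
        Z = _indicator_combinations(n, g)
        Z_c = Z - g / n
        spread = float(np.ptp(np.asarray(y, dtype=float)))
        q_all = _q_for_label_matrix(X_c, Z_c * spread, s2)
        return float(np.mean(q_all >= q_obs * (1 - 1e-12) - 1e-300))
    spread2 = float(np.ptp(np.asarray(y, dtype=float))) ** 2
    A = X_c.T @ X_c
    mean_z, var_z = _permutation_moments(A, n, g)
    scale0 = spread2 / (m * s2)
    mu = scale0 * mean_z
    var = scale0**2 * var_z
    if var <= 0 or mu <= 0:
        return 1.0
    k = 2 * mu**2 / var
    c = var / (2 * mu)
    return float(stats.chi2.sf(q_obs / c, df=k))


def pathway_screen(
    mrna: ExpressionMatrix,
    sets: GeneSetCollection,
    mirna: ExpressionMatrix,
    mirna_ids: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    fraction: float = 0.25,
    bh_threshold: float = 0.1,
    perm_threshold: float = 0.05,
    standardize: bool = False,
) -> list[PathwayResult]:
    """Run the global-test screen for each miRNA against every gene set.

    BH adjustment of the analytic p-values is pooled across all sets tested
    for one miRNA (all sources together); a set is significant iff its
    BH-adjusted p is below ``bh_threshold`` and its permutation p below
    ``perm_threshold``.  ``standardize`` optionally scales each gene to unit
    variance before testing (the statistic is covariance-based by default).
    """
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < 8:
        raise ValueError("need >= 8 samples shared between miRNA and mRNA matrices")
    gene_index = {gid: i for i, gid in enumerate(mrna.feature_ids)}
    results: list[PathwayResult] = []
    for mi, mirna_id in enumerate(mirna_ids):
        row = mirna.subset_samples(shared).row(mirna_id)
        groups = quartile_groups(row, shared, fraction=fraction, mirna_id=mirna_id)
        included = list(groups.bottom_ids) + list(groups.top_ids)
        y = np.array([0.0] * groups.group_size + [1.0] * groups.group_size)
        sub = mrna.subset_samples(included)
        per_mirna: list[PathwayResult] = []
        for si, (set_name, genes) in enumerate(sets):
            rows = [gene_index[gid] for gid in genes if gid in gene_index]
            n_dropped = len(genes) - len(rows)
            if n_dropped:
                logger.debug("%s/%s: %d set genes absent from matrix",
                             mirna_id, set_name, n_dropped)
            if not rows:
                logger.warning("%s/%s: no set genes present; set skipped",
                               mirna_id, set_name)
                continue
            X = sub.values[rows]
            if standardize:
                sd = X.std(axis=1, ddof=0, keepdims=True)
                X = np.where(sd > 0, (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1), 0.0)
            q = global_test_q(X, y)
            child = np.random.SeedSequence(entropy=seed, spawn_key=(mi, si))
            rng = np.random.default_rng(child)
            p_perm = permutation_p(X, y, n_perm=n_perm, seed=rng)
            p_app = approx_p(X, y)
            per_mirna.append(PathwayResult(
                mirna_id=mirna_id, set_name=set_name, Q=q,
                p_approx=p_app, p_perm=p_perm, p_bh=np.nan,
                significant=False, n_genes_used=len(rows),
            ))
        if per_mirna:
            adj = bh_adjust(np.array([r.p_approx for r in per_mirna]))
            for r, pb in zip(per_mirna, adj):
                r.p_bh = float(pb)
                r.significant = bool(pb < bh_threshold and r.p_perm < perm_threshold)
        results.extend(per_mirna)
    return results
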