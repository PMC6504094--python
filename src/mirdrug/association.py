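"""The three branch analyses linking one miRNA to one drug, with direction calls.

All statistics run on log10 miRNA expression against -log10 IC50, so a
positive correlation means higher miRNA expression goes with a *lower* IC50,
i.e. drug sensitivity; a negative correlation means resistance.

* Spearman branch: rank correlation over all non-missing samples, two-sided p
  from the t-approximation on n-2 degrees of freedom (the ``psych::corr.test``
  convention).
* Mann-Whitney branch: miRNA expression compared between censored ("resistant",
  IC50 at the maximum tested concentration) and variable ("sensitive") lines;
  exact p for small tie-free samples, otherwise the tie- and
  continuity-corrected normal approximation (the ``wilcox.test`` convention).
* 2-step branch: Spearman on the variable samples screens candidate pairs
  (unadjusted p below ``screen_alpha``); screened pairs are confirmed by the
  Mann-Whitney comparison above, whose p-value is the pair's final p.

``associate_all`` applies the per-drug branch to every miRNA x drug pair; the
Spearman computations are vectorised over miRNAs (each drug shares one missing
mask, so one rank transform serves all 411 features).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import DrugResponseProfile, ExpressionMatrix, Scale, neglog10_ic50
from .profile_classifier import AnalysisBranch, Branch, classify_profile

logger = logging.getLogger(__name__)


class Direction(enum.Enum):
    SENSITIVITY = "Sensitivity"  # higher miRNA -> lower IC50
    RESISTANCE = "Resistance"  # higher miRNA -> higher IC50


@dataclass
class AssociationResult:
    drug: str
    mirna: str
    branch: AnalysisBranch
    statistic: float  # rho for Spearman-type branches, U for Mann-Whitney
    statistic_name: str  # "rho" or "U"
    p_value: float
    direction: Direction
    n_used: int
    q_value: float | None = None
    significant: bool | None = None
    screened: bool | None = None  # 2-step audit flag; None off that branch


@dataclass(frozen=True)
class TwoStepResult:
    step1: tuple[float, float] | None  # (rho, p) on variable samples
    screened: bool
    step2: tuple[float, float] | None  # (U, p) resistant vs sensitive
    note: str = ""

    @property
    def final_p(self) -> float | None:
        return self.step2[1] if self.screened and self.step2 else None


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def _drop_pairwise_missing(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (t-approximation, n-2 df).

    Missing values are removed pairwise; needs >= 4 complete pairs and
    non-constant vectors.  |rho| = 1 yields p = 0.
    """
    x, y = _drop_pairwise_missing(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, _spearman_p(np.array([rho]), n)[0]


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho sqrt((n-2)/(1-rho^2))."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-12] = 0.0  # perfect monotone up to float noise
    return p


def mann_whitney_assoc(
    values: np.ndarray, is_resistant: np.ndarray
) -> tuple[float, float, Direction]:
    """Mann-Whitney U (for the resistant group) with two-sided p and direction.

    Exact p by enumeration when n1+n2 <= 20 and the values are tie-free,
    otherwise the normal approximation with tie and continuity correction.
    Direction is RESISTANCE iff the resistant group's median rank exceeds the
    sensitive group's (higher miRNA among censored lines).
    """
    values = np.asarray(values, dtype=float)
    is_resistant = np.asarray(is_resistant, dtype=bool)
    if values.shape != is_resistant.shape:
        raise ValueError("values and is_resistant must have equal length")
    keep = ~np.isnan(values)
    values, is_resistant = values[keep], is_resistant[keep]
    res = values[is_resistant]
    sen = values[~is_resistant]
    if len(res) == 0 or len(sen) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(values)
    tie_free = len(np.unique(values)) == n
    method = "exact" if (n <= 20 and tie_free) else "asymptotic"
    out = stats.mannwhitneyu(
        res, sen, alternative="two-sided", method=method, use_continuity=True
    )
    ranks = stats.rankdata(values)
    direction = (
        Direction.RESISTANCE
        if np.median(ranks[is_resistant]) > np.median(ranks[~is_resistant])
        else Direction.SENSITIVITY
    )
    return float(out.statistic), float(out.pvalue), direction


def two_step_assoc(
    p: DrugResponseProfile, mirna_row: np.ndarray, screen_alpha: float = 0.05
) -> TwoStepResult:
    """Screen on variable samples (Spearman), confirm censored-vs-variable (Mann-Whitney).

    Step 1 correlates the miRNA with -log10 IC50 over the samples *not* at the
    maximum tested concentration; pairs with unadjusted step-1 p below
    ``screen_alpha`` proceed to step 2, where at-max lines are labelled
    resistant and the rest sensitive.  A degenerate step 1 (constant values,
    too few samples) marks the pair as not screenable rather than erroring.
    """
    from .profile_classifier import classify_profile as _classify

    if _classify(p).branch is not Branch.TWO_STEP:
        raise ValueError(f"{p.drug_name}: profile is not on the 2-step branch")
    mirna_row = np.asarray(mirna_row, dtype=float)
    y = neglog10_ic50(p)
    variable = ~p.missing & ~p.at_max
    try:
        rho1, p1 = spearman_assoc(mirna_row[variable], y[variable])
    except ValueError as exc:
        return TwoStepResult(step1=None, screened=False, step2=None,
                             note=f"not screenable: {exc}")
    if p1 >= screen_alpha:
        return TwoStepResult(step1=(rho1, p1), screened=False, step2=None)
    keep = ~p.missing
    u, p2, _ = mann_whitney_assoc(mirna_row[keep], p.at_max[keep])
    return TwoStepResult(step1=(rho1, p1), screened=True, step2=(u, p2))


# ---------------------------------------------------------------------------
# panel-wide association
# ---------------------------------------------------------------------------


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _vectorised_spearman(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and p of every row of ``values`` against ``y`` (no missing allowed here).

    Pearson correlation of mid-ranks; matches ``spearman_assoc`` per pair.
    Rows or targets with zero rank variance yield NaN (the caller logs them).
    """
    n = values.shape[1]
    rx = _rank_rows(values)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx_c @ ry_c) / denom, np.nan)
    p = np.full_like(rho, np.nan)
    ok = ~np.isnan(rho)
    p[ok] = _spearman_p(rho[ok], n)
    return rho, p


def _direction_from_rho(rho: float) -> Direction:
    return Direction.SENSITIVITY if rho >= 0 else Direction.RESISTANCE


def associate_all(
    mirna: ExpressionMatrix,
    drugs: Sequence[DrugResponseProfile],
    screen_alpha: float = 0.05,
) -> list[AssociationResult]:
    """Run the branch chosen per drug for every (miRNA, drug) pair.

    Requires the miRNA matrix on the log10 scale; IC50s are transformed to
    -log10 internally.  Missing IC50s are excluded pairwise (one mask per drug).
    Degenerate pairs (constant vectors, too few samples) are logged and
    skipped, never silently dropped into the output.
    """
    if mirna.scale is not Scale.LOG10:
        raise ValueError("miRNA matrix must be log10-transformed (see log10_transform)")
    results: list[AssociationResult] = []
    n_skipped = 0
    any_overlap = False
    for profile in drugs:
        common = [s for s in mirna.sample_ids if s in set(profile.sample_ids)]
        if len(common) == 0:
            continue
        any_overlap = True
        sub = profile.subset_samples(common)
        keep = ~sub.missing
        if keep.sum() == 0:
            logger.warning("%s: all IC50 values missing; drug skipped", sub.drug_name)
            continue
        x_all = mirna.subset_samples(common).values[:, keep]
        aligned = DrugResponseProfile(
            drug_name=sub.drug_name,
            sample_ids=tuple(np.array(common)[keep]),
            ic50=sub.ic50[keep],
            max_conc=sub.max_conc,
        )
        branch = classify_profile(aligned)
        y = neglog10_ic50(aligned)
        n = len(y)

        if branch.branch is Branch.SPEARMAN:
            if np.ptp(y) == 0:
                logger.warning("%s: constant IC50 vector; drug skipped", aligned.drug_name)
                continue
            rho, p = _vectorised_spearman(x_all, y)
            for i, mid in enumerate(mirna.feature_ids):
                if np.isnan(rho[i]):
                    n_skipped += 1
                    logger.debug("%s x %s: constant miRNA row", aligned.drug_name, mid)
                    continue
                results.append(AssociationResult(
                    drug=aligned.drug_name, mirna=mid, branch=branch,
                    statistic=float(rho[i]), statistic_name="rho",
                    p_value=float(p[i]),
                    direction=_direction_from_rho(rho[i]), n_used=n,
                ))

        elif branch.branch is Branch.TWO_STEP:
            variable = ~aligned.at_max
            if np.ptp(y[variable]) == 0:
                logger.warning("%s: constant variable IC50s; drug skipped", aligned.drug_name)
                continue
            rho1, p1 = _vectorised_spearman(x_all[:, variable], y[variable])
            for i, mid in enumerate(mirna.feature_ids):
                if np.isnan(rho1[i]):
                    n_skipped += 1
                    continue
                screened = bool(p1[i] < screen_alpha)
                if not screened:
                    results.append(AssociationResult(
                        drug=aligned.drug_name, mirna=mid, branch=branch,
                        statistic=float(rho1[i]), statistic_name="rho",
                        p_value=float(p1[i]),
                        direction=_direction_from_rho(rho1[i]),
                        n_used=n, screened=False,
                    ))
                    continue
                u, p2, _ = mann_whitney_assoc(x_all[i], aligned.at_max)
                results.append(AssociationResult(
                    drug=aligned.drug_name, mirna=mid, branch=branch,
                    statistic=float(rho1[i]), statistic_name="rho",
                    p_value=float(p2),
                    direction=_direction_from_rho(rho1[i]),
                    n_used=n, screened=True,
                ))

        else:  # MANN_WHITNEY
            if aligned.n_at_max == 0 or aligned.n_variable == 0:
                logger.warning(
                    "%s: Mann-Whitney branch needs both censored and variable lines; "
                    "drug skipped", aligned.drug_name,
                )
                continue
            for i, mid in enumerate(mirna.feature_ids):
                try:
                    u, p, direction = mann_whitney_assoc(x_all[i], aligned.at_max)
                except ValueError:
                    n_skipped += 1
                    continue
                results.append(AssociationResult(
                    drug=aligned.drug_name, mirna=mid, branch=branch,
                    statistic=u, statistic_name="U", p_value=p,
                    direction=direction, n_used=n,
                ))

    if not any_overlap:
        raise ValueError("no drug profile shares samples with the miRNA matrix")
    if n_skipped:
        logger.info("associate_all: skipped %d degenerate pairs", n_skipped)
    return results
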