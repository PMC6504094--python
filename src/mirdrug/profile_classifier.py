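"""Per-drug choice among the three association analyses.

IC50 profiles across a cell-line panel range from fully "linear" (every line
has its own value) to almost fully censored (nearly all lines at the maximum
tested concentration).  The analysis applied to a drug depends only on two
counts over its non-missing samples: how many IC50s sit at the maximum
(``n_at_max``) and how many do not (``n_variable``):

* fewer than 10 variable values        -> Mann-Whitney test (censored vs not),
* otherwise at most 5 values at max    -> Spearman correlation,
* otherwise (>5 at max, >=10 variable) -> 2-step analysis.

Checking the censoring-dominated condition first makes the rules exhaustive
and mutually exclusive even for degenerate inputs (missing data, small n),
where the three published conditions could otherwise overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core_io import DrugResponseProfile


class Branch(enum.Enum):
    SPEARMAN = "Spearman correlation"
    TWO_STEP = "2-step analysis"
    MANN_WHITNEY = "Mann-Whitney test"


@dataclass(frozen=True)
class AnalysisBranch:
    branch: Branch
    n_at_max: int
    n_variable: int

    def __post_init__(self) -> None:
        if self.n_at_max < 0 or self.n_variable < 0:
            raise ValueError("counts must be nonnegative")


def classify_counts(n_at_max: int, n_variable: int) -> AnalysisBranch:
    """Branch from the two counts alone (magnitudes never matter)."""
    if n_at_max + n_variable < 1:
        raise ValueError("no non-missing IC50 values to classify")
    if n_variable < 10:
        branch = Branch.MANN_WHITNEY
    elif n_at_max <= 5:
        branch = Branch.SPEARMAN
    else:
        branch = Branch.TWO_STEP
    return AnalysisBranch(branch=branch, n_at_max=n_at_max, n_variable=n_variable)


def classify_profile(p: DrugResponseProfile) -> AnalysisBranch:
    """Decide which association analysis applies to one drug's IC50 profile."""
    return classify_counts(p.n_at_max, p.n_variable)
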