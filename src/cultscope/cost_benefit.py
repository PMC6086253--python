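"""Aggregate expert Likert ratings into per-practice economics.

Experts rate each practice on three 7-point Likert items: individual
economic cost, individual economic benefit and public environmental
benefit (1 = very inexpensive / no benefit, 7 = very expensive /
substantial benefit).  A practice's *net private cost* is a rater's cost
minus their private benefit — differenced within rater, before
averaging, because the two items of a single respondent share a frame of
reference that two different rater sets do not.  Public benefit is used
directly on its 1-7 scale; Likert means are ordinal summaries and are
never combined into benefit/cost ratios.

The sign of the mean net private cost classifies the selection regime: a
positive value marks a cooperative dilemma (individually costly, so
spreading requires group-level selection); a negative value marks a
practice that individual-level selection alone can spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class InsufficientRatersError(ValueError):
    """Raised when a practice has fewer usable raters than required."""


class SelectionRegime(Enum):
    GROUP_SELECTION_REQUIRED = "group_selection_required"
    INDIVIDUAL_SELECTION_POSSIBLE = "individual_selection_possible"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class PracticeEconomics:
    """Per-practice mean net private cost and mean public benefit.

    ``mean_net_private_cost`` lies in [-6, 6]; negative values mean the
    practice is net individually beneficial.  ``mean_public_benefit``
    lies on the raw 1-7 Likert scale.
    """

    practice_id: str
    mean_net_private_cost: float
    mean_public_benefit: float
    n_cost_raters: int
    n_public_raters: int

    def __post_init__(self) -> None:
        if not -6.0 <= self.mean_net_private_cost <= 6.0:
            raise ValueError(
                f"mean_net_private_cost {self.mean_net_private_cost} outside [-6, 6]"
            )
        if not 1.0 <= self.mean_public_benefit <= 7.0:
            raise ValueError(
                f"mean_public_benefit {self.mean_public_benefit} outside [1, 7]"
            )


def _check_likert(value: float, name: str) -> None:
    if not (1 <= value <= 7) or value != int(value):
        raise ValueError(f"{name}={value!r} is not an integer Likert value in [1, 7]")


def net_private_cost(cost: float | None, private_benefit: float | None) -> float | None:
    """One rater's net private cost: ``cost - private_benefit``, in [-6, 6].

    Returns ``None`` when either item is missing (the rater is then
    excluded from the practice mean).
    """
    if cost is None or private_benefit is None:
        return None
    if isinstance(cost, float) and np.isnan(cost):
        return None
    if isinstance(private_benefit, float) and np.isnan(private_benefit):
        return None
    _check_likert(cost, "cost")
    _check_likert(private_benefit, "private_benefit")
    return float(cost) - float(private_benefit)


def practice_economics(
    ratings: pd.DataFrame, practice_id: str, min_raters: int = 3
) -> PracticeEconomics:
    """Aggregate ratings for one practice.

    Requires at least ``min_raters`` raters with complete cost and
    private-benefit items, and at least ``min_raters`` with the public
    item; otherwise raises :class:`InsufficientRatersError` naming the
    short component.
    """
    if min_raters < 1:
        raise ValueError("min_raters must be >= 1")
    sub = ratings.loc[ratings["practice_id"] == practice_id]
    if sub.empty:
        raise InsufficientRatersError(
            f"practice {practice_id!r}: no ratings at all"
        )
    net = (sub["cost"] - sub["private_benefit"]).dropna()
    public = sub["public_benefit"].dropna()
    short = []
    if len(net) < min_raters:
        short.append(f"cost/benefit ({len(net)} complete raters)")
    if len(public) < min_raters:
        short.append(f"public benefit ({len(public)} raters)")
    if short:
        raise InsufficientRatersError(
            f"practice {practice_id!r}: fewer than {min_raters} raters for "
            + " and ".join(short)
        )
    return PracticeEconomics(
        practice_id=practice_id,
        mean_net_private_cost=float(net.mean()),
        mean_public_benefit=float(public.mean()),
        n_cost_raters=int(len(net)),
        n_public_raters=int(len(public)),
    )


def economics_table(
    ratings: pd.DataFrame, min_raters: int = 3
) -> tuple[list[PracticeEconomics], list[tuple[str, str]]]:
    """Aggregate every practice present in the ratings frame.

    Returns ``(economics, warnings)``; practices with too few raters land
    in the warning list instead of the results.
    """
    results: list[PracticeEconomics] = []
    warnings: list[tuple[str, str]] = []
    for practice in pd.unique(ratings["practice_id"]):
        try:
            results.append(practice_economics(ratings, practice, min_raters))
        except InsufficientRatersError as exc:
            warnings.append((practice, str(exc)))
    return results, warnings


def classify_selection_regime(econ: PracticeEconomics) -> SelectionRegime:
    """Sign rule on the mean net private cost.

    Positive net cost means only group-level selection can spread the
    practice; negative means individual-level selection suffices; an
    exact zero is reported as BOUNDARY rather than forced to a side.
    """
    if econ.mean_net_private_cost > 0:
        return SelectionRegime.GROUP_SELECTION_REQUIRED
    if econ.mean_net_private_cost < 0:
        return SelectionRegime.INDIVIDUAL_SELECTION_POSSIBLE
    return SelectionRegime.BOUNDARY
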