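"""Cognitive-conflict detection on repertory grids.

Implements the rule battery used in construct-system case formulation:

* **Construct classification.** A construct is *dilemmatic* when the
  ideal self sits exactly at the scale midpoint (neither pole offers a
  clear course of action); otherwise it is *congruent* when self-now
  and ideal-self ratings are similar (no change wished), *discrepant*
  when they fall at opposite poles (a desired change), and *neutral*
  in between. "Similar" and "opposite" are operationalized as integer
  gap bands (defaults: gap <= 1 congruent, gap >= 4 discrepant) and are
  exposed as parameters.
* **Implicative dilemmas.** A congruent--discrepant pair forms an
  implicative dilemma whenever the oriented Pearson correlation of the
  two rating rows strictly exceeds the threshold (default r > 0.35):
  the desired change on the discrepant construct would drag the valued
  pole of the congruent construct along with it.
* **Prototypical figures.** For a dilemma, the significant others whose
  ratings exemplify each side ("generous but depressed" people vs
  "happy but selfish" people); for a dilemmatic construct, the others
  rated at the most extreme scores the rater actually used on each
  side.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    Grid,
    GridError,
    Pole,
    pole_of_rating,
)

__all__ = [
    "Category",
    "DetectionParameters",
    "ConstructClassification",
    "ImplicativeDilemma",
    "PrototypicalFigures",
    "UndefinedCorrelationError",
    "classify_construct",
    "classify_all",
    "oriented_correlation",
    "detect_implicative_dilemmas",
    "detect_dilemmatic_constructs",
    "find_prototypical_figures",
    "find_dilemmatic_prototypes",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(GridError):
    """A rating row has zero variance over the chosen element set, so
    the Pearson correlation is undefined."""


Category = str  # one of "congruent" | "discrepant" | "dilemmatic" | "neutral"

CONGRUENT = "congruent"
DISCREPANT = "discrepant"
DILEMMATIC = "dilemmatic"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class DetectionParameters:
    """Tunable rule parameters.

    correlation_threshold
        Flag a pair only when the oriented correlation is strictly
        greater than this (default 0.35).
    congruent_gap_max / discrepant_gap_min
        Integer self--ideal gap bands for the verbal "similarly" /
        "opposite poles" definitions.
    include_self_ideal_in_correlation
        Whether the self and ideal columns enter the correlation
        (default True: the full score matrix is analysed).
    pole_membership_margin
        How far beyond the midpoint a rating must lie to count as
        "on" a pole when selecting prototypical figures.
    """

    correlation_threshold: float = 0.35
    congruent_gap_max: int = 1
    discrepant_gap_min: int = 4
    include_self_ideal_in_correlation: bool = True
    pole_membership_margin: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold < 1.0:
            raise GridError("correlation_threshold must be in (0, 1)")
        if self.congruent_gap_max >= self.discrepant_gap_min:
            raise GridError("congruent_gap_max must be < discrepant_gap_min")
        if self.pole_membership_margin < 1:
            raise GridError("pole_membership_margin must be >= 1")


@dataclass(frozen=True)
class ConstructClassification:
    construct_index: int
    category: Category
    self_rating: int
    ideal_rating: int

    @property
    def gap(self) -> int:
        return abs(self.self_rating - self.ideal_rating)


@dataclass(frozen=True)
class ImplicativeDilemma:
    """A flagged congruent--discrepant pair.

    Pole labels are arranged as the dilemma is presented clinically:
    the current position (self pole of the congruent construct together
    with the present/symptom pole of the discrepant one) versus the
    implication of change (undesired pole of the congruent construct
    with the desired pole of the discrepant one).
    """

    congruent_index: int
    discrepant_index: int
    oriented_r: float
    self_pole_congruent: str
    undesired_pole_congruent: str
    present_pole_discrepant: str
    desired_pole_discrepant: str

    @property
    def pair(self) -> tuple[int, int]:
        return (self.congruent_index, self.discrepant_index)


@dataclass(frozen=True)
class PrototypicalFigures:
    """Element indices exemplifying each side of one dilemma."""

    congruent_index: int
    discrepant_index: int
    current_side: tuple[int, ...]
    change_side: tuple[int, ...]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_construct(
    grid: Grid,
    construct_index: int,
    params: DetectionParameters | None = None,
) -> ConstructClassification:
    """Classify one construct from its self-now and ideal-self ratings.

    The dilemmatic rule is checked first (ideal at the midpoint);
    otherwise the absolute self--ideal gap decides: congruent when
    gap <= congruent_gap_max, discrepant when gap >= discrepant_gap_min,
    neutral in between.
    """
    params = params or DetectionParameters()
    if not 0 <= construct_index < grid.n_constructs:
        raise GridError(f"construct index {construct_index} out of range")
    s = grid.rating(construct_index, grid.self_index)
    i = grid.rating(construct_index, grid.ideal_index)
    if i == grid.scale.midpoint:
        cat = DILEMMATIC
    else:
        gap = abs(s - i)
        if gap <= params.congruent_gap_max:
            cat = CONGRUENT
        elif gap >= params.discrepant_gap_min:
            cat = DISCREPANT
        else:
            cat = NEUTRAL
    return ConstructClassification(construct_index, cat, s, i)


def classify_all(
    grid: Grid, params: DetectionParameters | None = None
) -> list[ConstructClassification]:
    params = params or DetectionParameters()
    return [
        classify_construct(grid, k, params) for k in range(grid.n_constructs)
    ]


# ---------------------------------------------------------------------------
# oriented correlation
# ---------------------------------------------------------------------------


def _element_set(grid: Grid, params: DetectionParameters) -> list[int]:
    if params.include_self_ideal_in_correlation:
        return list(range(grid.n_elements))
    return list(grid.other_indices)


def _oriented_row(
    grid: Grid, construct_index: int, reference_element: int
) -> np.ndarray:
    """Return the rating row, reflected if needed so the reference
    element's pole lies at the low end of the scale."""
    row = grid.ratings[construct_index].astype(float)
    ref = grid.rating(construct_index, reference_element)
    if ref > grid.scale.midpoint:
        row = grid.scale.min_rating + grid.scale.max_rating - row
    elif ref == grid.scale.midpoint:
        raise GridError(
            f"orientation reference rating for construct {construct_index} "
            "sits at the midpoint; orientation undefined"
        )
    return row


def oriented_correlation(
    grid: Grid,
    congruent_index: int,
    discrepant_index: int,
    params: DetectionParameters | None = None,
) -> float:
    """Pearson correlation of two rating rows after pole orientation.

    The congruent construct is oriented by the ideal element's pole
    (which, gaps being small, is also the self pole: the side the
    person wants to keep); the discrepant construct by the self
    element's pole (the present/symptom side). Each row is reflected
    when its reference rating lies above the midpoint, so a positive
    result means "elements resembling the current self on the valued
    construct also sit on the symptom side" -- the implicative-dilemma
    pattern.

    Raises :class:`UndefinedCorrelationError` when either row has zero
    variance over the chosen element set.
    """
    params = params or DetectionParameters()
    cols = _element_set(grid, params)
    x = _oriented_row(grid, congruent_index, grid.ideal_index)[cols]
    y = _oriented_row(grid, discrepant_index, grid.self_index)[cols]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero rating variance in pair ({congruent_index}, "
            f"{discrepant_index}) over the correlation element set"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against float fuzz just past +/-1
    return max(-1.0, min(1.0, r))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_implicative_dilemmas(
    grid: Grid, params: DetectionParameters | None = None
) -> list[ImplicativeDilemma]:
    """All congruent--discrepant pairs whose oriented correlation
    strictly exceeds the threshold.

    Dilemmatic and neutral constructs never participate. Pairs with an
    undefined (zero-variance) correlation are skipped with a warning.
    Output is sorted by descending oriented_r, ties broken by the
    (congruent, discrepant) index pair.
    """
    params = params or DetectionParameters()
    cls = classify_all(grid, params)
    congruent = [c for c in cls if c.category == CONGRUENT]
    discrepant = [c for c in cls if c.category == DISCREPANT]

    out: list[ImplicativeDilemma] = []
    for c, d in itertools.product(congruent, discrepant):
        try:
            r = oriented_correlation(
                grid, c.construct_index, d.construct_index, params
            )
        except GridError as exc:
            # zero-variance rows, or (on wide scales) an orientation
            # reference at the midpoint: correlation undefined, skip
            logger.warning("skipping pair: %s", exc)
            continue
        if r > params.correlation_threshold:
            out.append(_build_dilemma(grid, c, d, r))
    out.sort(key=lambda dd: (-dd.oriented_r, dd.congruent_index, dd.discrepant_index))
    return out


def _pole_label(grid: Grid, construct_index: int, pole: Pole) -> str:
    con = grid.constructs[construct_index]
    if pole is Pole.LEFT:
        return con.left_pole
    if pole is Pole.RIGHT:
        return con.right_pole
    raise GridError("midpoint has no pole label")


def _build_dilemma(
    grid: Grid,
    c: ConstructClassification,
    d: ConstructClassification,
    r: float,
) -> ImplicativeDilemma:
    # congruent: ideal's pole is the valued/self side (ideal is never at
    # the midpoint here -- that would have classified as dilemmatic)
    self_pole_c = pole_of_rating(c.ideal_rating, grid.scale)
    # discrepant: self's pole is the present/symptom side; with
    # gap >= 4 on a symmetric scale, self cannot sit at the midpoint
    present_pole_d = pole_of_rating(d.self_rating, grid.scale)
    return ImplicativeDilemma(
        congruent_index=c.construct_index,
        discrepant_index=d.construct_index,
        oriented_r=r,
        self_pole_congruent=_pole_label(grid, c.construct_index, self_pole_c),
        undesired_pole_congruent=_pole_label(
            grid, c.construct_index, self_pole_c.opposite()
        ),
        present_pole_discrepant=_pole_label(
            grid, d.construct_index, present_pole_d
        ),
        desired_pole_discrepant=_pole_label(
            grid, d.construct_index, present_pole_d.opposite()
        ),
    )


def detect_dilemmatic_constructs(grid: Grid) -> list[int]:
    """Indices of constructs whose ideal-self rating is the scale
    midpoint, in ascending order."""
    mid = grid.scale.midpoint
    ideal = grid.ideal_index
    return [
        k for k in range(grid.n_constructs) if grid.rating(k, ideal) == mid
    ]


# ---------------------------------------------------------------------------
# prototypical figures
# ---------------------------------------------------------------------------


def _on_pole(
    grid: Grid,
    construct_index: int,
    element_index: int,
    pole: Pole,
    margin: int,
) -> bool:
    rating = grid.rating(construct_index, element_index)
    mid = grid.scale.midpoint
    if pole is Pole.LEFT:
        return rating <= mid - margin
    if pole is Pole.RIGHT:
        return rating >= mid + margin
    return False


def find_prototypical_figures(
    grid: Grid,
    dilemma: ImplicativeDilemma,
    params: DetectionParameters | None = None,
) -> PrototypicalFigures:
    """Significant others exemplifying each side of an implicative
    dilemma.

    The *current side* holds others rated on the congruent construct's
    self pole AND the discrepant construct's present pole; the *change
    side* holds others on the undesired and desired poles respectively.
    Membership requires the rating to lie strictly on that side of the
    midpoint by at least ``pole_membership_margin``. Self and ideal are
    never included, and no element can satisfy both conjunctions.
    """
    params = params or DetectionParameters()
    ci, di = dilemma.congruent_index, dilemma.discrepant_index
    scale = grid.scale
    self_pole_c = pole_of_rating(grid.rating(ci, grid.ideal_index), scale)
    present_pole_d = pole_of_rating(grid.rating(di, grid.self_index), scale)
    m = params.pole_membership_margin

    current, change = [], []
    for e in grid.other_indices:
        if _on_pole(grid, ci, e, self_pole_c, m) and _on_pole(
            grid, di, e, present_pole_d, m
        ):
            current.append(e)
        elif _on_pole(grid, ci, e, self_pole_c.opposite(), m) and _on_pole(
            grid, di, e, present_pole_d.opposite(), m
        ):
            change.append(e)
    return PrototypicalFigures(ci, di, tuple(current), tuple(change))


def find_dilemmatic_prototypes(
    grid: Grid, construct_index: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Others at the most extreme rating actually used on each side of
    a dilemmatic construct.

    "Extreme" is relative to the range the rater used on this construct,
    not the theoretical scale ends: on the left side the minimum rating
    given to any significant other, on the right side the maximum. Ties
    are kept; a side with no other-element rating beyond the midpoint
    is empty.
    """
    if grid.rating(construct_index, grid.ideal_index) != grid.scale.midpoint:
        raise GridError(
            f"construct {construct_index} is not dilemmatic "
            "(ideal rating is not the scale midpoint)"
        )
    mid = grid.scale.midpoint
    others = grid.other_indices
    left_ratings = {
        e: grid.rating(construct_index, e)
        for e in others
        if grid.rating(construct_index, e) < mid
    }
    right_ratings = {
        e: grid.rating(construct_index, e)
        for e in others
        if grid.rating(construct_index, e) > mid
    }
    left = tuple(
        e
        for e, r in left_ratings.items()
        if r == min(left_ratings.values())
    ) if left_ratings else ()
    right = tuple(
        e
        for e, r in right_ratings.items()
        if r == max(right_ratings.values())
    ) if right_ratings else ()
    return left, right
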