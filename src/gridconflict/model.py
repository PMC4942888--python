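"""Core data types for repertory grids.

A repertory grid records how a person rates significant people
("elements") on their own bipolar personal constructs (e.g.
"shy -- sociable") using a symmetric Likert scale. The grid always
contains the current self and the ideal self among its elements; the
remaining elements are significant others. Rows are constructs,
columns are elements, and every cell holds an integer rating.

Everything downstream -- construct classification, implicative-dilemma
detection, summary indices -- operates on the :class:`Grid` defined
here. Validation is diagnostic rather than exception-driven:
:func:`validate_grid` returns a list of violations so callers can
report every problem at once.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Role",
    "Pole",
    "RatingScale",
    "Element",
    "Construct",
    "Grid",
    "Violation",
    "GridError",
    "validate_grid",
    "pole_of_rating",
    "reflect_construct",
]


class GridError(ValueError):
    """Domain error raised for operations on invalid grids or indices."""


class Role(str, enum.Enum):
    """Role of an element in the grid."""

    SELF = "self"
    IDEAL = "ideal"
    OTHER = "other"


class Pole(str, enum.Enum):
    """Side of a bipolar construct that a rating falls on.

    ``MIDPOINT`` marks ratings at the scale centre, which belong to
    neither pole.
    """

    LEFT = "left"
    RIGHT = "right"
    MIDPOINT = "midpoint"

    def opposite(self) -> "Pole":
        if self is Pole.LEFT:
            return Pole.RIGHT
        if self is Pole.RIGHT:
            return Pole.LEFT
        return Pole.MIDPOINT


@dataclass(frozen=True)
class RatingScale:
    """A symmetric Likert rating scale.

    The default is the 7-point scale (1..7) whose midpoint 4 anchors
    the dilemmatic-construct rule: an ideal-self rating at the midpoint
    means neither pole is clearly preferred.
    """

    min_rating: int = 1
    max_rating: int = 7
    midpoint: int = 4

    def __post_init__(self) -> None:
        if not (self.min_rating < self.midpoint < self.max_rating):
            raise GridError(
                f"scale must satisfy min < midpoint < max, got "
                f"{self.min_rating} / {self.midpoint} / {self.max_rating}"
            )
        if self.min_rating + self.max_rating != 2 * self.midpoint:
            raise GridError(
                "scale must be symmetric: midpoint must equal "
                "(min_rating + max_rating) / 2 exactly"
            )

    @property
    def span(self) -> int:
        return self.max_rating - self.min_rating

    def contains(self, rating: int) -> bool:
        return self.min_rating <= rating <= self.max_rating

    def reflect(self, rating: int) -> int:
        """Mirror a rating about the midpoint (pole swap)."""
        return self.min_rating + self.max_rating - rating


@dataclass(frozen=True)
class Element:
    label: str
    role: Role = Role.OTHER

    def __post_init__(self) -> None:
        if not self.label:
            raise GridError("element label must be nonempty")
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class Construct:
    """A bipolar construct; identity is positional index, so duplicate
    pole wording across constructs is allowed."""

    left_pole: str
    right_pole: str
    index: int = 0

    def __post_init__(self) -> None:
        if not self.left_pole or not self.right_pole:
            raise GridError("both pole labels must be nonempty")

    def swapped(self) -> "Construct":
        return Construct(self.right_pole, self.left_pole, self.index)


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``where`` is a (construct, element) cell
    or a coarser locus such as an element index."""

    code: str
    message: str
    where: tuple | None = None

    def __str__(self) -> str:  # pragma: no cover - convenience
        loc = f" at {self.where}" if self.where is not None else ""
        return f"[{self.code}]{loc} {self.message}"


@dataclass(frozen=True)
class Grid:
    """A complete repertory grid.

    ``ratings`` is a C x E integer matrix: row ``c`` holds construct
    ``c``'s ratings of every element; column ``e`` is element ``e``'s
    rating profile. Stored as an immutable numpy array.
    """

    elements: tuple[Element, ...]
    constructs: tuple[Construct, ...]
    ratings: np.ndarray
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(
            self,
            "constructs",
            tuple(
                replace(c, index=i) for i, c in enumerate(self.constructs)
            ),
        )
        arr = np.asarray(self.ratings)
        if arr.dtype.kind == "f":
            if not np.all(arr == np.round(arr)):
                raise GridError("ratings must be integers")
            arr = arr.astype(np.int64)
        arr = arr.astype(np.int64, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "ratings", arr)

    # -- shape ---------------------------------------------------------

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_constructs(self) -> int:
        return len(self.constructs)

    # -- role lookups --------------------------------------------------

    def _role_index(self, role: Role) -> int:
        idx = [i for i, e in enumerate(self.elements) if e.role is role]
        if len(idx) != 1:
            raise GridError(
                f"grid must have exactly one {role.value} element, found {len(idx)}"
            )
        return idx[0]

    @property
    def self_index(self) -> int:
        return self._role_index(Role.SELF)

    @property
    def ideal_index(self) -> int:
        return self._role_index(Role.IDEAL)

    @property
    def other_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, e in enumerate(self.elements) if e.role is Role.OTHER
        )

    def rating(self, construct_index: int, element_index: int) -> int:
        return int(self.ratings[construct_index, element_index])

    # -- equality ------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.elements == other.elements
            and self.constructs == other.constructs
            and self.scale == other.scale
            and np.array_equal(self.ratings, other.ratings)
        )

    def __hash__(self) -> int:  # frozen dataclass would otherwise try arrays
        return hash(
            (self.elements, self.constructs, self.scale, self.ratings.tobytes())
        )


def validate_grid(grid: Grid) -> list[Violation]:
    """Check every grid invariant, returning all violations found.

    An empty list means the grid is valid. Checks: matrix shape matches
    the element/construct lists, exactly one self and one ideal element,
    all ratings within scale bounds, and minimum size (>= 3 elements,
    >= 2 constructs) so that correlations and figure searches are
    defined.
    """
    v: list[Violation] = []
    C, E = grid.n_constructs, grid.n_elements

    if grid.ratings.ndim != 2 or grid.ratings.shape != (C, E):
        v.append(
            Violation(
                "shape",
                f"ratings matrix has shape {grid.ratings.shape}, "
                f"expected ({C}, {E})",
            )
        )
        return v  # further cell checks would be meaningless

    n_self = sum(1 for e in grid.elements if e.role is Role.SELF)
    n_ideal = sum(1 for e in grid.elements if e.role is Role.IDEAL)
    if n_self != 1:
        v.append(
            Violation(
                "duplicate_self" if n_self > 1 else "no_self",
                f"expected exactly one self element, found {n_self}",
            )
        )
    if n_ideal != 1:
        v.append(
            Violation(
                "duplicate_ideal" if n_ideal > 1 else "no_ideal",
                f"expected exactly one ideal element, found {n_ideal}",
            )
        )

    if E < 3:
        v.append(Violation("too_few_elements", f"need >= 3 elements, found {E}"))
    if C < 2:
        v.append(
            Violation("too_few_constructs", f"need >= 2 constructs, found {C}")
        )

    lo, hi = grid.scale.min_rating, grid.scale.max_rating
    bad = np.argwhere((grid.ratings < lo) | (grid.ratings > hi))
    for c, e in bad:
        v.append(
            Violation(
                "rating_out_of_bounds",
                f"rating {grid.ratings[c, e]} outside [{lo}, {hi}]",
                where=(int(c), int(e)),
            )
        )
    return v


def require_valid(grid: Grid) -> None:
    """Raise :class:`GridError` listing all violations, if any."""
    violations = validate_grid(grid)
    if violations:
        raise GridError(
            "invalid grid: " + "; ".join(str(x) for x in violations)
        )


def pole_of_rating(rating: int, scale: RatingScale) -> Pole:
    """Which pole a rating falls on, relative to the scale midpoint."""
    if not scale.contains(rating):
        raise GridError(
            f"rating {rating} outside scale "
            f"[{scale.min_rating}, {scale.max_rating}]"
        )
    if rating < scale.midpoint:
        return Pole.LEFT
    if rating > scale.midpoint:
        return Pole.RIGHT
    return Pole.MIDPOINT


def reflect_construct(grid: Grid, construct_index: int) -> Grid:
    """Return a new grid with one construct's orientation flipped.

    Pole labels are swapped and every rating x on that row becomes
    ``min + max - x``. Reflection is an involution and leaves the
    midpoint fixed, so it changes presentation, never substance.
    """
    if not 0 <= construct_index < grid.n_constructs:
        raise GridError(f"construct index {construct_index} out of range")
    ratings = np.array(grid.ratings)
    ratings[construct_index] = (
        grid.scale.min_rating + grid.scale.max_rating - ratings[construct_index]
    )
    constructs = list(grid.constructs)
    constructs[construct_index] = constructs[construct_index].swapped()
    return Grid(grid.elements, constructs, ratings, grid.scale)


def make_grid(
    element_labels: Sequence[str],
    self_label: str,
    ideal_label: str,
    construct_poles: Sequence[tuple[str, str]],
    ratings: Sequence[Sequence[int]],
    scale: RatingScale | None = None,
) -> Grid:
    """Convenience constructor from plain labels and nested lists."""
    elements = []
    for lbl in element_labels:
        if lbl == self_label:
            role = Role.SELF
        elif lbl == ideal_label:
            role = Role.IDEAL
        else:
            role = Role.OTHER
        elements.append(Element(lbl, role))
    constructs = [
        Construct(lp, rp, i) for i, (lp, rp) in enumerate(construct_poles)
    ]
    return Grid(
        tuple(elements),
        tuple(constructs),
        np.asarray(ratings),
        scale or RatingScale(),
    )
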