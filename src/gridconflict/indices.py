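"""Summary indices for a repertory grid, and pre/post comparison.

Four scalar descriptors of the grid, all normalized:

self_ideal_discrepancy
    mean |self - ideal| rating gap across constructs, divided by the
    scale span; 0 when the two profiles coincide, 1 at maximal gap on
    every construct.
self_isolation
    mean normalized city-block distance between the self profile and
    each significant other; high values mean the person sees nobody as
    resembling them.
adequacy_of_others
    1 minus the mean normalized city-block distance between the ideal
    profile and each significant other; high values mean others are
    seen as close to the ideal.
polarization
    percentage of all ratings at the scale extremes.

These are simple, documented operationalizations of the verbally named
measures; they are NOT certified re-implementations of any legacy grid
program's internal formulas. Each distance-based index uses city-block
distance so that construct reflection (a pure presentation change)
leaves it invariant.

:func:`compare_pre_post` reports, for each dilemma detected in a
pre-treatment grid, the two recognized resolution pathways: reduced
self--ideal discrepancy and weakened association between the construct
pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import (
    DetectionParameters,
    ImplicativeDilemma,
    UndefinedCorrelationError,
    detect_implicative_dilemmas,
)
from .model import Grid, GridError

__all__ = [
    "GridIndices",
    "DilemmaDelta",
    "ResolutionPathwayReport",
    "self_ideal_discrepancy",
    "self_isolation",
    "adequacy_of_others",
    "polarization",
    "compute_indices",
    "compare_pre_post",
]


@dataclass(frozen=True)
class GridIndices:
    self_ideal_discrepancy: float
    self_isolation: float
    adequacy_of_others: float
    polarization: float  # percent, 0..100


def self_ideal_discrepancy(grid: Grid) -> float:
    """Mean per-construct |self - ideal| gap, normalized by scale span."""
    gaps = np.abs(
        grid.ratings[:, grid.self_index] - grid.ratings[:, grid.ideal_index]
    )
    return float(gaps.mean() / grid.scale.span)


def _mean_cityblock_from(grid: Grid, column: int) -> float:
    others = grid.other_indices
    if not others:
        raise GridError("grid has no other-role elements")
    ref = grid.ratings[:, column]
    dists = [
        np.abs(grid.ratings[:, e] - ref).sum() for e in others
    ]
    return float(
        np.mean(dists) / (grid.n_constructs * grid.scale.span)
    )


def self_isolation(grid: Grid) -> float:
    """Mean normalized city-block distance from self to each other."""
    return _mean_cityblock_from(grid, grid.self_index)


def adequacy_of_others(grid: Grid) -> float:
    """Closeness of significant others to the ideal (1 - distance)."""
    return 1.0 - _mean_cityblock_from(grid, grid.ideal_index)


def polarization(grid: Grid) -> float:
    """Percent of ratings at the scale extremes."""
    extreme = (grid.ratings == grid.scale.min_rating) | (
        grid.ratings == grid.scale.max_rating
    )
    return float(100.0 * extreme.mean())


def compute_indices(grid: Grid) -> GridIndices:
    return GridIndices(
        self_ideal_discrepancy=self_ideal_discrepancy(grid),
        self_isolation=self_isolation(grid),
        adequacy_of_others=adequacy_of_others(grid),
        polarization=polarization(grid),
    )


# ---------------------------------------------------------------------------
# pre/post comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DilemmaDelta:
    """Change between assessments for one pre-grid dilemma."""

    congruent_index: int
    discrepant_index: int
    pre_oriented_r: float
    post_oriented_r: float | None  # None if undefined in the post grid
    delta_self_ideal_discrepancy: float
    resolved: bool

    @property
    def delta_association_strength(self) -> float | None:
        if self.post_oriented_r is None:
            return None
        return self.post_oriented_r - self.pre_oriented_r


@dataclass(frozen=True)
class ResolutionPathwayReport:
    pre_self_ideal_discrepancy: float
    post_self_ideal_discrepancy: float
    deltas: tuple[DilemmaDelta, ...]


def _check_compatible(pre: Grid, post: Grid) -> None:
    if pre.n_constructs != post.n_constructs:
        raise GridError("pre and post grids differ in construct count")
    for a, b in zip(pre.constructs, post.constructs):
        if (a.left_pole, a.right_pole) != (b.left_pole, b.right_pole):
            raise GridError(
                f"construct {a.index} pole labels differ between grids "
                f"({a.left_pole!r}-{a.right_pole!r} vs "
                f"{b.left_pole!r}-{b.right_pole!r})"
            )
    if pre.scale != post.scale:
        raise GridError("pre and post grids use different rating scales")
    if pre.n_elements != post.n_elements:
        raise GridError("pre and post grids differ in element count")


def _fixed_orientation_r(
    pre: Grid, post: Grid, dilemma: ImplicativeDilemma, params: DetectionParameters
) -> float | None:
    """Post-grid Pearson r for the pair, with reflections fixed from
    the pre grid so the association change is measured on a stable
    orientation even if the pair reclassifies after treatment."""
    cols = (
        list(range(post.n_elements))
        if params.include_self_ideal_in_correlation
        else list(post.other_indices)
    )
    rows = []
    for ci, ref in (
        (dilemma.congruent_index, pre.ideal_index),
        (dilemma.discrepant_index, pre.self_index),
    ):
        row = post.ratings[ci].astype(float)
        if pre.rating(ci, ref) > pre.scale.midpoint:
            row = post.scale.min_rating + post.scale.max_rating - row
        rows.append(row[cols])
    x, y = rows
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def compare_pre_post(
    pre: Grid, post: Grid, params: DetectionParameters | None = None
) -> ResolutionPathwayReport:
    """Track each pre-grid dilemma into the post grid.

    For every dilemma detected in ``pre``, reports the change in the
    overall self--ideal discrepancy, the change in the pair's
    association strength, and whether the pair is still flagged in
    ``post`` (``resolved`` means it no longer is, through either
    pathway: the pair's classification broke, or the correlation
    dropped to the threshold or below).
    """
    params = params or DetectionParameters()
    _check_compatible(pre, post)

    pre_sid = self_ideal_discrepancy(pre)
    post_sid = self_ideal_discrepancy(post)
    post_pairs = {
        d.pair for d in detect_implicative_dilemmas(post, params)
    }

    deltas = []
    for d in detect_implicative_dilemmas(pre, params):
        post_r = _fixed_orientation_r(pre, post, d, params)
        deltas.append(
            DilemmaDelta(
                congruent_index=d.congruent_index,
                discrepant_index=d.discrepant_index,
                pre_oriented_r=d.oriented_r,
                post_oriented_r=post_r,
                delta_self_ideal_discrepancy=post_sid - pre_sid,
                resolved=d.pair not in post_pairs,
            )
        )
    return ResolutionPathwayReport(pre_sid, post_sid, tuple(deltas))
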