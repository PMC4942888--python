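"""Shared fixtures and independent oracles.

The brute-force helpers here are deliberately written with explicit
Python loops and sums so they stay independent of the numpy-based
implementation paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from gridconflict import (
    DetectionParameters,
    Grid,
    RatingScale,
    make_grid,
)


# ---------------------------------------------------------------------------
# worked fixture: 5 elements x 2 constructs
# ---------------------------------------------------------------------------


@pytest.fixture
def g1() -> Grid:
    """Minimal worked example: a congruent 'generous-selfish' construct
    and a discrepant 'depressed-happy' one whose ratings co-vary."""
    return make_grid(
        ["Self", "Ideal", "Mother", "Father", "Friend"],
        "Self",
        "Ideal",
        [("generous", "selfish"), ("depressed", "happy")],
        [[2, 1, 2, 6, 5], [2, 7, 1, 6, 6]],
    )


G1_EXPECTED_R = 8.6 / math.sqrt(18.8 * 29.2)  # two-pass sums done by hand


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def pearson_bruteforce(x, y) -> float:
    """Two-pass Pearson correlation with explicit sums (no numpy)."""
    n = len(x)
    assert n == len(y) and n >= 2
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    denom = math.sqrt(sxx * syy)
    if denom == 0:
        return math.nan
    return sxy / denom


def oriented_pearson_bruteforce(
    grid: Grid, ci: int, di: int, params: DetectionParameters | None = None
) -> float:
    """Re-derivation of the oriented pair correlation from first
    principles: reflect a row when its reference rating lies above the
    midpoint, then brute-force Pearson over the chosen element set."""
    params = params or DetectionParameters()
    scale = grid.scale
    cols = (
        list(range(grid.n_elements))
        if params.include_self_ideal_in_correlation
        else list(grid.other_indices)
    )

    def oriented(row_idx: int, ref_col: int) -> list[float]:
        ref = grid.rating(row_idx, ref_col)
        assert ref != scale.midpoint
        vals = [float(grid.rating(row_idx, e)) for e in cols]
        if ref > scale.midpoint:
            vals = [scale.min_rating + scale.max_rating - v for v in vals]
        return vals

    x = oriented(ci, grid.ideal_index)
    y = oriented(di, grid.self_index)
    return pearson_bruteforce(x, y)


# ---------------------------------------------------------------------------
# random grids for property tests
# ---------------------------------------------------------------------------


def random_grid(
    rng: np.random.Generator,
    max_elements: int = 12,
    max_constructs: int = 10,
    scale: RatingScale | None = None,
) -> Grid:
    """A uniformly random valid grid (may contain degenerate rows)."""
    scale = scale or RatingScale()
    E = int(rng.integers(3, max_elements + 1))
    C = int(rng.integers(2, max_constructs + 1))
    labels = [f"E{i}" for i in range(E)]
    ratings = rng.integers(scale.min_rating, scale.max_rating + 1, (C, E))
    return make_grid(
        labels,
        labels[0],
        labels[1],
        [(f"L{k}", f"R{k}") for k in range(C)],
        ratings,
        scale,
    )
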