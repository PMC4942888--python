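"""Synthetic repertory grids with planted conflict structure.

Real grids cannot be shipped, so every detector and index is exercised
on generated ones. A :class:`SimulationSpec` plants any mix of:

``implicative_dilemma``
    a congruent--discrepant construct pair whose other-element ratings
    are drawn from a latent bivariate construction with a chosen
    correlation, then discretized to the scale;
``null_pair``
    the same construction with zero latent correlation -- an eligible
    pair that should usually NOT be flagged;
``dilemmatic``
    a single construct whose ideal-self rating sits at the midpoint.

Discretization (round + clamp) attenuates the latent correlation, so
tests should assert against the *realized* correlation reported by
:func:`realized_plant_correlations`, not the latent target.

Determinism: a spec with a given seed always produces the same grid;
replicate streams are derived from ``(base_seed, replicate_index)``
seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import (
    CONGRUENT,
    DISCREPANT,
    DetectionParameters,
    UndefinedCorrelationError,
    classify_construct,
    detect_implicative_dilemmas,
    oriented_correlation,
)
from .model import (
    Construct,
    Element,
    Grid,
    GridError,
    RatingScale,
    Role,
)

__all__ = [
    "PlantSpec",
    "SimulationSpec",
    "generate_grid",
    "plant_construct_indices",
    "realized_plant_correlations",
    "detection_rate",
    "null_detection_rate",
    "bracket_threshold",
]

#: latent rating spread (scale units) before rounding to integers
RATING_SD = 1.5

PAIR_KINDS = ("implicative_dilemma", "null_pair")


@dataclass(frozen=True)
class PlantSpec:
    """One planted structure.

    For pair kinds the self/ideal cells must realize the intended
    classification under default parameters (checked at construction):
    the congruent member's gap must be small and its ideal off the
    midpoint, the discrepant member's gap large. ``target_r`` is the
    latent correlation of the two rows over significant others.
    """

    kind: str
    target_r: float = 0.0
    congruent_self: int = 2
    congruent_ideal: int = 1
    discrepant_self: int = 2
    discrepant_ideal: int = 7
    dilemmatic_self: int = 2

    def __post_init__(self) -> None:
        if self.kind not in PAIR_KINDS + ("dilemmatic",):
            raise GridError(f"unknown plant kind {self.kind!r}")
        if self.kind in PAIR_KINDS:
            if not -1.0 < self.target_r < 1.0:
                raise GridError("target_r must be in (-1, 1)")
            scale = RatingScale()
            params = DetectionParameters()
            mid = scale.midpoint
            if self.congruent_ideal == mid or (
                abs(self.congruent_self - self.congruent_ideal)
                > params.congruent_gap_max
            ):
                raise GridError(
                    "congruent self/ideal cells do not classify as congruent"
                )
            if self.discrepant_ideal == mid or (
                abs(self.discrepant_self - self.discrepant_ideal)
                < params.discrepant_gap_min
            ):
                raise GridError(
                    "discrepant self/ideal cells do not classify as discrepant"
                )

    @property
    def n_constructs(self) -> int:
        return 2 if self.kind in PAIR_KINDS else 1


@dataclass(frozen=True)
class SimulationSpec:
    n_other_elements: int
    plants: tuple[PlantSpec, ...] = ()
    background_constructs: int = 0
    seed: int = 0
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        object.__setattr__(self, "plants", tuple(self.plants))
        if self.n_other_elements < 1:
            raise GridError("need at least one other-role element")
        if self.background_constructs < 0:
            raise GridError("background_constructs must be >= 0")
        total = (
            sum(p.n_constructs for p in self.plants) + self.background_constructs
        )
        if total < 2:
            raise GridError("spec must produce at least 2 constructs")
        for p in self.plants:
            if (
                p.kind in PAIR_KINDS
                and p.target_r != 0.0
                and self.n_other_elements < 2
            ):
                raise GridError(
                    "a correlated pair needs at least 2 other elements"
                )


def _discretize(latent: np.ndarray, scale: RatingScale) -> np.ndarray:
    raw = np.rint(scale.midpoint + latent * RATING_SD)
    return np.clip(raw, scale.min_rating, scale.max_rating).astype(np.int64)


def _pair_rows(
    plant: PlantSpec, n_others: int, scale: RatingScale, rng: np.random.Generator
) -> np.ndarray:
    """Two discretized rows over significant others with latent
    correlation ``target_r`` (shared-factor construction)."""
    r = plant.target_r
    a = np.sqrt(abs(r))
    b = np.sqrt(1.0 - abs(r))
    z = rng.standard_normal(n_others)
    e1 = rng.standard_normal(n_others)
    e2 = rng.standard_normal(n_others)
    x1 = a * z + b * e1
    x2 = np.sign(r) * a * z + b * e2 if r != 0 else e2
    return np.vstack([_discretize(x1, scale), _discretize(x2, scale)])


def plant_construct_indices(spec: SimulationSpec) -> list[tuple[int, ...]]:
    """Construct row indices of each plant, in spec order (pairs take
    two consecutive rows; background rows come last)."""
    out, k = [], 0
    for p in spec.plants:
        out.append(tuple(range(k, k + p.n_constructs)))
        k += p.n_constructs
    return out


def generate_grid(spec: SimulationSpec) -> Grid:
    """Deterministically generate a valid grid realizing the spec.

    Self/ideal cells come straight from each plant (so the intended
    classification holds by construction); other-element ratings are
    latent-normal draws discretized to the scale. Background construct
    rows are independent noise with unconstrained self/ideal cells.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.scale
    n_others = spec.n_other_elements

    elements = (
        Element("Self now", Role.SELF),
        Element("Ideal self", Role.IDEAL),
        *(
            Element(f"Other{i + 1:02d}", Role.OTHER)
            for i in range(n_others)
        ),
    )

    rows: list[np.ndarray] = []
    constructs: list[Construct] = []

    def add_row(self_r: int, ideal_r: int, others: np.ndarray, tag: str) -> None:
        k = len(constructs)
        constructs.append(Construct(f"{tag}-{k}-left", f"{tag}-{k}-right", k))
        rows.append(np.concatenate([[self_r, ideal_r], others]))

    for p in spec.plants:
        if p.kind in PAIR_KINDS:
            others = _pair_rows(p, n_others, scale, rng)
            add_row(p.congruent_self, p.congruent_ideal, others[0], "congruent")
            add_row(p.discrepant_self, p.discrepant_ideal, others[1], "discrepant")
        else:
            others = _discretize(rng.standard_normal(n_others), scale)
            add_row(p.dilemmatic_self, scale.midpoint, others, "dilemmatic")

    for _ in range(spec.background_constructs):
        vals = rng.integers(
            scale.min_rating, scale.max_rating + 1, size=n_others + 2
        )
        add_row(int(vals[0]), int(vals[1]), vals[2:], "background")

    grid = Grid(elements, tuple(constructs), np.vstack(rows), scale)

    # plant-fidelity check: intended classifications must be realized
    for p, idx in zip(spec.plants, plant_construct_indices(spec)):
        if p.kind in PAIR_KINDS:
            got = (
                classify_construct(grid, idx[0]).category,
                classify_construct(grid, idx[1]).category,
            )
            if got != (CONGRUENT, DISCREPANT):
                raise GridError(
                    f"plant {p.kind} realized classification {got}"
                )
        elif classify_construct(grid, idx[0]).category != "dilemmatic":
            raise GridError("dilemmatic plant not realized")
    return grid


def realized_plant_correlations(
    grid: Grid,
    spec: SimulationSpec,
    params: DetectionParameters | None = None,
) -> list[float | None]:
    """Oriented correlation actually realized by each pair plant after
    discretization (None for dilemmatic plants or zero-variance rows)."""
    params = params or DetectionParameters()
    out: list[float | None] = []
    for p, idx in zip(spec.plants, plant_construct_indices(spec)):
        if p.kind not in PAIR_KINDS:
            out.append(None)
            continue
        try:
            out.append(oriented_correlation(grid, idx[0], idx[1], params))
        except UndefinedCorrelationError:
            out.append(None)
    return out


def _replicate_seed(base_seed: int, replicate: int) -> int:
    """Documented counter scheme: child seed from (base, counter)."""
    return int(np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0])


def detection_rate(
    target_r: float,
    n_other_elements: int,
    n_replicates: int,
    seed: int,
    params: DetectionParameters | None = None,
) -> float:
    """Fraction of replicate grids in which a single planted pair with
    the given latent correlation is flagged as an implicative dilemma."""
    params = params or DetectionParameters()
    kind = "null_pair" if target_r == 0 else "implicative_dilemma"
    hits = 0
    for rep in range(n_replicates):
        spec = SimulationSpec(
            n_other_elements=n_other_elements,
            plants=(PlantSpec(kind, target_r=target_r),),
            seed=_replicate_seed(seed, rep),
        )
        grid = generate_grid(spec)
        flagged = {
            d.pair for d in detect_implicative_dilemmas(grid, params)
        }
        hits += (0, 1) in flagged
    return hits / n_replicates


def null_detection_rate(
    n_other_elements: int,
    n_replicates: int,
    seed: int,
    params: DetectionParameters | None = None,
) -> float:
    """Operating characteristic of the threshold rule under no planted
    association: P(oriented r > threshold) for a null pair at this
    element count."""
    if n_replicates < 100:
        raise GridError("need at least 100 replicates for a stable rate")
    return detection_rate(0.0, n_other_elements, n_replicates, seed, params)


# ---------------------------------------------------------------------------
# decision-boundary location
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass Pearson correlation by explicit sums (the oracle the
    boundary search is measured with)."""
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if denom == 0:
        return float("nan")
    return float((xm * ym).sum() / denom)


def bracket_threshold(
    params: DetectionParameters | None = None,
    seed: int = 0,
    n_elements: int = 12,
    iterations: int = 6000,
) -> float:
    """Locate the detector's decision boundary empirically.

    Hill-climbs over integer rating rows of a minimal two-construct
    grid (self/ideal cells fixed to a congruent/discrepant pattern,
    other cells mutated), pushing the pair's correlation toward the
    configured threshold from both sides while querying the detector,
    and returns the supremum of correlations at which the pair was NOT
    flagged -- the boundary, equal to ``correlation_threshold`` under
    strict-inequality flagging.
    """
    params = params or DetectionParameters()
    rng = np.random.default_rng(seed)
    scale = RatingScale()
    n_others = n_elements - 2
    if n_others < 3:
        raise GridError("need at least 5 elements to search")

    elements = (
        Element("Self now", Role.SELF),
        Element("Ideal self", Role.IDEAL),
        *(Element(f"Other{i + 1:02d}", Role.OTHER) for i in range(n_others)),
    )
    constructs = (
        Construct("keep-left", "keep-right", 0),
        Construct("sym-left", "sym-right", 1),
    )
    fixed = np.array([[2, 1], [2, 7]])

    def rows_to_grid(others: np.ndarray) -> Grid:
        return Grid(
            elements, constructs, np.hstack([fixed, others]), scale
        )

    def oracle_r(others: np.ndarray) -> float:
        # same element set the detector uses
        if params.include_self_ideal_in_correlation:
            x = np.concatenate([fixed[0], others[0]]).astype(float)
            y = np.concatenate([fixed[1], others[1]]).astype(float)
        else:
            x, y = others[0].astype(float), others[1].astype(float)
        return _pearson(x, y)

    def flagged(others: np.ndarray) -> bool:
        dilemmas = detect_implicative_dilemmas(rows_to_grid(others), params)
        return any(d.pair == (0, 1) for d in dilemmas)

    t = params.correlation_threshold
    best_below = -np.inf
    current = rng.integers(scale.min_rating, scale.max_rating + 1, (2, n_others))
    cur_gap = np.inf
    stale = 0
    for _ in range(iterations):
        cand = current.copy()
        i = rng.integers(0, 2)
        j = rng.integers(0, n_others)
        cand[i, j] = rng.integers(scale.min_rating, scale.max_rating + 1)
        r = oracle_r(cand)
        if np.isnan(r):
            continue
        if not flagged(cand) and r > best_below:
            best_below = r
        gap = abs(r - t)
        if gap < cur_gap:
            current, cur_gap, stale = cand, gap, 0
        else:
            stale += 1
            if stale > 300:  # random restart off a plateau
                current = rng.integers(
                    scale.min_rating, scale.max_rating + 1, (2, n_others)
                )
                cur_gap, stale = np.inf, 0
    return float(best_below)
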