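"""High-level analysis interface.

:class:`DilemmaAnalysis` is the model object built from a grid (or a
grid file); its :meth:`~DilemmaAnalysis.fit` runs the full pipeline --
validation, construct classification, implicative-dilemma detection,
prototypical figures, dilemmatic constructs and summary indices -- and
returns a :class:`DilemmaResults` carrying the findings, Fisher-z
confidence intervals for each dilemma's correlation, diagnostics, and
a text ``summary()``.

The results convert to the serializable
:class:`~gridconflict.io.AnalysisResultDocument` via
:meth:`DilemmaResults.to_document`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .detection import (
    CONGRUENT,
    DISCREPANT,
    ConstructClassification,
    DetectionParameters,
    ImplicativeDilemma,
    PrototypicalFigures,
    classify_all,
    detect_dilemmatic_constructs,
    detect_implicative_dilemmas,
    find_dilemmatic_prototypes,
    find_prototypical_figures,
    oriented_correlation,
)
from .indices import GridIndices, compute_indices
from .io import (
    AnalysisResultDocument,
    ClassificationDoc,
    ConstructDoc,
    DilemmaDoc,
    DilemmaticConstructDoc,
    ElementDoc,
    FiguresDoc,
    GridSummaryDoc,
    IndicesDoc,
    ParametersDoc,
    ScaleDoc,
    read_grid,
    round6,
)
from .model import Grid, GridError, require_valid

__all__ = ["DilemmaAnalysis", "DilemmaResults", "analyze_grid"]


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = math.atanh(r)
    # two-sided normal quantile; 1.959964 for 95%
    from statistics import NormalDist

    q = NormalDist().inv_cdf(0.5 + level / 2.0)
    se = 1.0 / math.sqrt(n - 3)
    return (math.tanh(z - q * se), math.tanh(z + q * se))


@dataclass(frozen=True)
class DilemmaResults:
    """Findings of one grid analysis.

    Attributes mirror the clinical workflow: per-construct
    classifications, the implicative dilemmas sorted by association
    strength, their prototypical figures, the dilemmatic constructs
    with their pole extremes, and the four grid indices.
    """

    grid: Grid
    params: DetectionParameters
    classifications: tuple[ConstructClassification, ...]
    dilemmas: tuple[ImplicativeDilemma, ...]
    figures: tuple[PrototypicalFigures, ...]
    dilemmatic_constructs: tuple[int, ...]
    dilemmatic_prototypes: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    indices: GridIndices
    warnings: tuple[str, ...]

    # -- tabular views -------------------------------------------------

    def classification_frame(self) -> pd.DataFrame:
        rows = [
            {
                "construct": c.construct_index,
                "left_pole": self.grid.constructs[c.construct_index].left_pole,
                "right_pole": self.grid.constructs[c.construct_index].right_pole,
                "self": c.self_rating,
                "ideal": c.ideal_rating,
                "gap": c.gap,
                "category": c.category,
            }
            for c in self.classifications
        ]
        return pd.DataFrame(rows)

    def dilemma_frame(self) -> pd.DataFrame:
        n = (
            self.grid.n_elements
            if self.params.include_self_ideal_in_correlation
            else len(self.grid.other_indices)
        )
        rows = []
        for d in self.dilemmas:
            lo, hi = _fisher_ci(d.oriented_r, n)
            rows.append(
                {
                    "congruent": d.congruent_index,
                    "discrepant": d.discrepant_index,
                    "oriented_r": d.oriented_r,
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "keep": d.self_pole_congruent,
                    "avoid": d.undesired_pole_congruent,
                    "present": d.present_pole_discrepant,
                    "desired": d.desired_pole_discrepant,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "congruent",
                "discrepant",
                "oriented_r",
                "ci95_low",
                "ci95_high",
                "keep",
                "avoid",
                "present",
                "desired",
            ],
        )

    def summary(self) -> str:
        """Human-readable overview of the analysis."""
        g = self.grid
        lines = [
            "Repertory grid conflict analysis",
            "=" * 40,
            f"Elements:   {g.n_elements} "
            f"({len(g.other_indices)} significant others)",
            f"Constructs: {g.n_constructs}",
            f"Scale:      {g.scale.min_rating}-{g.scale.max_rating} "
            f"(midpoint {g.scale.midpoint})",
            "",
            "Construct classification:",
            self.classification_frame().to_string(index=False),
            "",
            f"Implicative dilemmas (r > "
            f"{self.params.correlation_threshold:g}): {len(self.dilemmas)}",
        ]
        if len(self.dilemmas):
            lines.append(
                self.dilemma_frame().to_string(
                    index=False, float_format=lambda v: f"{v:.3f}"
                )
            )
        if self.dilemmatic_constructs:
            labels = ", ".join(
                f"{k} ({g.constructs[k].left_pole}-{g.constructs[k].right_pole})"
                for k in self.dilemmatic_constructs
            )
            lines.append(f"Dilemmatic constructs: {labels}")
        idx = self.indices
        lines += [
            "",
            "Indices:",
            f"  self-ideal discrepancy: {idx.self_ideal_discrepancy:.3f}",
            f"  self isolation:         {idx.self_isolation:.3f}",
            f"  adequacy of others:     {idx.adequacy_of_others:.3f}",
            f"  polarization:           {idx.polarization:.1f}%",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------

    def to_document(self) -> AnalysisResultDocument:
        g = self.grid
        labels = [e.label for e in g.elements]
        dilemma_docs = []
        for d, f in zip(self.dilemmas, self.figures):
            dilemma_docs.append(
                DilemmaDoc(
                    congruent_index=d.congruent_index,
                    discrepant_index=d.discrepant_index,
                    oriented_r=round6(d.oriented_r),
                    self_pole_congruent=d.self_pole_congruent,
                    undesired_pole_congruent=d.undesired_pole_congruent,
                    present_pole_discrepant=d.present_pole_discrepant,
                    desired_pole_discrepant=d.desired_pole_discrepant,
                    figures=FiguresDoc(
                        current_side=[labels[e] for e in f.current_side],
                        change_side=[labels[e] for e in f.change_side],
                    ),
                )
            )
        dilemmatic_docs = []
        for k, (left, right) in zip(
            self.dilemmatic_constructs, self.dilemmatic_prototypes
        ):
            con = g.constructs[k]
            dilemmatic_docs.append(
                DilemmaticConstructDoc(
                    construct_index=k,
                    left_pole=con.left_pole,
                    right_pole=con.right_pole,
                    left_extreme_elements=[labels[e] for e in left],
                    right_extreme_elements=[labels[e] for e in right],
                )
            )
        return AnalysisResultDocument(
            tool="gridconflict",
            tool_version=__version__,
            parameters=ParametersDoc(
                correlation_threshold=round6(self.params.correlation_threshold),
                congruent_gap_max=self.params.congruent_gap_max,
                discrepant_gap_min=self.params.discrepant_gap_min,
                include_self_ideal_in_correlation=(
                    self.params.include_self_ideal_in_correlation
                ),
                pole_membership_margin=self.params.pole_membership_margin,
            ),
            grid=GridSummaryDoc(
                n_elements=g.n_elements,
                n_constructs=g.n_constructs,
                scale=ScaleDoc(
                    min_rating=g.scale.min_rating,
                    max_rating=g.scale.max_rating,
                    midpoint=g.scale.midpoint,
                ),
                elements=[
                    ElementDoc(label=e.label, role=e.role.value)
                    for e in g.elements
                ],
                constructs=[
                    ConstructDoc(left_pole=c.left_pole, right_pole=c.right_pole)
                    for c in g.constructs
                ],
            ),
            classifications=[
                ClassificationDoc(
                    construct_index=c.construct_index,
                    category=c.category,
                    self_rating=c.self_rating,
                    ideal_rating=c.ideal_rating,
                    gap=c.gap,
                )
                for c in self.classifications
            ],
            dilemmas=dilemma_docs,
            dilemmatic_constructs=dilemmatic_docs,
            indices=IndicesDoc(
                self_ideal_discrepancy=round6(self.indices.self_ideal_discrepancy),
                self_isolation=round6(self.indices.self_isolation),
                adequacy_of_others=round6(self.indices.adequacy_of_others),
                polarization=round6(self.indices.polarization),
            ),
        )

    def plot_dilemmas(self, ax=None):
        """Bar chart of oriented correlations against the threshold.

        Requires matplotlib (``pip install gridconflict[plot]``).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [
            f"{d.self_pole_congruent}/{d.present_pole_discrepant}"
            for d in self.dilemmas
        ]
        ax.bar(range(len(self.dilemmas)), [d.oriented_r for d in self.dilemmas])
        ax.axhline(
            self.params.correlation_threshold, color="red", linestyle="--",
            label=f"threshold {self.params.correlation_threshold:g}",
        )
        ax.set_xticks(range(len(self.dilemmas)))
        ax.set_xticklabels(names, rotation=45, ha="right")
        ax.set_ylabel("oriented r")
        ax.legend()
        return ax


class DilemmaAnalysis:
    """Conflict-analysis model for one repertory grid.

    Parameters
    ----------
    grid
        A valid :class:`~gridconflict.model.Grid`.
    params
        Detection parameters; defaults follow the standard procedure
        (r > 0.35, gap bands 1/4, all elements in the correlation).
    """

    def __init__(self, grid: Grid, params: DetectionParameters | None = None):
        require_valid(grid)
        self.grid = grid
        self.params = params or DetectionParameters()

    @classmethod
    def from_file(
        cls, path, params: DetectionParameters | None = None
    ) -> "DilemmaAnalysis":
        return cls(read_grid(path), params)

    def fit(self) -> DilemmaResults:
        """Run the full detection pipeline."""
        grid, params = self.grid, self.params
        warnings: list[str] = []

        classifications = classify_all(grid, params)
        # record zero-variance pairs skipped by the detector
        congruent = [
            c.construct_index for c in classifications if c.category == CONGRUENT
        ]
        discrepant = [
            c.construct_index for c in classifications if c.category == DISCREPANT
        ]
        for ci in congruent:
            for di in discrepant:
                try:
                    oriented_correlation(grid, ci, di, params)
                except GridError as exc:
                    warnings.append(str(exc))

        dilemmas = detect_implicative_dilemmas(grid, params)
        figures = tuple(
            find_prototypical_figures(grid, d, params) for d in dilemmas
        )
        dilemmatic = tuple(detect_dilemmatic_constructs(grid))
        prototypes = tuple(
            find_dilemmatic_prototypes(grid, k) for k in dilemmatic
        )
        return DilemmaResults(
            grid=grid,
            params=params,
            classifications=tuple(classifications),
            dilemmas=tuple(dilemmas),
            figures=figures,
            dilemmatic_constructs=dilemmatic,
            dilemmatic_prototypes=prototypes,
            indices=compute_indices(grid),
            warnings=tuple(warnings),
        )


def analyze_grid(
    grid: Grid, params: DetectionParameters | None = None
) -> DilemmaResults:
    """One-call pipeline: ``DilemmaAnalysis(grid, params).fit()``."""
    return DilemmaAnalysis(grid, params).fit()
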