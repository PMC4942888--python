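"""Grid file I/O and the JSON analysis-results document.

Grid text dialect
-----------------
A grid is a small UTF-8 delimited text file (TAB by default):

.. code-block:: text

    # optional comment lines start with '#'
    scale 1 7
    SELF:Self now	IDEAL:Ideal self	Mother	Father	Friend
    generous	2	1	2	6	5	selfish
    depressed	2	7	1	6	6	happy

* line 1 (first non-comment): ``scale <min> <max>``; the midpoint is
  inferred and the scale must be symmetric (odd number of levels);
* line 2: element headers, exactly one carrying the ``SELF:`` prefix
  and one the ``IDEAL:`` prefix;
* each further line: left pole label, one integer rating per element,
  right pole label.

Labels containing the delimiter, quotes or newlines are double-quoted
with doubled-quote escaping (CSV convention). Because role prefixes are
recognized after unquoting, an *other*-element label may not itself
begin with a role prefix; the writer rejects such grids.

Results document
----------------
:class:`AnalysisResultDocument` is the complete, reproducible record of
one analysis: grid summary, parameters used, classifications, dilemmas
with their prototypical figures, dilemmatic constructs with their pole
extremes, and the four indices. It serializes to JSON with stable key
order and floats rounded to 6 decimals; the matching JSON schema ships
in ``gridconflict/schemas/results.schema.json``.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .model import (
    Construct,
    Element,
    Grid,
    Role,
    RatingScale,
    GridError,
    validate_grid,
)

__all__ = [
    "GridFileDialect",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "AnalysisResultDocument",
    "write_results",
    "read_results",
    "validate_results_document",
    "load_shipped_schema",
]

SELF_PREFIX = "SELF:"
IDEAL_PREFIX = "IDEAL:"


class GridFormatError(GridError):
    """Parse or validation failure, locating the offending line/field."""

    def __init__(self, message: str, line: int | None = None, field: int | None = None):
        loc = ""
        if line is not None:
            loc = f"line {line}"
            if field is not None:
                loc += f", field {field + 1}"
            loc = f" ({loc})"
        super().__init__(f"{message}{loc}")
        self.line = line
        self.field = field


@dataclass(frozen=True)
class GridFileDialect:
    delimiter: str = "\t"
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise GridError("delimiter must be a single character")


def _open_maybe(path_or_stream, mode: str):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode, encoding="utf-8", newline=""), True
    return path_or_stream, False


def read_grid(
    source, dialect: GridFileDialect | None = None, *, validate: bool = True
) -> Grid:
    """Parse a grid file (path, or open text stream).

    With ``validate=True`` (default) grid-invariant violations raise a
    :class:`GridFormatError`; with ``validate=False`` syntactically
    well-formed but invalid grids are returned for the caller to
    diagnose via :func:`~gridconflict.model.validate_grid`.
    """
    dialect = dialect or GridFileDialect()
    stream, owned = _open_maybe(source, "r")
    try:
        return _parse_grid(stream, dialect, validate)
    finally:
        if owned:
            stream.close()


def _parse_grid(stream: IO[str], dialect: GridFileDialect, validate: bool = True) -> Grid:
    numbered = [
        (i + 1, line)
        for i, line in enumerate(stream.read().splitlines())
        if line.strip() and not line.lstrip().startswith(dialect.comment_prefix)
    ]
    if len(numbered) < 4:
        raise GridFormatError(
            "grid file needs a scale line, an element header line and at "
            "least 2 construct lines"
        )

    # scale line
    ln, text = numbered[0]
    parts = text.split()
    if len(parts) != 3 or parts[0] != "scale":
        raise GridFormatError("expected 'scale <min> <max>'", line=ln)
    try:
        lo, hi = int(parts[1]), int(parts[2])
    except ValueError:
        raise GridFormatError("scale bounds must be integers", line=ln) from None
    if (lo + hi) % 2 != 0 or not lo < (lo + hi) // 2 < hi:
        raise GridFormatError(
            f"scale {lo}..{hi} is not a symmetric scale with an integer "
            "midpoint",
            line=ln,
        )
    scale = RatingScale(lo, hi, (lo + hi) // 2)

    def fields_of(line_no: int, text: str) -> list[str]:
        reader = csv.reader(
            _io.StringIO(text), delimiter=dialect.delimiter, quotechar='"'
        )
        rows = list(reader)
        if len(rows) != 1:
            raise GridFormatError("malformed quoting", line=line_no)
        return rows[0]

    # element header line
    ln, text = numbered[1]
    headers = fields_of(ln, text)
    elements: list[Element] = []
    for j, h in enumerate(headers):
        if h.startswith(SELF_PREFIX):
            elements.append(Element(h[len(SELF_PREFIX):], Role.SELF))
        elif h.startswith(IDEAL_PREFIX):
            elements.append(Element(h[len(IDEAL_PREFIX):], Role.IDEAL))
        else:
            if not h:
                raise GridFormatError("empty element label", line=ln, field=j)
            elements.append(Element(h, Role.OTHER))
    n_self = sum(1 for e in elements if e.role is Role.SELF)
    n_ideal = sum(1 for e in elements if e.role is Role.IDEAL)
    if n_self != 1:
        raise GridFormatError(
            f"expected exactly one SELF: element, found {n_self}", line=ln
        )
    if n_ideal != 1:
        raise GridFormatError(
            f"no ideal element" if n_ideal == 0 else "duplicate IDEAL: element",
            line=ln,
        )
    E = len(elements)

    # construct lines
    constructs: list[Construct] = []
    rows: list[list[int]] = []
    for ln, text in numbered[2:]:
        f = fields_of(ln, text)
        if len(f) != E + 2:
            raise GridFormatError(
                f"expected {E + 2} fields (left pole, {E} ratings, right "
                f"pole), found {len(f)}",
                line=ln,
            )
        left, right = f[0], f[-1]
        if not left or not right:
            raise GridFormatError("empty pole label", line=ln)
        ratings = []
        for j, cell in enumerate(f[1:-1], start=1):
            try:
                ratings.append(int(cell))
            except ValueError:
                raise GridFormatError(
                    f"rating {cell!r} is not an integer", line=ln, field=j
                ) from None
        constructs.append(Construct(left, right, len(constructs)))
        rows.append(ratings)

    grid = Grid(tuple(elements), tuple(constructs), np.array(rows), scale)
    if validate:
        violations = validate_grid(grid)
        if violations:
            raise GridFormatError(
                "invalid grid: " + "; ".join(str(v) for v in violations)
            )
    return grid


def write_grid(grid: Grid, target, dialect: GridFileDialect | None = None) -> None:
    """Write a grid in the text dialect; ``read_grid`` round-trips it."""
    dialect = dialect or GridFileDialect()
    violations = validate_grid(grid)
    if violations:
        raise GridFormatError(
            "refusing to write invalid grid: "
            + "; ".join(str(v) for v in violations)
        )
    for e in grid.elements:
        if e.role is Role.OTHER and (
            e.label.startswith(SELF_PREFIX) or e.label.startswith(IDEAL_PREFIX)
        ):
            raise GridFormatError(
                f"other-element label {e.label!r} begins with a role prefix "
                "and cannot be represented in this dialect"
            )

    stream, owned = _open_maybe(target, "w")
    try:
        stream.write(f"scale {grid.scale.min_rating} {grid.scale.max_rating}\n")
        writer = csv.writer(
            stream, delimiter=dialect.delimiter, quotechar='"',
            lineterminator="\n",
        )
        headers = []
        for e in grid.elements:
            prefix = {
                Role.SELF: SELF_PREFIX,
                Role.IDEAL: IDEAL_PREFIX,
                Role.OTHER: "",
            }[e.role]
            headers.append(prefix + e.label)
        writer.writerow(headers)
        for k, con in enumerate(grid.constructs):
            writer.writerow(
                [con.left_pole]
                + [str(int(x)) for x in grid.ratings[k]]
                + [con.right_pole]
            )
    finally:
        if owned:
            stream.close()


# ---------------------------------------------------------------------------
# results document
# ---------------------------------------------------------------------------


def round6(x: float) -> float:
    """Float policy for serialized documents: 6 decimals."""
    return round(float(x), 6)


class _Doc(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScaleDoc(_Doc):
    min_rating: int
    max_rating: int
    midpoint: int


class ElementDoc(_Doc):
    label: str
    role: Literal["self", "ideal", "other"]


class ConstructDoc(_Doc):
    left_pole: str
    right_pole: str


class GridSummaryDoc(_Doc):
    n_elements: int
    n_constructs: int
    scale: ScaleDoc
    elements: list[ElementDoc]
    constructs: list[ConstructDoc]


class ParametersDoc(_Doc):
    correlation_threshold: float
    congruent_gap_max: int
    discrepant_gap_min: int
    include_self_ideal_in_correlation: bool
    pole_membership_margin: int


class ClassificationDoc(_Doc):
    construct_index: int
    category: Literal["congruent", "discrepant", "dilemmatic", "neutral"]
    self_rating: int
    ideal_rating: int
    gap: int


class FiguresDoc(_Doc):
    current_side: list[str] = Field(
        description="labels of others exemplifying the current position"
    )
    change_side: list[str] = Field(
        description="labels of others exemplifying the implication of change"
    )


class DilemmaDoc(_Doc):
    congruent_index: int
    discrepant_index: int
    oriented_r: float
    self_pole_congruent: str
    undesired_pole_congruent: str
    present_pole_discrepant: str
    desired_pole_discrepant: str
    figures: FiguresDoc


class DilemmaticConstructDoc(_Doc):
    construct_index: int
    left_pole: str
    right_pole: str
    left_extreme_elements: list[str]
    right_extreme_elements: list[str]


class IndicesDoc(_Doc):
    self_ideal_discrepancy: float
    self_isolation: float
    adequacy_of_others: float
    polarization: float


class AnalysisResultDocument(_Doc):
    """Complete record of one grid analysis; reproducible from this
    document plus the grid file alone."""

    tool: str
    tool_version: str
    parameters: ParametersDoc
    grid: GridSummaryDoc
    classifications: list[ClassificationDoc]
    dilemmas: list[DilemmaDoc]
    dilemmatic_constructs: list[DilemmaticConstructDoc]
    indices: IndicesDoc


def write_results(result: AnalysisResultDocument, target) -> None:
    """Serialize a results document as stable-key-order JSON."""
    payload = result.model_dump(mode="json")
    text = json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    else:
        target.write(text)


def read_results(source) -> AnalysisResultDocument:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    return AnalysisResultDocument.model_validate_json(text)


def validate_results_document(payload) -> AnalysisResultDocument:
    """Validate a dict/JSON payload against the document model,
    raising ``pydantic.ValidationError`` on mismatch."""
    if isinstance(payload, (str, bytes)):
        return AnalysisResultDocument.model_validate_json(payload)
    return AnalysisResultDocument.model_validate(payload)


def results_json_schema() -> dict:
    """The JSON schema of the results document (draft 2020-12)."""
    return AnalysisResultDocument.model_json_schema()


def load_shipped_schema() -> dict:
    """The schema file shipped with the package (kept in sync with
    :func:`results_json_schema` by the test suite)."""
    text = (
        resources.files("gridconflict.schemas")
        .joinpath("results.schema.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)
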