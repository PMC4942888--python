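"""Plain-text case-formulation report.

Renders an :class:`~gridconflict.io.AnalysisResultDocument` as the
two-column schematic used when presenting a dilemma to a patient: the
current position (valued pole + symptom pole) on the left, the
implication of change (undesired pole + desired pole) on the right,
with the prototypical figures exemplifying each side underneath.
Rendering is deterministic: the same document always yields the same
bytes.
"""

from __future__ import annotations

from .io import AnalysisResultDocument

__all__ = ["render_report"]

_COL = 30


def _two_col(left: str, right: str) -> str:
    return f"  {left:<{_COL}}{right}"


def render_report(doc: AnalysisResultDocument) -> str:
    out: list[str] = []
    g = doc.grid
    out.append("REPERTORY GRID CONFLICT REPORT")
    out.append("=" * 60)
    out.append(
        f"Grid: {g.n_elements} elements x {g.n_constructs} constructs, "
        f"scale {g.scale.min_rating}-{g.scale.max_rating}"
    )
    out.append("")

    if not doc.dilemmas:
        out.append("No implicative dilemmas detected.")
    for i, d in enumerate(doc.dilemmas, 1):
        out.append(
            f"IMPLICATIVE DILEMMA {i} (associated at r = {d.oriented_r:.3f})"
        )
        out.append(_two_col("current position", "implication of change"))
        out.append(_two_col("-" * len("current position"),
                            "-" * len("implication of change")))
        out.append(_two_col(d.self_pole_congruent, d.undesired_pole_congruent))
        out.append(_two_col(d.present_pole_discrepant, d.desired_pole_discrepant))
        cur = ", ".join(d.figures.current_side) or "(none)"
        chg = ", ".join(d.figures.change_side) or "(none)"
        out.append(_two_col(f"figures: {cur}", f"figures: {chg}"))
        out.append("")

    if doc.dilemmatic_constructs:
        out.append("DILEMMATIC CONSTRUCTS (ideal at the scale midpoint)")
        for dc in doc.dilemmatic_constructs:
            left_ex = ", ".join(dc.left_extreme_elements) or "(none)"
            right_ex = ", ".join(dc.right_extreme_elements) or "(none)"
            out.append(
                f"  {dc.left_pole} - {dc.right_pole}: "
                f"most {dc.left_pole}: {left_ex}; "
                f"most {dc.right_pole}: {right_ex}"
            )
        out.append("")

    idx = doc.indices
    out.append("GRID INDICES")
    out.append(f"  self-ideal discrepancy : {idx.self_ideal_discrepancy:.3f}")
    out.append(f"  self isolation         : {idx.self_isolation:.3f}")
    out.append(f"  adequacy of others     : {idx.adequacy_of_others:.3f}")
    out.append(f"  polarization           : {idx.polarization:.1f}%")
    out.append("")

    p = doc.parameters
    out.append(
        f"parameters: threshold r > {p.correlation_threshold:g}; "
        f"congruent gap <= {p.congruent_gap_max}; "
        f"discrepant gap >= {p.discrepant_gap_min}; "
        f"self/ideal in correlation: "
        f"{'yes' if p.include_self_ideal_in_correlation else 'no'}; "
        f"pole margin {p.pole_membership_margin}"
    )
    out.append(f"generated by {doc.tool} {doc.tool_version}")
    return "\n".join(out) + "\n"
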