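"""Construct classification, dilemma detection and prototypical figures."""

import logging

import numpy as np
import pytest

from gridconflict import (
    DetectionParameters,
    GridError,
    UndefinedCorrelationError,
    classify_construct,
    detect_dilemmatic_constructs,
    detect_implicative_dilemmas,
    find_dilemmatic_prototypes,
    find_prototypical_figures,
    make_grid,
    oriented_correlation,
    reflect_construct,
)
from gridconflict.model import Grid, pole_of_rating

from conftest import (
    G1_EXPECTED_R,
    oriented_pearson_bruteforce,
    random_grid,
)


def two_construct_grid(row_c, row_d, n_labels=None):
    """Helper: congruent row + discrepant row over named elements."""
    E = len(row_c)
    labels = n_labels or ["Self", "Ideal"] + [f"O{i}" for i in range(E - 2)]
    return make_grid(
        labels, labels[0], labels[1],
        [("keepL", "keepR"), ("symL", "symR")],
        [row_c, row_d],
    )


class TestClassification:
    @pytest.mark.parametrize(
        "self_r,ideal_r,expected",
        [
            (2, 1, "congruent"),
            (5, 5, "congruent"),
            (2, 7, "discrepant"),
            (7, 3, "discrepant"),
            (3, 6, "neutral"),
            (1, 3, "neutral"),
            (1, 4, "dilemmatic"),
            (7, 4, "dilemmatic"),
            (4, 4, "dilemmatic"),
        ],
    )
    def test_default_gap_bands(self, self_r, ideal_r, expected):
        g = two_construct_grid([self_r, ideal_r, 3, 5], [1, 6, 2, 7])
        c = classify_construct(g, 0)
        assert c.category == expected
        assert c.gap == abs(self_r - ideal_r)

    def test_dilemmatic_rule_fires_at_exactly_the_midpoint(self):
        """Sweeping ideal ratings over the whole scale marks the
        construct dilemmatic at one single value: the midpoint."""
        hits = []
        for ideal in range(1, 8):
            g = two_construct_grid([2, ideal, 3, 5], [1, 6, 2, 7])
            if classify_construct(g, 0).category == "dilemmatic":
                hits.append(ideal)
        assert hits == [4]

    def test_custom_gap_bands_respected(self):
        params = DetectionParameters(congruent_gap_max=2, discrepant_gap_min=3)
        g = two_construct_grid([1, 3, 3, 5], [1, 6, 2, 7])
        assert classify_construct(g, 0, params).category == "congruent"
        g = two_construct_grid([2, 5, 3, 5], [1, 6, 2, 7])
        assert classify_construct(g, 0, params).category == "discrepant"


class TestOrientedCorrelation:
    def test_worked_fixture_matches_hand_oracle(self, g1):
        r = oriented_correlation(g1, 0, 1)
        assert r == pytest.approx(G1_EXPECTED_R, abs=1e-12)
        assert r == pytest.approx(0.367, abs=5e-4)

    def test_reflecting_either_row_does_not_change_result(self, g1):
        base = oriented_correlation(g1, 0, 1)
        for k in (0, 1):
            assert oriented_correlation(
                reflect_construct(g1, k), 0, 1
            ) == pytest.approx(base, abs=1e-12)

    def test_identical_oriented_rows_give_unity(self):
        # both reference ratings sit low, so no reflection happens and
        # the two raw rows are literally identical
        g = two_construct_grid([2, 1, 3, 5, 6], [2, 1, 3, 5, 6])
        assert oriented_correlation(g, 0, 1) == pytest.approx(1.0)

    def test_zero_variance_row_raises(self):
        g = two_construct_grid([2, 2, 2, 2, 2], [2, 7, 3, 5, 6])
        with pytest.raises(UndefinedCorrelationError):
            oriented_correlation(g, 0, 1)

    def test_excluding_self_ideal_changes_element_set(self, g1):
        incl = oriented_correlation(g1, 0, 1)
        excl = oriented_correlation(
            g1, 0, 1, DetectionParameters(include_self_ideal_in_correlation=False)
        )
        assert excl == pytest.approx(
            oriented_pearson_bruteforce(
                g1, 0, 1,
                DetectionParameters(include_self_ideal_in_correlation=False),
            ),
            abs=1e-12,
        )
        assert incl != pytest.approx(excl, abs=1e-6)

    def test_agrees_with_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(101)
        checked = 0
        while checked < 200:
            g = random_grid(rng)
            ci, di = 0, 1
            if (
                g.rating(ci, g.ideal_index) == g.scale.midpoint
                or g.rating(di, g.self_index) == g.scale.midpoint
            ):
                continue
            try:
                got = oriented_correlation(g, ci, di)
            except UndefinedCorrelationError:
                continue
            want = oriented_pearson_bruteforce(g, ci, di)
            assert got == pytest.approx(want, abs=1e-12)
            checked += 1


class TestDetectImplicativeDilemmas:
    def test_worked_fixture_yields_single_dilemma_with_fig_layout(self, g1):
        dilemmas = detect_implicative_dilemmas(g1)
        assert len(dilemmas) == 1
        d = dilemmas[0]
        assert d.pair == (0, 1)
        assert d.oriented_r == pytest.approx(G1_EXPECTED_R, abs=1e-12)
        # current position: generous + depressed; change: selfish + happy
        assert d.self_pole_congruent == "generous"
        assert d.undesired_pole_congruent == "selfish"
        assert d.present_pole_discrepant == "depressed"
        assert d.desired_pole_discrepant == "happy"

    def test_pair_exactly_at_threshold_is_not_flagged(self, g1):
        """Strict inequality: r > threshold, never >=."""
        r = oriented_correlation(g1, 0, 1)
        at = DetectionParameters(correlation_threshold=r)
        assert detect_implicative_dilemmas(g1, at) == []
        below = DetectionParameters(correlation_threshold=r - 1e-9)
        assert len(detect_implicative_dilemmas(g1, below)) == 1

    def test_sub_threshold_pair_not_flagged(self):
        # oracle r of this pair is 0.30 exactly over the 6 elements
        g = two_construct_grid([2, 1, 1, 2, 6, 7], [2, 7, 1, 1, 2, 7])
        r = oriented_pearson_bruteforce(g, 0, 1)
        assert r <= 0.35
        assert detect_implicative_dilemmas(g) == []

    def test_no_discrepant_constructs_means_no_dilemmas(self):
        g = make_grid(
            ["s", "i", "a", "b"], "s", "i",
            [("x", "y"), ("u", "v")],
            [[2, 1, 3, 5], [3, 3, 1, 7]],
        )
        assert detect_implicative_dilemmas(g) == []

    def test_zero_variance_pair_skipped_with_warning(self, caplog):
        g = two_construct_grid([2, 2, 2, 2, 2], [2, 7, 3, 5, 6])
        with caplog.at_level(logging.WARNING, logger="gridconflict.detection"):
            assert detect_implicative_dilemmas(g) == []
        assert any("zero rating variance" in m for m in caplog.messages)

    def test_output_sorted_by_descending_r(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            g = random_grid(rng, max_elements=10, max_constructs=8)
            ds = detect_implicative_dilemmas(g)
            rs = [d.oriented_r for d in ds]
            assert rs == sorted(rs, reverse=True)

    def test_lowering_threshold_never_removes_a_dilemma(self):
        rng = np.random.default_rng(44)
        hi = DetectionParameters(correlation_threshold=0.5)
        lo = DetectionParameters(correlation_threshold=0.2)
        for _ in range(40):
            g = random_grid(rng, max_elements=10, max_constructs=8)
            pairs_hi = {d.pair for d in detect_implicative_dilemmas(g, hi)}
            pairs_lo = {d.pair for d in detect_implicative_dilemmas(g, lo)}
            assert pairs_hi <= pairs_lo

    def test_dilemmatic_constructs_never_join_dilemmas(self):
        rng = np.random.default_rng(55)
        for _ in range(40):
            g = random_grid(rng, max_elements=10, max_constructs=8)
            dilemmatic = set(detect_dilemmatic_constructs(g))
            for d in detect_implicative_dilemmas(g):
                assert d.congruent_index not in dilemmatic
                assert d.discrepant_index not in dilemmatic


class TestInvariances:
    def test_reflection_leaves_detection_results_unchanged(self):
        rng = np.random.default_rng(66)
        for _ in range(40):
            g = random_grid(rng, max_elements=10, max_constructs=6)
            base = detect_implicative_dilemmas(g)
            k = int(rng.integers(0, g.n_constructs))
            refl = detect_implicative_dilemmas(reflect_construct(g, k))
            assert [(d.pair, round(d.oriented_r, 12)) for d in base] == [
                (d.pair, round(d.oriented_r, 12)) for d in refl
            ]
            # verbal labels are preserved (reflection is presentational)
            assert [
                (d.self_pole_congruent, d.present_pole_discrepant)
                for d in base
            ] == [
                (d.self_pole_congruent, d.present_pole_discrepant)
                for d in refl
            ]

    def test_permuting_other_elements_permutes_figures_only(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            g = random_grid(rng, max_elements=10, max_constructs=6)
            others = list(g.other_indices)
            perm = rng.permutation(others)
            mapping = dict(zip(others, perm.tolist()))
            order = sorted(range(g.n_elements),
                           key=lambda e: mapping.get(e, e))
            inv = {old: new for new, old in enumerate(order)}
            g2 = Grid(
                tuple(g.elements[e] for e in order),
                g.constructs,
                g.ratings[:, order],
                g.scale,
            )
            base = detect_implicative_dilemmas(g)
            perm_d = detect_implicative_dilemmas(g2)
            assert [(d.pair, round(d.oriented_r, 12)) for d in base] == [
                (d.pair, round(d.oriented_r, 12)) for d in perm_d
            ]
            for d, d2 in zip(base, perm_d):
                f = find_prototypical_figures(g, d)
                f2 = find_prototypical_figures(g2, d2)
                assert sorted(inv[e] for e in f.current_side) == sorted(
                    f2.current_side
                )
                assert sorted(inv[e] for e in f.change_side) == sorted(
                    f2.change_side
                )


class TestDilemmaticConstructs:
    def test_only_midpoint_ideal_rows_detected(self):
        g = make_grid(
            ["s", "i", "a", "b"], "s", "i",
            [("x", "y"), ("u", "v"), ("p", "q")],
            [[2, 4, 3, 5], [3, 1, 1, 7], [5, 4, 2, 6]],
        )
        assert detect_dilemmatic_constructs(g) == [0, 2]

    def test_extreme_ideals_yield_empty_list(self):
        g = make_grid(
            ["s", "i", "a"], "s", "i",
            [("x", "y"), ("u", "v")],
            [[2, 1, 3], [3, 7, 1]],
        )
        assert detect_dilemmatic_constructs(g) == []


class TestPrototypicalFigures:
    def test_worked_fixture_sides(self, g1):
        d = detect_implicative_dilemmas(g1)[0]
        f = find_prototypical_figures(g1, d)
        labels = [e.label for e in g1.elements]
        assert [labels[e] for e in f.current_side] == ["Mother"]
        assert sorted(labels[e] for e in f.change_side) == ["Father", "Friend"]

    def test_agrees_with_bruteforce_enumeration(self, g1):
        """Independent re-derivation: enumerate other elements and test
        the two pole conjunctions directly."""
        d = detect_implicative_dilemmas(g1)[0]
        f = find_prototypical_figures(g1, d)
        scale = g1.scale
        self_pole = pole_of_rating(g1.rating(0, g1.ideal_index), scale)
        present_pole = pole_of_rating(g1.rating(1, g1.self_index), scale)
        current, change = [], []
        for e in g1.other_indices:
            p0 = pole_of_rating(g1.rating(0, e), scale)
            p1 = pole_of_rating(g1.rating(1, e), scale)
            if p0 is self_pole and p1 is present_pole:
                current.append(e)
            elif p0 is self_pole.opposite() and p1 is present_pole.opposite():
                change.append(e)
        assert list(f.current_side) == current
        assert list(f.change_side) == change

    def test_midpoint_rating_excludes_element_from_both_sides(self):
        g = two_construct_grid([2, 1, 2, 4, 6], [2, 7, 1, 2, 6])
        d = detect_implicative_dilemmas(
            g, DetectionParameters(correlation_threshold=0.01)
        )[0]
        f = find_prototypical_figures(g, d)
        # element 3 is at the midpoint on construct 0: on neither side
        assert 3 not in f.current_side and 3 not in f.change_side

    def test_unpolarized_grid_gives_empty_sides(self):
        g = two_construct_grid([2, 1, 4, 4, 4], [2, 7, 4, 4, 3])
        d_list = detect_implicative_dilemmas(
            g, DetectionParameters(correlation_threshold=0.01)
        )
        if d_list:
            f = find_prototypical_figures(g, d_list[0])
            assert f.current_side == () and f.change_side == ()

    def test_self_and_ideal_never_appear(self):
        rng = np.random.default_rng(88)
        for _ in range(30):
            g = random_grid(rng)
            for d in detect_implicative_dilemmas(g):
                f = find_prototypical_figures(g, d)
                members = set(f.current_side) | set(f.change_side)
                assert g.self_index not in members
                assert g.ideal_index not in members
                assert not (set(f.current_side) & set(f.change_side))


class TestDilemmaticPrototypes:
    def grid_with_row(self, row):
        return make_grid(
            ["s", "i", "a", "b", "c"], "s", "i",
            [("x", "y"), ("u", "v")],
            [row, [1, 7, 2, 3, 4]],
        )

    def test_used_range_extremes(self):
        g = self.grid_with_row([4, 4, 2, 3, 6])
        left, right = find_dilemmatic_prototypes(g, 0)
        assert left == (2,)   # element 'a' rated 2
        assert right == (4,)  # element 'c' rated 6

    def test_ties_are_kept(self):
        g = self.grid_with_row([4, 4, 2, 2, 6])
        left, right = find_dilemmatic_prototypes(g, 0)
        assert left == (2, 3)

    def test_all_others_at_midpoint_gives_empty_sides(self):
        g = self.grid_with_row([4, 4, 4, 4, 4])
        assert find_dilemmatic_prototypes(g, 0) == ((), ())

    def test_non_dilemmatic_construct_rejected(self):
        g = self.grid_with_row([4, 4, 2, 3, 6])
        with pytest.raises(GridError):
            find_dilemmatic_prototypes(g, 1)
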