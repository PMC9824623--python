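import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arfusion.ds_engine import MassFunction
from arfusion.fuzzy_regions import (
    FuzzyPartition,
    Proposition,
    RegionGrid,
    RegionThresholds,
    Trapezoid,
    default_grids,
    fit_regions,
    fuzzy_mass,
    membership,
    proposition_mass,
    quantile_partition,
)

INF = float("inf")


def random_partition(rng, n_sets):
    cuts = np.sort(rng.uniform(-10, 10, size=2 * (n_sets - 1)))
    ramps = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_sets - 1)]
    if any(lo == hi for lo, hi in ramps):  # zero-width ramp: nudge
        ramps = [(lo, lo + 1e-6) if lo == hi else (lo, hi) for lo, hi in ramps]
    return FuzzyPartition.from_ramps(ramps)


class TestTrapezoid:
    def test_plateau_and_outside(self):
        t = Trapezoid(0, 1, 2, 3)
        assert membership(t, -0.5) == 0.0
        assert membership(t, 1.0) == 1.0
        assert membership(t, 1.5) == 1.0
        assert membership(t, 3.5) == 0.0

    def test_ramp_midpoint_is_half(self):
        t = Trapezoid(0, 1, 2, 3)
        assert membership(t, 0.5) == pytest.approx(0.5)
        assert membership(t, 2.5) == pytest.approx(0.5)

    def test_triangular_apex(self):
        t = Trapezoid(0, 1, 1, 2)
        assert membership(t, 1.0) == 1.0

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            Trapezoid(1, 0, 2, 3)


class TestPartition:
    @given(st.integers(2, 5), st.integers(0, 2**31 - 1))
    def test_partition_of_unity_everywhere(self, n_sets, seed):
        rng = np.random.default_rng(seed)
        part = random_partition(rng, n_sets)
        for v in rng.uniform(-15, 15, size=200):
            assert abs(part.memberships(v).sum() - 1.0) < 1e-9

    def test_shoulders_cover_infinite_tails(self):
        part = FuzzyPartition.from_ramps([(0.0, 1.0)])
        assert part.memberships(-1e9).tolist() == [1.0, 0.0]
        assert part.memberships(1e9).tolist() == [0.0, 1.0]

    def test_adjacent_sets_must_share_ramps(self):
        with pytest.raises(ValueError):
            FuzzyPartition(
                (Trapezoid(-INF, -INF, 0, 1), Trapezoid(0.5, 1, INF, INF))
            )

    def test_quantile_partition_handles_ties(self):
        part = quantile_partition([1.0] * 50 + [2.0] * 50, n_sets=3)
        assert len(part) == 3
        assert abs(part.memberships(1.5).sum() - 1.0) < 1e-9

    def test_serialization_round_trip(self):
        part = quantile_partition(np.linspace(0, 10, 101), n_sets=3)
        again = FuzzyPartition.from_dict(part.to_dict())
        assert again == part


class TestPropositionLadder:
    @pytest.mark.parametrize(
        "prop,expected",
        [
            (Proposition("P1"), (0, 0, 1)),
            (Proposition("P2", "H1"), (0.33, 0, 0.67)),
            (Proposition("P3", "H1"), (0.67, 0, 0.33)),
            (Proposition("P4", "H1"), (1, 0, 0)),
            (Proposition("P2", "H2"), (0, 0.33, 0.67)),
            (Proposition("P3", "H2"), (0, 0.67, 0.33)),
            (Proposition("P4", "H2"), (0, 1, 0)),
        ],
    )
    def test_seven_rows(self, prop, expected):
        assert proposition_mass(prop).as_tuple() == expected

    def test_p1_takes_no_preference(self):
        with pytest.raises(ValueError):
            Proposition("P1", "H1")

    def test_p2_requires_preference(self):
        with pytest.raises(ValueError):
            Proposition("P2")


def two_region_grid(mass_left, mass_right):
    """1-D helper grid: two x-sets (ramp on [0,1]), one y-set."""
    px = FuzzyPartition.from_ramps([(0.0, 1.0)])
    py = FuzzyPartition.from_ramps([])
    masses = np.array([[mass_left], [mass_right]], dtype=float)
    props = [[Proposition("P1")], [Proposition("P1")]]
    return RegionGrid(px, py, props, masses, np.zeros((2, 1)), np.full((2, 1), 10.0))


class TestFitRegions:
    PX = FuzzyPartition.from_ramps([(0.45, 0.55)])
    PY = FuzzyPartition.from_ramps([])

    def points(self, n_pos, n_neg, x):
        return [(x, 0.0, 1)] * n_pos + [(x, 0.0, 0)] * n_neg

    def test_pure_region_gets_total_confidence(self):
        grid = fit_regions(self.points(10, 0, 0.0), self.PX, self.PY)
        assert str(grid.propositions[0][0]) == "P4(H1)"
        assert grid.masses[0, 0].tolist() == [1.0, 0.0, 0.0]

    def test_even_region_is_ignorance(self):
        grid = fit_regions(self.points(5, 5, 0.0), self.PX, self.PY)
        assert str(grid.propositions[0][0]) == "P1(H1,H2)"

    def test_three_quarters_is_strong_preference(self):
        grid = fit_regions(self.points(15, 5, 0.0), self.PX, self.PY)
        assert str(grid.propositions[0][0]) == "P3(H1,H2)"
        assert grid.masses[0, 0].tolist() == [0.67, 0.0, 0.33]

    def test_low_support_forced_to_ignorance(self):
        grid = fit_regions(self.points(3, 0, 0.0), self.PX, self.PY)
        assert str(grid.propositions[0][0]) == "P1(H1,H2)"

    def test_label_flip_mirrors_propositions(self):
        pts = self.points(15, 5, 0.0) + self.points(2, 18, 1.0)
        flipped = [(x, y, 1 - l) for x, y, l in pts]
        g = fit_regions(pts, self.PX, self.PY)
        gf = fit_regions(flipped, self.PX, self.PY)
        swap = {"H1": "H2", "H2": "H1", None: None}
        for i in range(2):
            p, pf = g.propositions[i][0], gf.propositions[i][0]
            assert pf.level == p.level and pf.preferred == swap[p.preferred]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_regions([], self.PX, self.PY)


class TestFuzzyMass:
    def test_single_region_membership_returns_its_bpa(self):
        grid = two_region_grid((0.33, 0, 0.67), (1, 0, 0))
        assert fuzzy_mass(-5.0, 0.0, grid).as_tuple() == pytest.approx((0.33, 0, 0.67))

    def test_hand_expanded_mixture(self):
        grid = two_region_grid((0.33, 0, 0.67), (1, 0, 0))
        # x = 0.5 -> memberships (0.5, 0.5)
        assert fuzzy_mass(0.5, 0.0, grid).as_tuple() == pytest.approx((0.665, 0, 0.335))

    def test_all_ignorance_grid_everywhere_vacuous(self):
        grid = two_region_grid((0, 0, 1), (0, 0, 1))
        for x in (-3.0, 0.2, 0.8, 9.0):
            assert fuzzy_mass(x, 0.0, grid).as_tuple() == (0, 0, 1)

    @given(st.floats(-20, 20), st.integers(0, 2**31 - 1))
    def test_output_is_valid_bpa(self, x, seed):
        rng = np.random.default_rng(seed)
        left, right = rng.dirichlet([1, 1, 1]), rng.dirichlet([1, 1, 1])
        grid = two_region_grid(tuple(left), tuple(right))
        m = fuzzy_mass(x, 0.0, grid)
        assert isinstance(m, MassFunction)  # validates sum-to-1 and positivity

    def test_continuous_across_region_boundary(self):
        """Crossing a ramp changes the mass gradually, the stated point of
        fuzzification: no jump at the old crisp boundary."""
        grid = two_region_grid((0, 0.67, 0.33), (1, 0, 0))
        xs = np.linspace(-0.2, 1.2, 141)
        scores = np.array([fuzzy_mass(x, 0.0, grid).h1 for x in xs])
        steps = np.abs(np.diff(scores))
        assert steps.max() < 0.02  # bounded by slope * dx, no discontinuity


class TestDefaultGrids:
    def test_region_counts_match_learning_graphs(self):
        grids = default_grids()
        assert grids["sc_p"].region_count == 9
        assert grids["o_d"].region_count == 12
        assert grids["f1_f2"].region_count == 9

    def test_axis_set_counts(self):
        grids = default_grids()
        assert (grids["o_d"].n_x, grids["o_d"].n_y) == (3, 4)

    def test_template_builds_quantile_partitions(self):
        rng = np.random.default_rng(0)
        px, py = default_grids()["o_d"].build(rng.normal(size=100), rng.normal(size=100))
        assert (len(px), len(py)) == (3, 4)


class TestThresholdBands:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.95, "P4(H1)"), (0.75, "P3(H1,H2)"), (0.60, "P2(H1,H2)"),
            (0.50, "P1(H1,H2)"), (0.40, "P2(H2,H1)"), (0.25, "P3(H2,H1)"),
            (0.05, "P4(H2)"),
        ],
    )
    def test_default_bands(self, p, expected):
        thr = RegionThresholds()
        assert str(thr.proposition(p, support=100.0)) == expected

    def test_bands_are_mirror_symmetric(self):
        thr = RegionThresholds()
        swap = {"H1": "H2", "H2": "H1", None: None}
        for p in np.linspace(0.01, 0.99, 97):
            a = thr.proposition(float(p), 100.0)
            b = thr.proposition(float(1 - p), 100.0)
            assert b.level == a.level and b.preferred == swap[a.preferred]
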