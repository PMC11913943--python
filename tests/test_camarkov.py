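"""CA-Markov pipeline: correlation screening, Markov projection, transition
potentials, allocation mechanics and simulation determinism."""

import numpy as np
import pytest

from encroach import camarkov, synthetic
from encroach.camarkov import (
    AllocationError,
    MLPHyperparams,
    SimulationConfig,
    ca_allocate,
    covariate_correlation,
    fit_transition_potential,
    markov_project,
    persistence_baseline,
    simulate,
    validate,
)
from encroach.change import TransitionMatrix, crosstab
from encroach.grids import ClassScheme, Grid
from encroach.synthetic import CovariateStack, moore_fraction
from tests.conftest import make_map

W, G, B = 1, 2, 3
TWO = ClassScheme(codes=(1, 2), names=("a", "b"))


def stack_from(arrays, pixel_size=5.0):
    shape = next(iter(arrays.values())).shape
    origin = (0.0, shape[0] * pixel_size)
    return CovariateStack(
        grids={
            name: Grid(values=np.asarray(v, dtype=float), pixel_size=pixel_size, origin=origin)
            for name, v in arrays.items()
        }
    )


class TestCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.random((40, 40))
        corr = covariate_correlation(stack_from({"x": x, "y": x.copy(), "z": -x}))
        assert corr.loc["x", "y"] == pytest.approx(1.0)
        assert corr.loc["x", "z"] == pytest.approx(-1.0)
        assert np.all(np.diag(corr.to_numpy()) == 1.0)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(1)
        corr = covariate_correlation(
            stack_from({"x": rng.random((100, 100)), "y": rng.random((100, 100))})
        )
        assert abs(corr.loc["x", "y"]) < 0.05

    def test_constant_covariate_missing(self):
        rng = np.random.default_rng(2)
        corr = covariate_correlation(
            stack_from({"x": rng.random((20, 20)), "c": np.full((20, 20), 3.0)})
        )
        assert np.isnan(corr.loc["x", "c"])
        assert corr.loc["c", "c"] == 1.0


class TestMarkovProject:
    def test_identity_matrix_fixes_areas(self):
        m = TransitionMatrix(np.diag([30.0, 70.0]), duration=5.0, scheme=TWO)
        proj = markov_project(m, [30.0, 70.0], steps=4)
        for k in range(5):
            np.testing.assert_allclose(proj.loc[k].to_numpy(), [30.0, 70.0])

    def test_hand_two_step_projection(self):
        entries = np.array([[90.0, 10.0], [0.0, 100.0]])  # P = [[0.9, 0.1], [0, 1]]
        m = TransitionMatrix(entries, duration=5.0, scheme=TWO)
        proj = markov_project(m, [100.0, 0.0], steps=2)
        np.testing.assert_allclose(proj.loc[1].to_numpy(), [90.0, 10.0])
        np.testing.assert_allclose(proj.loc[2].to_numpy(), [81.0, 19.0])

    def test_total_area_conserved(self):
        rng = np.random.default_rng(3)
        m = TransitionMatrix(rng.uniform(0, 10, (3, 3)), duration=5.0,
                             scheme=ClassScheme((1, 2, 3), ("a", "b", "c")))
        proj = markov_project(m, m.row_totals, steps=6)
        totals = proj.sum(axis=1).to_numpy()
        np.testing.assert_allclose(totals, totals[0], atol=1e-6)

    def test_zero_area_row_treated_as_identity(self):
        entries = np.array([[10.0, 5.0], [0.0, 0.0]])
        m = TransitionMatrix(entries, duration=5.0, scheme=TWO)
        proj = markov_project(m, [0.0, 50.0], steps=1)
        assert proj.loc[1, "b"] >= 50.0  # class b persists (identity row)


class TestFitPotential:
    def test_no_change_yields_near_zero_potentials(self, scheme):
        rng = np.random.default_rng(4)
        codes = rng.integers(1, 4, (40, 40))
        m = make_map(codes, scheme)
        stack = stack_from({"dem": rng.random((40, 40)), "twi": rng.random((40, 40))})
        model = fit_transition_potential(m, m, stack, seed=0)
        pots = model.potentials(m, stack)
        for (i, j), g in pots.items():
            assert g.values.max() <= 0.05

    def test_determinism_under_fixed_seed(self, scheme, small_series):
        stack = small_series.covariates
        a, b = small_series.maps[0], small_series.maps[1]
        m1 = fit_transition_potential(a, b, stack, seed=5)
        m2 = fit_transition_potential(a, b, stack, seed=5)
        p1, p2 = m1.potentials(b, stack), m2.potentials(b, stack)
        for key in p1:
            np.testing.assert_array_equal(p1[key].values, p2[key].values)

    def test_potentials_in_unit_interval_and_masked_to_source(self, scheme, small_series):
        stack = small_series.covariates
        model = fit_transition_potential(small_series.maps[0], small_series.maps[1], stack, seed=6)
        pots = model.potentials(small_series.maps[1], stack)
        for (i, j), g in pots.items():
            assert g.values.min() >= 0.0 and g.values.max() <= 1.0
            assert np.all(g.values[small_series.maps[1].grid.values != i] == 0.0)


class TestAllocate:
    def make_potential(self, codes, values, scheme):
        grid = Grid(values=np.asarray(values, dtype=float), pixel_size=5.0,
                    origin=(0.0, np.asarray(values).shape[0] * 5.0))
        return grid

    def test_zero_targets_identity(self, scheme):
        rng = np.random.default_rng(7)
        m = make_map(rng.integers(1, 4, (10, 10)), scheme)
        out = ca_allocate(m, {}, {}, w=1.0, seed=0)
        np.testing.assert_array_equal(out.grid.values, m.grid.values)

    def test_top_two_cells_converted(self, scheme):
        codes = np.full((4, 4), G)
        codes[0, 0] = W
        m = make_map(codes, scheme)
        pot = np.arange(16, dtype=float).reshape(4, 4) / 16.0
        pots = {(G, W): self.make_potential(codes, pot, scheme)}
        out = ca_allocate(m, pots, {(G, W): 2}, w=0.0, seed=1)
        converted = (out.grid.values == W) & (codes == G)
        assert converted.sum() == 2
        assert converted[3, 3] and converted[3, 2]  # the two highest grass potentials

    def test_neighbourhood_weight_pulls_growth_to_cluster(self, scheme):
        rng = np.random.default_rng(8)
        codes = np.full((30, 30), G)
        codes[12:18, 12:18] = W  # a woody cluster
        m = make_map(codes, scheme)
        pot = rng.random((30, 30))
        pots = {(G, W): self.make_potential(codes, pot, scheme)}
        frac = moore_fraction(codes, W)
        means = {}
        for w in (0.0, 2.0):
            out = ca_allocate(m, pots, {(G, W): 40}, w=w, seed=9)
            converted = (out.grid.values == W) & (codes == G)
            means[w] = frac[converted].mean()
        assert means[2.0] > means[0.0]

    def test_realized_counts_exact(self, scheme):
        rng = np.random.default_rng(10)
        codes = rng.integers(1, 4, (20, 20))
        m = make_map(codes, scheme)
        pots = {
            (G, W): self.make_potential(codes, rng.random((20, 20)), scheme),
            (W, G): self.make_potential(codes, rng.random((20, 20)), scheme),
        }
        targets = {(G, W): 17, (W, G): 5}
        out = ca_allocate(m, pots, targets, w=0.0, seed=11)
        assert int(((codes == G) & (out.grid.values == W)).sum()) == 17
        assert int(((codes == W) & (out.grid.values == G)).sum()) == 5

    def test_infeasible_demand_names_transition(self, scheme):
        codes = np.full((3, 3), G)
        m = make_map(codes, scheme)
        pots = {(B, W): self.make_potential(codes, np.ones((3, 3)), scheme)}
        with pytest.raises(AllocationError, match="3->1"):
            ca_allocate(m, pots, {(B, W): 1}, w=0.0, seed=0)


class TestSimulate:
    def test_identity_matrix_freezes_landscape(self, scheme, small_series):
        stack = small_series.covariates
        start = small_series.maps[1]
        model = fit_transition_potential(small_series.maps[0], start, stack, seed=12)
        areas = np.array(list(start.areas_ha().values()))
        identity = TransitionMatrix(np.diag(areas), duration=5.0, scheme=scheme)
        out = simulate(start, model, stack, identity, SimulationConfig(steps=2, seed=13))
        for m in out:
            np.testing.assert_array_equal(m.grid.values, start.grid.values)

    def test_determinism(self, scheme, small_series):
        stack = small_series.covariates
        a, b = small_series.maps[0], small_series.maps[1]
        model = fit_transition_potential(a, b, stack, seed=14)
        matrix = crosstab(a, b, 5.0)
        cfg = SimulationConfig(steps=2, seed=15)
        r1 = simulate(b, model, stack, matrix, cfg)
        r2 = simulate(b, model, stack, matrix, cfg)
        for x, y in zip(r1, r2):
            np.testing.assert_array_equal(x.grid.values, y.grid.values)

    def test_class_counts_match_markov_projection(self, scheme, small_series):
        """Allocation realizes the Markov quantities within one cell per class."""
        stack = small_series.covariates
        a, b = small_series.maps[0], small_series.maps[1]
        model = fit_transition_potential(a, b, stack, seed=16)
        matrix = crosstab(a, b, 5.0)
        out = simulate(b, model, stack, matrix, SimulationConfig(steps=1, seed=17))
        counts_b = np.array([v for v in b.counts().values()], dtype=float)
        P = matrix.entries / matrix.row_totals[:, None]
        expected = counts_b @ P
        realized = np.array([v for v in out[0].counts().values()], dtype=float)
        np.testing.assert_allclose(realized, expected, atol=1.0 * len(counts_b))

    def test_expanding_dynamics_grow_woody_cover(self, scheme, small_series):
        stack = small_series.covariates
        a, b = small_series.maps[0], small_series.maps[1]
        model = fit_transition_potential(a, b, stack, seed=18)
        matrix = crosstab(a, b, 5.0)
        out = simulate(b, model, stack, matrix, SimulationConfig(steps=2, seed=19))
        woody = [b.fractions()["woody vegetation"]] + [
            m.fractions()["woody vegetation"] for m in out
        ]
        assert woody[2] > woody[1] > woody[0]


class TestValidate:
    def test_perfect_simulation(self, scheme):
        rng = np.random.default_rng(20)
        m = make_map(rng.integers(1, 4, (20, 20)), scheme)
        v = validate(m, m)
        assert v["overall_percent_correct"] == 100.0
        assert v["kappa"] == 1.0
        assert v["QADI"] == 0.0

    def test_known_disagreement_rate(self, scheme):
        codes = np.full((20, 20), G)
        sim = codes.copy()
        sim.ravel()[:60] = W  # 15% of 400 cells disagree
        v = validate(make_map(sim, scheme), make_map(codes, scheme))
        assert v["overall_percent_correct"] == pytest.approx(85.0)

    def test_persistence_baseline_equals_validating_start(self, scheme, small_series):
        b, c = small_series.maps[1], small_series.maps[2]
        assert persistence_baseline(b, c) == validate(b, c)
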