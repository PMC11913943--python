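"""Three-level Intensity Analysis: hand arithmetic, identities and an
independent cell-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from encroach import datasets
from encroach.change import TransitionMatrix, crosstab
from encroach.grids import ClassScheme, InvalidInputError
from encroach.intensity import (
    category_level,
    interval_level,
    loss_side_transition_level,
    stationarity,
    transition_level,
)
from tests.conftest import make_map

TWO = ClassScheme(codes=(1, 2), names=("a", "b"))
THREE = ClassScheme(codes=(1, 2, 3), names=("c1", "c2", "c3"))

# Worked 3-class example used across levels: rows = class at t.
HAND = TransitionMatrix(
    entries=np.array([[50.0, 5.0, 0.0], [10.0, 30.0, 5.0], [0.0, 5.0, 10.0]]),
    duration=1.0,
    scheme=THREE,
)


class TestIntervalLevel:
    def test_diagonal_matrix_has_zero_intensity(self):
        m = TransitionMatrix(np.diag([8.0, 9.0]), duration=2.0, scheme=TWO)
        ii = interval_level([m])
        assert ii.s_t.iloc[0] == 0.0

    def test_hand_two_class_example(self):
        m = TransitionMatrix(np.array([[8.0, 2.0], [1.0, 9.0]]), duration=2.0, scheme=TWO)
        ii = interval_level([m])
        assert ii.s_t.iloc[0] == pytest.approx(7.5)  # 3 / (2 * 20) * 100

    def test_reconstructed_first_interval_near_published_rate(self):
        m = datasets.bisley_completed_matrix("2009-2014")
        total = float(datasets.bisley_area_table().loc[2009].sum())
        ii = interval_level([m], total_area=total)
        assert ii.s_t.iloc[0] == pytest.approx(5.20, rel=0.02)

    def test_uniform_is_duration_weighted_mean_of_s_t(self):
        rng = np.random.default_rng(4)
        mats = [
            TransitionMatrix(rng.uniform(1, 20, (2, 2)), duration=d, scheme=TWO)
            for d in (5.0, 5.0, 4.0)
        ]
        # force equal totals so the matrices describe the same landscape
        mats = [
            TransitionMatrix(m.entries / m.total_area * 100.0, duration=m.duration, scheme=TWO)
            for m in mats
        ]
        ii = interval_level(mats)
        durations = np.array(ii.durations)
        assert ii.u == pytest.approx(float((ii.s_t.to_numpy() * durations).sum() / durations.sum()),
                                     abs=1e-9)

    def test_zero_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            TransitionMatrix(np.diag([1.0, 1.0]), duration=0.0, scheme=TWO)


class TestCategoryLevel:
    def test_diagonal_matrix_all_dormant(self):
        m = TransitionMatrix(np.diag([5.0, 5.0, 5.0]), duration=1.0, scheme=THREE)
        ci = category_level(m, u=1.0)
        assert (ci.gain_intensity == 0).all() and (ci.loss_intensity == 0).all()
        assert not ci.active_gainer.any() and not ci.active_loser.any()

    def test_hand_example_gain_and_loss(self):
        ci = category_level(HAND, u=5.0)
        assert ci.gain_intensity["c1"] == pytest.approx(100 * 10 / 60)  # 16.67 %/yr
        assert ci.loss_intensity["c2"] == pytest.approx(100 * 15 / 45)  # 33.33 %/yr

    def test_reconstructed_woody_gain_near_published(self):
        m = datasets.bisley_completed_matrix("2009-2014")
        ci = category_level(m, u=4.45)
        assert ci.gain_intensity["woody vegetation"] == pytest.approx(6.54, rel=0.02)

    def test_absent_class_gain_is_missing_not_zero(self):
        entries = np.array([[5.0, 1.0, 0.0], [1.0, 5.0, 0.0], [1.0, 1.0, 0.0]])
        m = TransitionMatrix(entries, duration=1.0, scheme=THREE)
        ci = category_level(m, u=1.0)
        assert np.isnan(ci.gain_intensity["c3"])
        assert pd.isna(ci.active_gainer["c3"])
        assert not np.isnan(ci.gain_intensity["c1"])

    def test_gains_losses_conservation(self):
        rng = np.random.default_rng(7)
        m = TransitionMatrix(rng.uniform(0, 10, (4, 4)), duration=2.0,
                             scheme=ClassScheme((1, 2, 3, 4), ("a", "b", "c", "d")))
        assert m.gains.sum() == pytest.approx(m.losses.sum())
        assert m.gains.sum() == pytest.approx(m.change_area)


class TestTransitionLevel:
    def test_uniform_offdiagonal_symmetry(self):
        entries = np.full((3, 3), 2.0)
        np.fill_diagonal(entries, 10.0)
        m = TransitionMatrix(entries, duration=1.0, scheme=THREE)
        ti = transition_level(m, "c1")
        np.testing.assert_allclose(ti.intensity.to_numpy(), ti.uniform)
        assert not ti.targets.any()

    def test_hand_example_targeting(self):
        ti = transition_level(HAND, "c1")
        assert ti.intensity["c2"] == pytest.approx(100 * 10 / 45)  # 22.22
        assert ti.uniform == pytest.approx(100 * 10 / 60)          # 16.67
        assert bool(ti.targets["c2"]) is True

    def test_reconstructed_woody_gain_targets_grasses(self):
        m = datasets.bisley_completed_matrix("2009-2014")
        ti = transition_level(m, "woody vegetation")
        assert ti.intensity["grasses"] > ti.uniform

    def test_gain_identity(self):
        """sum_i R_tin * area_i(t) * duration = gain_n * 100."""
        rng = np.random.default_rng(11)
        m = TransitionMatrix(rng.uniform(0.1, 10, (3, 3)), duration=3.0, scheme=THREE)
        for n, name in enumerate(THREE.names):
            ti = transition_level(m, name)
            areas = {nm: a for nm, a in zip(THREE.names, m.row_totals)}
            lhs = sum(ti.intensity[src] * areas[src] for src in ti.intensity.index) * m.duration
            assert lhs == pytest.approx(m.gains[n] * 100.0, abs=1e-9)


class TestLossSide:
    def test_diagonal_is_zero(self):
        m = TransitionMatrix(np.diag([5.0, 5.0, 5.0]), duration=1.0, scheme=THREE)
        ti = loss_side_transition_level(m, "c2")
        assert (ti.intensity == 0).all() and ti.uniform == 0

    def test_hand_example(self):
        ti = loss_side_transition_level(HAND, "c2")
        assert ti.intensity["c1"] == pytest.approx(100 * 10 / 60)   # 16.67
        assert ti.uniform == pytest.approx(100 * 15 / (115 - 40))   # 20.0

    def test_uniform_offdiagonal_symmetry(self):
        entries = np.full((3, 3), 2.0)
        np.fill_diagonal(entries, 10.0)
        m = TransitionMatrix(entries, duration=1.0, scheme=THREE)
        ti = loss_side_transition_level(m, "c1")
        np.testing.assert_allclose(ti.intensity.to_numpy(), ti.uniform)


class TestStationarity:
    def test_identical_matrices_all_stationary(self):
        m = HAND
        reports = [category_level(m, u=5.0) for _ in range(3)]
        table = stationarity([r.active_gainer for r in reports])
        assert table["stationary"].all()

    def test_alternating_flags_not_stationary(self):
        a = pd.Series([True, False], index=["x", "y"], dtype="boolean")
        b = pd.Series([False, False], index=["x", "y"], dtype="boolean")
        table = stationarity([a, b])
        assert not table.loc["x", "stationary"]
        assert table.loc["y", "stationary"] and table.loc["y", "value"] == False  # noqa: E712

    def test_bare_areas_stationary_active_gainer_across_intervals(self):
        """Bare-area gains exceed the uniform rate in every observed interval."""
        mats = datasets.bisley_completed_matrices()
        total = float(datasets.bisley_area_table().loc[2009].sum())
        ii = interval_level(list(mats.values()), total_area=total)
        reports = [category_level(m, ii.u) for m in mats.values()]
        table = stationarity([r.active_gainer for r in reports])
        assert table.loc["bare areas", "stationary"]
        assert table.loc["bare areas", "value"] == True  # noqa: E712

    def test_needs_two_intervals(self):
        with pytest.raises(InvalidInputError):
            stationarity([pd.Series([True], dtype="boolean")])


class TestBruteForceOracle:
    """Intensities computed by direct cell enumeration from synthetic maps
    must match the module's matrix-based formulas."""

    @pytest.fixture()
    def maps_pair(self, scheme):
        rng = np.random.default_rng(23)
        a = make_map(rng.integers(1, 4, (40, 40)), scheme, pixel_size=5.0)
        codes = a.grid.values.copy()
        flip = rng.random(codes.shape) < 0.2
        codes[flip] = rng.integers(1, 4, int(flip.sum()))
        return a, make_map(codes, scheme, pixel_size=5.0)

    def brute(self, a, b, duration):
        """Counting loops over raw cells; no matrix algebra."""
        av, bv = a.grid.values.ravel(), b.grid.values.ravel()
        n = len(av)
        pa = a.grid.pixel_area_ha
        area = n * pa
        changed = sum(1 for x, y in zip(av, bv) if x != y) * pa
        s = changed / (duration * area) * 100
        gain, loss, r = {}, {}, {}
        for code in a.scheme.codes:
            gained = sum(1 for x, y in zip(av, bv) if y == code and x != code) * pa
            lost = sum(1 for x, y in zip(av, bv) if x == code and y != code) * pa
            area_t1 = sum(1 for y in bv if y == code) * pa
            area_t = sum(1 for x in av if x == code) * pa
            gain[code] = (gained / duration) / area_t1 * 100
            loss[code] = (lost / duration) / area_t * 100
            for src in a.scheme.codes:
                if src != code:
                    flow = sum(1 for x, y in zip(av, bv) if x == src and y == code) * pa
                    src_area = sum(1 for x in av if x == src) * pa
                    r[(src, code)] = (flow / duration) / src_area * 100
        return s, gain, loss, r

    def test_all_levels_match(self, maps_pair):
        a, b = maps_pair
        duration = 5.0
        m = crosstab(a, b, duration)
        s, gain, loss, r = self.brute(a, b, duration)
        ii = interval_level([m])
        assert ii.s_t.iloc[0] == pytest.approx(s, abs=1e-9)
        ci = category_level(m, ii.u)
        for code, name in zip(a.scheme.codes, a.scheme.names):
            assert ci.gain_intensity[name] == pytest.approx(gain[code], abs=1e-9)
            assert ci.loss_intensity[name] == pytest.approx(loss[code], abs=1e-9)
        for code, name in zip(a.scheme.codes, a.scheme.names):
            ti = transition_level(m, name)
            for src_code, src_name in zip(a.scheme.codes, a.scheme.names):
                if src_code != code:
                    assert ti.intensity[src_name] == pytest.approx(r[(src_code, code)], abs=1e-9)
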