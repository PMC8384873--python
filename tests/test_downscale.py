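"""Delta methods, CO₂-matched reference times, land masks and infilling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climwindows.downscale import (
    classical_delta,
    dynamic_delta,
    fill_submarine_cells,
    land_mask,
    select_reference_time,
)
from climwindows.fields import GridSpec, climate_field
from climwindows.series import CO2Series, SeaLevelSeries

GRID = GridSpec.regular(0.0, 30.0, 2.5, 0.0, 20.0, 2.0)
FINE = GridSpec.regular(2.0, 28.0, 1.0, 2.0, 18.0, 0.8)


def const(value, grid=GRID, var="precip"):
    return climate_field(np.full(grid.shape, float(value)), grid, var)


class TestReferenceTime:
    CO2 = CO2Series(time_ka=np.array([0.0, 5.0, 14.0, 21.0]),
                    value=np.array([280.0, 240.0, 230.0, 190.0]))

    def test_nearest_co2_value(self):
        # CO2(t)=240 ppm, snapshots at {21: 190, 14: 230, 0: 280} -> 14 ka
        assert select_reference_time(self.CO2, 5.0, [0.0, 14.0, 21.0]) == 14.0

    def test_exact_match(self):
        assert select_reference_time(self.CO2, 14.0, [0.0, 14.0, 21.0]) == 14.0

    def test_tie_breaks_toward_recent(self):
        co2 = CO2Series(time_ka=np.array([0.0, 7.0, 14.0]), value=np.array([250.0, 260.0, 270.0]))
        # CO2(7)=260 is equidistant from 250 (t=0) and 270 (t=14): choose 0
        assert select_reference_time(co2, 7.0, [0.0, 14.0]) == 0.0

    def test_empty_snapshots(self):
        with pytest.raises(ValueError):
            select_reference_time(self.CO2, 5.0, [])


class TestDynamicDelta:
    def test_identity_when_t_equals_that(self):
        rng = np.random.default_rng(0)
        coarse = climate_field(rng.uniform(50, 400, GRID.shape), GRID, "precip")
        fine = climate_field(rng.uniform(50, 400, FINE.shape), FINE, "precip")
        out = dynamic_delta(coarse, coarse, fine, "multiplicative")
        np.testing.assert_allclose(out.values, fine.values, rtol=1e-9)
        fine_t = climate_field(rng.uniform(-5, 30, FINE.shape), FINE, "temp")
        out_t = dynamic_delta(coarse, coarse, fine_t, "additive")
        np.testing.assert_allclose(out_t.values, fine_t.values, rtol=0, atol=1e-9)

    def test_unit_correction_returns_regridded_coarse(self):
        from climwindows.fields import regrid

        rng = np.random.default_rng(1)
        coarse_t = climate_field(rng.uniform(50, 400, GRID.shape), GRID, "precip")
        coarse_that = climate_field(rng.uniform(50, 400, GRID.shape), GRID, "precip")
        fine_that = regrid(coarse_that, FINE)
        out = dynamic_delta(coarse_t, coarse_that, fine_that, "multiplicative")
        np.testing.assert_allclose(out.values, regrid(coarse_t, FINE).values, rtol=1e-9)

    def test_multiplicative_arithmetic(self):
        out = dynamic_delta(const(100), const(50), const(60, FINE), "multiplicative")
        np.testing.assert_allclose(out.values, 120.0, rtol=1e-12)

    def test_additive_arithmetic(self):
        out = dynamic_delta(const(15, var="temp"), const(12, var="temp"),
                            const(10, FINE, "temp"), "additive")
        np.testing.assert_allclose(out.values, 13.0, atol=1e-12)

    def test_multiplicative_nonnegative_and_capped(self):
        # hyperarid reference cell: denominator floored, ratio capped at 100
        out = dynamic_delta(const(100), const(0.0), const(60, FINE), "multiplicative")
        assert np.all(out.values >= 0)
        assert np.all(out.values <= 100 * 100.0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            dynamic_delta(const(1), const(1), const(1, FINE), "geometric")

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dynamic_delta(const(1), const(1, FINE), const(1, FINE), "additive")


class TestClassicalDelta:
    def test_multiplicative_arithmetic(self):
        out = classical_delta(const(80), const(20), const(40, FINE), "multiplicative")
        np.testing.assert_allclose(out.values, 160.0, rtol=1e-12)

    def test_obs_equal_model_returns_model_t(self):
        from climwindows.fields import regrid

        rng = np.random.default_rng(2)
        model_t = climate_field(rng.uniform(50, 400, GRID.shape), GRID, "precip")
        model_0 = climate_field(rng.uniform(50, 400, GRID.shape), GRID, "precip")
        obs = regrid(model_0, FINE)
        out = classical_delta(model_t, model_0, obs, "multiplicative")
        np.testing.assert_allclose(out.values, regrid(model_t, FINE).values, rtol=1e-9)

    def test_model_constant_in_time_returns_obs(self):
        rng = np.random.default_rng(3)
        obs = climate_field(rng.uniform(10, 500, FINE.shape), FINE, "precip")
        out = classical_delta(const(123.0), const(123.0), obs, "multiplicative")
        np.testing.assert_allclose(out.values, obs.values, rtol=1e-9)


class TestLandMask:
    SEA = SeaLevelSeries(time_ka=np.array([0.0, 10.0]), value=np.array([0.0, -50.0]))

    def elev(self, values):
        return climate_field(np.asarray(values, float), (np.zeros(len(values)), np.arange(len(values), dtype=float)), "elevation")

    def test_strict_inequality(self):
        m = land_mask(self.elev([10.0, -10.0, -50.0]), self.SEA, 10.0)  # s = -50
        assert m.values.tolist() == [True, True, False]  # E == s is sea

    def test_present_day(self):
        m = land_mask(self.elev([10.0, -10.0]), self.SEA, 0.0)
        assert m.values.tolist() == [True, False]

    def test_outside_coverage(self):
        with pytest.raises(ValueError):
            land_mask(self.elev([0.0]), self.SEA, 20.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-200, 200), min_size=4, max_size=20),
           st.floats(-120, -1), st.floats(-120, -1))
    def test_nesting(self, elevs, s1, s2):
        """Lower sea level exposes a superset of the land at higher sea level."""
        sea = SeaLevelSeries(time_ka=np.array([0.0, 1.0, 2.0]),
                             value=np.array([0.0, min(s1, s2), max(s1, s2)]))
        e = self.elev(elevs)
        land_low = land_mask(e, sea, 1.0).values   # lower sea level
        land_high = land_mask(e, sea, 2.0).values
        assert np.all(land_high <= land_low)


class TestInfilling:
    def nodes(self, lons, lats, values):
        return climate_field(np.asarray(values, float),
                             (np.asarray(lons, float), np.asarray(lats, float)), "precip")

    def test_constant_donors(self):
        f = self.nodes([0, 1, 0, 1, 0.5], [0, 0, 1, 1, 0.5], [5, 5, 5, 5, 999])
        out = fill_submarine_cells(f, [1, 1, 1, 1, 0], [0, 0, 0, 0, 1])
        assert np.isclose(out.values[-1], 5.0)

    def test_single_donor_copied(self):
        f = self.nodes([0, 3], [0, 0], [42.0, 0.0])
        out = fill_submarine_cells(f, [1, 0], [0, 1], k=4, power=7.0)
        assert np.isclose(out.values[1], 42.0)

    def test_two_equidistant_donors_average(self):
        f = self.nodes([-1.0, 1.0, 0.0], [0, 0, 0], [10.0, 20.0, 0.0])
        out = fill_submarine_cells(f, [1, 1, 0], [0, 0, 1], k=2)
        assert np.isclose(out.values[2], 15.0)

    def test_donors_unchanged(self):
        f = self.nodes([0, 1, 2], [0, 0, 0], [1.0, 2.0, 0.0])
        out = fill_submarine_cells(f, [1, 1, 0], [0, 0, 1])
        assert out.values[0] == 1.0 and out.values[1] == 2.0

    def test_no_donors(self):
        f = self.nodes([0, 1], [0, 0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fill_submarine_cells(f, [0, 0], [1, 1])
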