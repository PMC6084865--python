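"""Grid geometry: boxes, bilinear regridding, cos-weighted averaging, indices."""

import numpy as np
import pandas as pd
import pytest

from paddyclim import anomalies, fields, synthetic
from paddyclim.fields import (
    NINO34_BOX,
    BoundingBox,
    GridSpec,
    area_average,
    make_field,
    monthly_to_seasonal,
    month_index,
    nino34_index,
    regrid_bilinear,
)

from conftest import monthly_series, tiny_config


def grid_field(values, grid, n_months=None, units="1", name="f"):
    n_months = n_months or values.shape[0]
    return make_field(values, grid, month_index(2000, n_months), name, units)


class TestGridAndBox:
    def test_step_must_divide_bounds(self):
        with pytest.raises(ValueError):
            GridSpec(0.0, 10.0, 0.0, 10.0, 3.0)

    def test_cell_centers_offset_half_step(self):
        g = GridSpec(0.0, 4.0, 10.0, 14.0, 2.0)
        assert np.allclose(g.lats, [1.0, 3.0])
        assert np.allclose(g.lons, [11.0, 13.0])

    def test_nino34_membership(self):
        # 170°W–120°W: a cell at 165°E (and at the dateline) lies outside;
        # 130°W = 230°E lies inside.
        assert not NINO34_BOX.contains(0.0, 165.0)
        assert not NINO34_BOX.contains(0.0, 180.0)
        assert NINO34_BOX.contains(0.0, 230.0)
        assert not NINO34_BOX.contains(8.0, 230.0)

    def test_wrap_around_box(self):
        box = BoundingBox(lon_min=350.0, lon_max=10.0, lat_min=-5.0, lat_max=5.0)
        assert box.contains(0.0, 355.0)
        assert box.contains(0.0, 5.0)
        assert not box.contains(0.0, 180.0)

    def test_negative_longitudes_normalized(self):
        box = BoundingBox(lon_min=-170.0, lon_max=-120.0, lat_min=-5.0, lat_max=5.0)
        assert (box.lon_min, box.lon_max) == (190.0, 240.0)

    def test_invalid_latitudes_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 10, 5, -5)


class TestRegridBilinear:
    source = GridSpec(0.0, 10.0, 100.0, 110.0, 1.0)
    target = GridSpec(2.0, 8.0, 102.0, 108.0, 0.5)

    def test_constant_field_preserved(self):
        f = grid_field(np.full((3, 10, 10), 4.2), self.source)
        out = regrid_bilinear(f, self.target)
        assert np.allclose(out.values, 4.2)

    def test_bilinear_function_reproduced(self):
        g = self.source
        lat, lon = np.meshgrid(g.lats, g.lons, indexing="ij")
        f = grid_field((2 * lat + 3 * lon)[None, :, :], g, n_months=1)
        out = regrid_bilinear(f, self.target)
        tlat, tlon = np.meshgrid(self.target.lats, self.target.lons, indexing="ij")
        assert np.allclose(out.values[0], 2 * tlat + 3 * tlon, atol=1e-10)

    def test_midpoint_of_four_corners(self):
        g = GridSpec(0.0, 2.0, 0.0, 2.0, 1.0)  # centers 0.5, 1.5
        f = grid_field(np.array([[[0.0, 1.0], [1.0, 2.0]]]), g, n_months=1)
        mid = f.interp(lat=1.0, lon=1.0, method="linear")
        assert float(mid.values[0]) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        def brute_bilinear(values, xs, ys, x, y):
            i = np.searchsorted(xs, x) - 1
            j = np.searchsorted(ys, y) - 1
            x0, x1 = xs[i], xs[i + 1]
            y0, y1 = ys[j], ys[j + 1]
            wx, wy = (x - x0) / (x1 - x0), (y - y0) / (y1 - y0)
            return (
                values[i, j] * (1 - wx) * (1 - wy)
                + values[i + 1, j] * wx * (1 - wy)
                + values[i, j + 1] * (1 - wx) * wy
                + values[i + 1, j + 1] * wx * wy
            )

        rng = np.random.default_rng(11)
        vals = rng.normal(size=(1, 10, 10))
        f = grid_field(vals, self.source, n_months=1)
        out = regrid_bilinear(f, self.target)
        for ilat, lat in enumerate(self.target.lats):
            for ilon, lon in enumerate(self.target.lons):
                expect = brute_bilinear(
                    vals[0], self.source.lats, self.source.lons, lat, lon
                )
                assert abs(out.values[0, ilat, ilon] - expect) < 1e-10

    def test_extrapolation_rejected(self):
        f = grid_field(np.zeros((1, 10, 10)), self.source, n_months=1)
        with pytest.raises(ValueError):
            regrid_bilinear(f, GridSpec(0.0, 20.0, 100.0, 110.0, 1.0))


class TestAreaAverage:
    def test_uniform_field_any_box(self):
        g = GridSpec(-30.0, 30.0, 0.0, 20.0, 10.0)
        f = grid_field(np.full((2, 6, 2), 7.7), g)
        out = area_average(f, BoundingBox(0, 20, -30, 30))
        assert np.allclose(out.values, 7.7)

    def test_hand_cos_weighting_two_latitudes(self):
        # cells at 0° (value 10) and 60° (value 20): (10·1 + 20·0.5) / 1.5
        g = GridSpec(-5.0, 65.0, 0.0, 10.0, 10.0)
        values = np.zeros((1, 7, 1))
        values[0, 0, 0] = 10.0  # center 0°
        values[0, 6, 0] = 20.0  # center 60°
        f = grid_field(values, g, n_months=1)
        out_low = area_average(f, BoundingBox(0, 10, -2, 2))
        assert float(out_low.iloc[0]) == pytest.approx(10.0)
        box = BoundingBox(0, 10, -2, 62)
        masked = f.where((f.lat == 0.0) | (f.lat == 60.0))
        got = area_average(masked, box)
        assert float(got.iloc[0]) == pytest.approx(
            (10.0 * np.cos(0.0) + 20.0 * np.cos(np.deg2rad(60))) / 1.5
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        g = GridSpec(-20.0, 20.0, 100.0, 140.0, 5.0)
        vals = rng.normal(size=(4, 8, 8))
        f = grid_field(vals, g)
        box = BoundingBox(105, 130, -12, 17)
        got = area_average(f, box).values
        # explicit double loop with cos weights
        expect = []
        for t in range(4):
            num = den = 0.0
            for i, lat in enumerate(g.lats):
                for j, lon in enumerate(g.lons):
                    if box.contains(lat, lon):
                        w = np.cos(np.deg2rad(lat))
                        num += w * vals[t, i, j]
                        den += w
            expect.append(num / den)
        assert np.allclose(got, expect, atol=1e-10)

    def test_missing_cells_excluded_monthwise(self):
        g = GridSpec(0.0, 2.0, 0.0, 2.0, 1.0)
        vals = np.array([[[1.0, 3.0], [1.0, 3.0]], [[np.nan, 3.0], [np.nan, 3.0]]])
        f = grid_field(vals, g)
        out = area_average(f, BoundingBox(0, 2, 0, 2))
        assert out.iloc[0] == pytest.approx(2.0)
        assert out.iloc[1] == pytest.approx(3.0)

    def test_empty_box_rejected(self):
        g = GridSpec(0.0, 10.0, 0.0, 10.0, 1.0)
        f = grid_field(np.zeros((1, 10, 10)), g, n_months=1)
        with pytest.raises(ValueError):
            area_average(f, BoundingBox(200, 210, 50, 60))

    def test_longitude_origin_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(3, 4, 6))
        g1 = GridSpec(0.0, 20.0, 10.0, 40.0, 5.0)
        g2 = GridSpec(0.0, 20.0, 10.0 - 360.0, 40.0 - 360.0, 5.0)
        f1 = grid_field(vals, g1)
        f2 = grid_field(vals, g2)
        box = BoundingBox(12, 35, 2, 18)
        assert np.allclose(
            area_average(f1, box).values, area_average(f2, box).values
        )

    def test_regrid_then_average_stable(self):
        # smooth field: box average changes by < 0.5% after 2x refinement
        g = GridSpec(-20.0, 20.0, 160.0, 260.0, 5.0)
        lat, lon = np.meshgrid(g.lats, g.lons, indexing="ij")
        smooth = 20.0 + np.sin(np.deg2rad(lon)) + np.cos(np.deg2rad(lat * 2))
        f = grid_field(smooth[None], g, n_months=1)
        fine = regrid_bilinear(f, GridSpec(-15.0, 15.0, 170.0, 250.0, 2.5))
        box = BoundingBox(175, 245, -12, 12)
        coarse_avg = float(area_average(f, box).iloc[0])
        fine_avg = float(area_average(fine, box).iloc[0])
        assert abs(fine_avg - coarse_avg) / abs(coarse_avg) < 0.005


class TestNino34Index:
    sst_grid = GridSpec(-10.0, 10.0, 160.0, 280.0, 5.0)

    def _sst(self, anomaly_per_month):
        n = len(anomaly_per_month)
        months = np.arange(n) % 12
        cycle = 27 + np.cos(2 * np.pi * months / 12)
        vals = np.broadcast_to(
            (cycle + anomaly_per_month)[:, None, None], (n, 4, 24)
        ).copy()
        return grid_field(vals, self.sst_grid, units="degC", name="sst")

    def test_pure_seasonal_cycle_gives_zero_index(self):
        sst = self._sst(np.zeros(120))
        idx = nino34_index(sst, base_period=(2000, 2009))
        assert np.allclose(idx.values, 0.0, atol=1e-10)

    def test_uniform_trendless_anomaly_recovered(self):
        # per-year pattern, zero mean, exactly orthogonal to the linear trend
        # and constant within each year (so no leakage into the climatology)
        per_year = np.array([1, -1, -1, 1, 0, 0, 1, -1, -1, 1], dtype=float)
        anom = np.repeat(per_year, 12)
        sst = self._sst(anom)
        idx = nino34_index(sst, base_period=(2000, 2009))
        assert np.allclose(idx.values, anom - anom.mean(), atol=1e-10)

    def test_recovers_generating_enso_index(self):
        # compare on a common footing: the index construction removes the
        # realization's climatology and sample trend by design, so the truth
        # is the generating series pushed through the same anomaly transform
        cfg = tiny_config(seed=5)
        enso = synthetic.gen_enso_index(cfg)
        sst = synthetic.gen_sst(cfg, enso)
        idx = nino34_index(sst, base_period=(cfg.start_year, cfg.start_year + 29))
        truth = anomalies.remove_linear_trend(anomalies.remove_annual_cycle(enso))
        r = np.corrcoef(idx.values, truth.values)[0, 1]
        assert r > 0.95


class TestMonthlyToSeasonal:
    def test_constant_series(self):
        out = monthly_to_seasonal(monthly_series(np.full(36, 3.0)), 6)
        assert np.allclose(out.values, 3.0)
        assert len(out) == 3

    def test_djf_straddles_year_and_labels_final_year(self):
        series = monthly_series(np.arange(36.0), start="2000-01")
        out = monthly_to_seasonal(series, season_start_month=12)
        # first complete DJF: Dec 2000 (11), Jan 2001 (12), Feb 2001 (13)
        assert out.index[0] == 2001
        assert out.iloc[0] == pytest.approx(12.0)

    def test_length_12_is_annual_mean(self):
        series = monthly_series(np.arange(24.0), start="2000-01")
        out = monthly_to_seasonal(series, season_start_month=1, length=12)
        assert np.allclose(out.values, [5.5, 17.5])

    def test_incomplete_seasons_dropped(self):
        # 14 months: exactly one complete DJF; the partial one at the start
        # (no Nov/Dec 1999) must not appear
        series = monthly_series(np.arange(14.0), start="2000-01")
        out = monthly_to_seasonal(series, season_start_month=12)
        assert list(out.index) == [2001]

    def test_no_complete_season_rejected(self):
        with pytest.raises(ValueError):
            monthly_to_seasonal(monthly_series([1.0, 2.0], start="2000-03"), 12)
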