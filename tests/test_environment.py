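import math

import numpy as np
import pandas as pd
import pytest

from seepbef import (
    Grid, annual_npp, export_flux, extract_at_samples, interpolate_to_grid,
    read_ascii_grid, slope, slope_grid, tpi, tpi_grid, tri, tri_grid, write_ascii_grid,
)


class TestGridIO:
    def test_ascii_roundtrip(self, tmp_path, rng):
        g = Grid(rng.normal(1000, 5, size=(6, 4)), cell_size=2.0, x_origin=10.0, y_origin=-5.0)
        write_ascii_grid(g, tmp_path / "g.asc")
        back = read_ascii_grid(tmp_path / "g.asc")
        np.testing.assert_allclose(back.values, g.values, atol=1e-6)
        assert back.cell_size == 2.0 and back.x_origin == 10.0 and back.y_origin == -5.0

    def test_ragged_grid_rejected(self, tmp_path):
        (tmp_path / "bad.asc").write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n4 5\n")
        with pytest.raises(ValueError):
            read_ascii_grid(tmp_path / "bad.asc")

    def test_cell_index_maps_centers(self):
        g = Grid(np.arange(9.0).reshape(3, 3), cell_size=1.0)
        assert g.cell_index(0.5, 2.5) == (0, 0)   # top-left cell center
        assert g.cell_index(2.5, 0.5) == (2, 2)   # bottom-right
        with pytest.raises(IndexError):
            g.cell_index(-0.1, 1.0)


class TestInterpolation:
    def test_single_point_gives_constant_grid(self):
        g = Grid(np.zeros((4, 4)), 1.0)
        pts = pd.DataFrame({"x": [1.3], "y": [2.2], "value": [7.5]})
        out = interpolate_to_grid(pts, g, method="idw")
        assert (out.values == 7.5).all()

    def test_nearest_honors_coincident_point(self):
        g = Grid(np.zeros((4, 4)), 1.0)
        pts = pd.DataFrame({"x": [0.5, 3.5], "y": [3.5, 0.5], "value": [1.0, 9.0]})
        out = interpolate_to_grid(pts, g, method="nearest")
        assert out.values[0, 0] == 1.0 and out.values[3, 3] == 9.0

    def test_idw_midpoint_of_two_points_is_mean(self):
        g = Grid(np.zeros((1, 3)), 1.0)  # centers at x = 0.5, 1.5, 2.5
        pts = pd.DataFrame({"x": [0.5, 2.5], "y": [0.5, 0.5], "value": [1.0, 3.0]})
        out = interpolate_to_grid(pts, g, method="idw")
        assert out.values[0, 1] == pytest.approx(2.0, abs=1e-12)
        assert out.values[0, 0] == pytest.approx(1.0, abs=1e-12)  # exact hit

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError):
            interpolate_to_grid(pd.DataFrame(columns=["x", "y", "value"]),
                                Grid(np.zeros((3, 3)), 1.0))


class TestNPPAndExport:
    def test_annual_sum_conventions(self):
        assert annual_npp(np.zeros(12)) == 0.0
        assert annual_npp(np.full(12, 10.0)) == 120.0
        assert annual_npp(np.full(12, 1.0), convention="mean_times_days") == pytest.approx(365.0)

    def test_wrong_length_or_negative_rejected(self):
        with pytest.raises(ValueError):
            annual_npp(np.ones(11))
        with pytest.raises(ValueError):
            annual_npp(np.r_[np.ones(11), -1.0])
        with pytest.raises(ValueError):
            annual_npp(np.r_[np.ones(11), np.nan])

    def test_export_flux_closed_forms(self):
        npp = 500.0
        assert export_flux(npp, 0.0, prd=0.4, rld=400.0, prr=0.01) == pytest.approx(
            npp * 0.41, rel=1e-12)
        assert export_flux(npp, 400.0, prd=0.4, rld=400.0, prr=0.01) == pytest.approx(
            npp * (0.4 / math.e + 0.01), rel=1e-12)

    def test_export_flux_monotone_in_depth_linear_in_npp(self):
        assert export_flux(500, 2000) < export_flux(500, 500)
        assert export_flux(1000, 700) == pytest.approx(2 * export_flux(500, 700), rel=1e-12)
        with pytest.raises(ValueError):
            export_flux(500, 100, rld=0.0)


def _loop_terrain(values, cell, row, col):
    """Direct-definition oracle for slope / TRI / TPI at an interior cell."""
    z = values
    nb = [z[row + dr, col + dc] for dr in (-1, 0, 1) for dc in (-1, 0, 1)
          if not (dr == 0 and dc == 0)]
    a, b, c = z[row - 1, col - 1], z[row - 1, col], z[row - 1, col + 1]
    d, f = z[row, col - 1], z[row, col + 1]
    g, h, i = z[row + 1, col - 1], z[row + 1, col], z[row + 1, col + 1]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
    s = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
    t_ri = np.mean([abs(z[row, col] - v) for v in nb])
    t_pi = z[row, col] - np.mean(nb)
    return s, t_ri, t_pi


class TestTerrain:
    def test_flat_grid_is_featureless(self):
        g = Grid(np.full((5, 5), 1234.0), 1.0)
        assert (slope_grid(g).values == 0).all()
        assert (tri_grid(g).values == 0).all()
        assert (tpi_grid(g).values == 0).all()

    def test_isolated_peak_definitions(self):
        v = np.ones((3, 3))
        v[1, 1] = 9.0
        g = Grid(v, 1.0)
        assert tpi(g, 1, 1) == pytest.approx(8.0)
        assert tri(g, 1, 1) == pytest.approx(8.0)

    def test_inclined_plane_slope_and_tpi(self):
        grad = 0.3
        x = np.arange(6)
        g = Grid(np.tile(grad * x, (6, 1)), 1.0)
        assert slope(g, 2, 3) == pytest.approx(math.degrees(math.atan(grad)), abs=1e-9)
        assert tpi(g, 2, 3) == pytest.approx(0.0, abs=1e-12)

    def test_interior_cells_match_loop_oracle(self, rng):
        g = Grid(rng.normal(1000, 3, size=(10, 10)), 2.0)
        sg, tg, pg = slope_grid(g), tri_grid(g), tpi_grid(g)
        for row in range(1, 9):
            for col in range(1, 9):
                s, t_ri, t_pi = _loop_terrain(g.values, 2.0, row, col)
                assert sg.values[row, col] == pytest.approx(s, abs=1e-10)
                assert tg.values[row, col] == pytest.approx(t_ri, abs=1e-10)
                assert pg.values[row, col] == pytest.approx(t_pi, abs=1e-10)

    def test_tpi_sums_to_zero_over_periodic_interior(self):
        # (n+2) x (m+2) grid whose interior block is one full period of a
        # zero-mean doubly periodic surface; every neighbour shift of the
        # block is also a full period, so interior TPI must cancel.
        n, m = 8, 12
        ii, jj = np.meshgrid(np.arange(n + 2), np.arange(m + 2), indexing="ij")
        z = np.sin(2 * np.pi * ii / n) + np.cos(2 * np.pi * jj / m)
        g = Grid(z, 1.0)
        interior = tpi_grid(g).values[1:-1, 1:-1]
        assert abs(interior.sum()) <= 1e-9 * max(np.abs(z).sum(), 1.0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            slope_grid(Grid(np.zeros((2, 5)), 1.0))


class TestExtraction:
    def test_cell_center_and_constant_grid(self):
        g = Grid(np.arange(9.0).reshape(3, 3), 1.0)
        coords = pd.DataFrame({"x": [0.5], "y": [2.5]}, index=["sA"])
        out = extract_at_samples({"v": g}, coords)
        assert out.loc["sA", "v"] == 0.0
        const = Grid(np.full((3, 3), 4.2), 1.0)
        assert (extract_at_samples({"v": const}, coords)["v"] == 4.2).all()

    def test_out_of_bounds_names_the_sample(self):
        g = Grid(np.zeros((3, 3)), 1.0)
        coords = pd.DataFrame({"x": [99.0], "y": [0.5]}, index=["lost_core"])
        with pytest.raises(IndexError, match="lost_core"):
            extract_at_samples({"v": g}, coords)
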