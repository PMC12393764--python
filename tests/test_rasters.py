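"""Raster grids, resampling, distances, coastal classification, matrix build."""

import numpy as np
import pandas as pd
import pytest

from sulfurscape.rasters import (CovariateStack, RasterGrid, build_matrix,
                                 classify_site, distance_to_coast, extract_at,
                                 load_stack, read_ascii_grid, resample,
                                 supercover_line, write_ascii_grid,
                                 _haversine_km)


def km_grid(values, cell=5.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, origin=(0.0, values.shape[0] * cell),
                      cell_size=cell, crs_id="local-km")


@pytest.fixture()
def coastal_grid():
    """12x15 km grid, 5 km cells, three western columns are sea."""
    elev = np.full((12, 15), 100.0)
    elev[:, :3] = -10.0
    return km_grid(elev)


class TestAsciiGridIO:
    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        g = RasterGrid(rng.normal(size=(7, 9)), origin=(-4.25, 43.5),
                       cell_size=0.05, crs_id="EPSG:4326", nodata=-1.0)
        p = tmp_path / "g.asc"
        write_ascii_grid(g, p)
        back = read_ascii_grid(p)
        assert back.same_grid(g)
        assert np.array_equal(back.values, g.values)
        assert back.nodata == g.nodata

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 1\n1 2\n")
        with pytest.raises(ValueError, match="georeference"):
            read_ascii_grid(p)


class TestResample:
    def test_identity_on_same_grid(self, coastal_grid):
        out = resample(coastal_grid, coastal_grid)
        assert np.array_equal(out.values, coastal_grid.values)

    def test_constant_layer_stays_constant(self):
        src = km_grid(np.full((4, 4), 7.5), cell=20.0)
        tgt = km_grid(np.zeros((16, 16)), cell=5.0)
        out = resample(src, tgt)
        assert np.allclose(out.values, 7.5)

    def test_bilinear_midpoint_of_two_rows(self):
        src = km_grid([[0.0, 0.0], [10.0, 10.0]], cell=1.0)
        tgt = RasterGrid(np.zeros((1, 2)), origin=(0.0, 1.5), cell_size=1.0,
                         crs_id="local-km")
        out = resample(src, tgt)
        assert np.allclose(out.values, 5.0)

    def test_load_stack_coregisters(self, coastal_grid, tmp_path):
        paths = {}
        for name in ("r.elevation", "r.age"):
            p = tmp_path / f"{name}.asc"
            write_ascii_grid(coastal_grid, p)
            paths[name] = p
        stack = load_stack(paths, coastal_grid)
        assert set(stack.names) == {"r.elevation", "r.age"}
        assert stack["r.age"].same_grid(coastal_grid)


class TestDistanceToCoast:
    def test_sea_cells_zero_and_adjacent_one_step(self, coastal_grid):
        d = distance_to_coast(coastal_grid)
        assert np.all(d.values[:, :3] == 0)
        assert np.allclose(d.values[:, 3], 5.0)

    def test_matches_bruteforce_on_degree_grid(self):
        rng = np.random.default_rng(5)
        elev = rng.normal(200, 250, (30, 30))
        g = RasterGrid(elev, origin=(-5.0, 44.0), cell_size=0.02,
                       crs_id="EPSG:4326")
        d = distance_to_coast(g)
        xs, ys = g.cell_centers()
        sea = elev <= 0
        bf = np.empty_like(elev)
        for i in range(30):
            for j in range(30):
                bf[i, j] = 0.0 if sea[i, j] else _haversine_km(
                    xs[i, j], ys[i, j], xs[sea], ys[sea]).min()
        assert np.allclose(d.values, bf)

    def test_all_land_grid_rejected(self):
        with pytest.raises(ValueError, match="no sea"):
            distance_to_coast(km_grid(np.full((20, 20), 50.0)))


class TestSupercoverLine:
    def test_horizontal_and_vertical(self):
        assert supercover_line(0, 0, 0, 3) == [(0, 0), (0, 1), (0, 2), (0, 3)]
        assert supercover_line(2, 1, 0, 1) == [(2, 1), (1, 1), (0, 1)]

    def test_diagonal_includes_corner_neighbours(self):
        cells = set(supercover_line(0, 0, 2, 2))
        assert {(0, 0), (1, 1), (2, 2), (0, 1), (1, 0), (1, 2), (2, 1)} <= cells

    def test_connected_and_endpoints(self):
        cells = supercover_line(1, 1, 4, 9)
        assert cells[0] == (1, 1) and cells[-1] == (4, 9)
        for (r0, c0), (r1, c1) in zip(cells, cells[1:]):
            assert abs(r1 - r0) + abs(c1 - c0) == 1


class TestClassifySite:
    def make_site(self, grid, row, col):
        x, y = grid.center_of(row, col)
        return {"site_id": "s", "lon": x, "lat": y}

    def test_near_coast_low_transect_is_coastal(self, coastal_grid):
        d = distance_to_coast(coastal_grid)
        site = self.make_site(coastal_grid, 5, 4)  # 10 km out, 100 m elevation
        assert classify_site(site, coastal_grid, d) == "coastal"

    def test_far_site_is_inland_regardless_of_elevation(self, coastal_grid):
        d = distance_to_coast(coastal_grid)
        site = self.make_site(coastal_grid, 5, 13)  # > 50 km
        assert classify_site(site, coastal_grid, d) == "inland"

    def test_ridge_on_transect_blocks_coastal(self, coastal_grid):
        elev = coastal_grid.values.copy()
        elev[:, 4] = 600.0  # ridge between the coast and column 6
        g = km_grid(elev)
        d = distance_to_coast(g)
        site = self.make_site(g, 5, 6)  # 20 km out but behind a 600 m ridge
        assert classify_site(site, g, d) == "inland"
        # the same site without the ridge is coastal
        d0 = distance_to_coast(coastal_grid)
        assert classify_site(site, coastal_grid, d0) == "coastal"

    def test_monotone_in_barrier_threshold(self, coastal_grid):
        elev = coastal_grid.values.copy()
        elev[:, 4] = 600.0
        g = km_grid(elev)
        d = distance_to_coast(g)
        for row in range(0, 12, 3):
            for col in (4, 5, 6):
                site = self.make_site(g, row, col)
                low = classify_site(site, g, d, barrier_m=300.0)
                high = classify_site(site, g, d, barrier_m=1000.0)
                if low == "coastal":
                    assert high == "coastal"


class TestExtractAndMatrix:
    @pytest.fixture()
    def stack(self, coastal_grid):
        col_index = np.tile(np.arange(15.0), (12, 1))
        layers = {"r.elevation": coastal_grid,
                  "r.colidx": coastal_grid.copy_with(col_index)}
        return CovariateStack(layers)

    def sites_df(self, grid, cells):
        rows = []
        for i, (r, c) in enumerate(cells):
            x, y = grid.center_of(r, c)
            rows.append({"site_id": f"s{i}", "lon": x, "lat": y})
        return pd.DataFrame(rows)

    def test_cell_centre_extracts_exact_value(self, stack, coastal_grid):
        sites = self.sites_df(coastal_grid, [(2, 7), (9, 11)])
        vals, logs = extract_at(stack, sites)
        assert vals.loc["s0", "r.colidx"] == 7
        assert vals.loc["s1", "r.colidx"] == 11
        assert not logs

    def test_nodata_cell_reported_absent_with_warning(self, stack, coastal_grid):
        g = stack["r.elevation"]
        g.values[2, 7] = g.nodata
        sites = self.sites_df(coastal_grid, [(2, 7)])
        vals, logs = extract_at(stack, sites)
        assert np.isnan(vals.loc["s0", "r.elevation"])
        assert any("r.elevation" in m for m in logs)

    def test_site_outside_extent_named_in_error(self, stack):
        sites = pd.DataFrame([{"site_id": "far", "lon": 1e4, "lat": 1e4}])
        with pytest.raises(ValueError, match="far"):
            extract_at(stack, sites)

    def test_matrix_shape_and_bit_identical_lookup(self, stack, coastal_grid):
        sites = self.sites_df(coastal_grid, [(3, 5), (8, 10)])
        samples = pd.DataFrame({
            "sample_id": [f"i{k}" for k in range(5)],
            "site_id": ["s0", "s0", "s0", "s1", "s1"],
            "d34S": [10.0, 11.0, 12.0, 5.0, 6.0],
        })
        m = build_matrix(samples, sites, stack)
        assert m.shape == (5, 2 + 2 + 1)  # ids + response + 2 layers
        # columns bit-identical to direct cell lookup
        assert (m.loc[m.site_id == "s0", "r.colidx"] == 5.0).all()
        assert (m.loc[m.site_id == "s1", "r.colidx"] == 10.0).all()

    def test_nodata_site_rows_dropped_with_warning(self, stack, coastal_grid):
        stack["r.colidx"].values[3, 5] = stack["r.colidx"].nodata
        sites = self.sites_df(coastal_grid, [(3, 5), (8, 10)])
        samples = pd.DataFrame({
            "sample_id": ["i0", "i1"], "site_id": ["s0", "s1"],
            "d34S": [10.0, 5.0]})
        with pytest.warns(UserWarning, match="r.colidx"):
            m = build_matrix(samples, sites, stack)
        assert list(m["sample_id"]) == ["i1"]

    def test_zero_usable_rows_rejected(self, stack, coastal_grid):
        sites = self.sites_df(coastal_grid, [(3, 5)])
        samples = pd.DataFrame({"sample_id": ["i0"], "site_id": ["s0"],
                                "d34S": [np.nan]})
        with pytest.raises(ValueError, match="no usable rows"):
            build_matrix(samples, sites, stack)

    def test_full_default_world_matrix_has_21_predictors(self, screened_matrix):
        pred_cols = [c for c in screened_matrix.columns if c.startswith("r.")]
        assert len(pred_cols) == 21
        assert screened_matrix["d34S"].notna().all()
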