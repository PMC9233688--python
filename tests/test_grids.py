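"""Lattice geometry, raster I/O, polygon-cell association and sampling."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

import paleorange as pr
from paleorange.grids import (
    read_ascii_raster,
    read_raster_stack,
    write_ascii_raster,
)


@pytest.fixture
def grid10():
    return pr.GridSpec(n_rows=10, n_cols=10, x_min=0.0, y_min=0.0, cell_size=1.0)


class TestGridSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pr.GridSpec(n_rows=0, n_cols=5, x_min=0, y_min=0, cell_size=1)
        with pytest.raises(ValueError):
            pr.GridSpec(n_rows=5, n_cols=5, x_min=0, y_min=0, cell_size=-1)

    def test_cell_center_formula(self, grid10):
        # row 0 is the northernmost row
        x, y = grid10.cell_center(0, 0)
        assert (x, y) == (0.5, 9.5)
        x, y = grid10.cell_center(9, 9)
        assert (x, y) == (9.5, 0.5)

    def test_cell_of_inverts_cell_center(self, grid10):
        for r in range(10):
            for c in range(10):
                x, y = grid10.cell_center(r, c)
                assert grid10.cell_of(x, y) == (r, c)

    def test_half_open_seam_rule(self, grid10):
        # vertical seam x=3 belongs to the cell on its east side (col 3)
        assert grid10.cell_of(3.0, 0.5)[1] == 3
        # horizontal seam y=7 is the top edge of the cell below it (row 3)
        assert grid10.cell_of(0.5, 7.0)[0] == 3
        # the north/west outer edges are inside, south/east are not
        assert grid10.cell_of(0.0, 10.0) == (0, 0)
        with pytest.raises(ValueError):
            grid10.cell_of(10.0, 5.0)
        with pytest.raises(ValueError):
            grid10.cell_of(5.0, 0.0)


class TestRasterIO:
    def test_round_trip_bit_exact(self, tmp_path, grid10):
        rng = np.random.default_rng(0)
        layer = rng.standard_normal(grid10.shape) * 17.3
        mask = np.zeros(grid10.shape, dtype=bool)
        mask[2, 3] = mask[7, 7] = mask[0, 9] = True
        path = tmp_path / "layer.asc"
        write_ascii_raster(path, grid10, layer, mask)
        g2, layer2, mask2 = read_ascii_raster(path)
        assert g2.matches(grid10)
        np.testing.assert_array_equal(mask2, mask)
        np.testing.assert_array_equal(layer2[~mask2], layer[~mask])
        assert np.isnan(layer2[mask2]).all()

    def test_stack_unifies_nodata_across_layers(self, tmp_path, grid10):
        rng = np.random.default_rng(1)
        a, b = rng.random(grid10.shape), rng.random(grid10.shape)
        mask_a = np.zeros(grid10.shape, dtype=bool)
        mask_a[[0, 4, 9], [0, 4, 9]] = True  # 3 nodata cells in layer 1 only
        write_ascii_raster(tmp_path / "a.asc", grid10, a, mask_a)
        write_ascii_raster(tmp_path / "b.asc", grid10, b)
        stack = read_raster_stack(
            [tmp_path / "a.asc", tmp_path / "b.asc"], ["bio01", "bio02"]
        )
        assert stack.variables == ["bio01", "bio02"]
        assert stack.nodata_mask.sum() == 3
        assert np.isnan(stack.values["bio02"][stack.nodata_mask]).all()

    def test_lattice_mismatch_is_hard_error(self, tmp_path, grid10):
        other = pr.GridSpec(n_rows=10, n_cols=10, x_min=0, y_min=0, cell_size=0.5)
        write_ascii_raster(tmp_path / "a.asc", grid10, np.zeros(grid10.shape))
        write_ascii_raster(tmp_path / "b.asc", other, np.zeros(other.shape))
        with pytest.raises(ValueError, match="lattice mismatch"):
            read_raster_stack([tmp_path / "a.asc", tmp_path / "b.asc"], ["x", "y"])

    def test_unreadable_file_names_path(self):
        with pytest.raises(FileNotFoundError, match="nowhere.asc"):
            read_raster_stack(["nowhere.asc"], ["bio01"])


class TestCellsInPolygons:
    def test_unit_square_covers_four_centers(self, grid10):
        # square spanning the centers of cells (8,0),(8,1),(9,0),(9,1) exactly
        poly = box(0.5, 0.5, 1.5, 1.5)
        member = pr.cells_in_polygons(grid10, [poly])
        assert member.sum() == 4
        assert member[8, 0] and member[8, 1] and member[9, 0] and member[9, 1]

    def test_polygon_missing_all_centers_is_empty(self, grid10):
        member = pr.cells_in_polygons(grid10, [box(0.1, 0.1, 0.4, 0.4)])
        assert member.sum() == 0

    def test_empty_polygon_set(self, grid10):
        assert pr.cells_in_polygons(grid10, []).sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_point_in_polygon(self, seed):
        """Oracle equivalence: exhaustive covers() test of all 2500 centers."""
        grid = pr.GridSpec(n_rows=50, n_cols=50, x_min=0, y_min=0, cell_size=1.0)
        rng = np.random.default_rng(seed)
        pts = rng.uniform(5, 45, size=(7, 2))
        hull = Polygon(pts).convex_hull
        member = pr.cells_in_polygons(grid, [hull])
        for r in range(50):
            for c in range(50):
                x, y = grid.cell_center(r, c)
                assert member[r, c] == hull.covers(Point(x, y))


class TestSampleOccurrences:
    def test_deterministic_under_seed(self, small_world, cold_species_setup):
        _, present, _ = small_world
        _, _, polys, _ = cold_species_setup
        a = pr.sample_occurrences(present, polys, 50, 50, seed=9)
        b = pr.sample_occurrences(present, polys, 50, 50, seed=9)
        assert a.equals(b)

    def test_label_counts_and_cell_membership(self, small_world, cold_species_setup):
        _, present, _ = small_world
        _, occ, polys, table = cold_species_setup
        assert (table.label == 1).sum() == 80
        assert (table.label == 0).sum() == 80
        pres_member = pr.cells_in_polygons(present.grid, polys.presence)
        for _, row in table[table.label == 1].iterrows():
            r, c = present.grid.cell_of(row.x, row.y)
            assert pres_member[r, c]

    def test_exhaustion_uses_every_cell_once(self, small_world, cold_species_setup):
        _, present, _ = small_world
        _, occ, polys, _ = cold_species_setup
        n_eligible = int(occ.sum())
        table = pr.sample_occurrences(present, polys, n_eligible, 10, seed=4)
        pres = table[table.label == 1]
        cells = {present.grid.cell_of(x, y) for x, y in zip(pres.x, pres.y)}
        assert len(cells) == n_eligible  # no duplicates: every cell exactly once

    def test_insufficient_cells_reports_count(self, small_world, cold_species_setup):
        _, present, _ = small_world
        _, occ, polys, _ = cold_species_setup
        n_eligible = int(occ.sum())
        with pytest.raises(ValueError, match=str(n_eligible)):
            pr.sample_occurrences(present, polys, n_eligible + 1, 10, seed=4)

    def test_sample_mean_approaches_zonal_mean(self, small_world, cold_species_setup):
        """Monte-Carlo mean of bio01 over presence rows tracks the zonal mean."""
        _, present, _ = small_world
        _, occ, polys, _ = cold_species_setup
        zonal = present.values["bio01"][occ].mean()
        n_eligible = int(occ.sum())
        full = pr.sample_occurrences(present, polys, n_eligible, 10, seed=5)
        # sampling every eligible cell recovers the zonal mean exactly
        assert full[full.label == 1]["bio01"].mean() == pytest.approx(zonal)
        sigma = present.values["bio01"][occ].std()
        sub = pr.sample_occurrences(present, polys, 40, 10, seed=5)
        delta = abs(sub[sub.label == 1]["bio01"].mean() - zonal)
        assert delta < 4 * sigma / np.sqrt(40)  # ~1/sqrt(n) shrinkage

    def test_with_replacement_mode_allows_duplicates(self, small_world, cold_species_setup):
        _, present, _ = small_world
        _, occ, polys, _ = cold_species_setup
        n_eligible = int(occ.sum())
        table = pr.sample_occurrences(
            present, polys, n_eligible * 2, 10, seed=6, with_replacement=True
        )
        assert (table.label == 1).sum() == n_eligible * 2


class TestExtractAtPoints:
    def test_cell_center_and_identity(self, grid10):
        rng = np.random.default_rng(3)
        layer = rng.random(grid10.shape)
        x, y = grid10.cell_center(4, 7)
        assert pr.extract_at_points(layer, grid10, [(x, y)])[0] == layer[4, 7]
        xs, ys = grid10.all_centers()
        vals = pr.extract_at_points(layer, grid10, list(zip(xs.ravel(), ys.ravel())))
        np.testing.assert_array_equal(vals.reshape(grid10.shape), layer)

    def test_shared_edge_follows_half_open_rule(self, grid10):
        layer = np.arange(100, dtype=float).reshape(10, 10)
        # x=5 is the west edge of column 5
        assert pr.extract_at_points(layer, grid10, [(5.0, 9.5)])[0] == layer[0, 5]

    def test_matches_floor_index_oracle(self, grid10):
        rng = np.random.default_rng(4)
        layer = rng.random(grid10.shape)
        pts = rng.uniform(0.01, 9.99, size=(20, 2))
        vals = pr.extract_at_points(layer, grid10, [tuple(p) for p in pts])
        for (x, y), v in zip(pts, vals):
            r = int(np.floor(grid10.y_max - y))  # cell_size 1, interior points
            c = int(np.floor(x))
            assert v == layer[r, c]

    def test_point_outside_names_index(self, grid10):
        layer = np.zeros(grid10.shape)
        with pytest.raises(ValueError, match="point 1"):
            pr.extract_at_points(layer, grid10, [(0.5, 0.5), (11.0, 0.5)])
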