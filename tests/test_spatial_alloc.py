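"""Voronoi service areas and areal interpolation against geometric oracles."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

import maskgap as mg


def stores_df(xy, counts):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "store_id": [f"S{i}" for i in range(len(xy))],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "avg_daily_customers": np.asarray(counts, dtype=float),
        }
    )


class TestBuildVoronoi:
    def test_single_store_gets_whole_region(self):
        region = box(0, 0, 100, 100)
        surf = mg.build_voronoi(stores_df([[40, 60]], [7.0]), region)
        assert len(surf.cells) == 1
        assert surf.cells[0].equals(region)

    def test_two_symmetric_stores_split_in_half(self):
        region = box(0, 0, 100, 100)
        surf = mg.build_voronoi(stores_df([[25, 50], [75, 50]], [1, 1]), region)
        areas = sorted(c.area for c in surf.cells)
        assert areas[0] == pytest.approx(5000.0, rel=1e-9)
        assert areas[1] == pytest.approx(5000.0, rel=1e-9)

    def test_duplicate_stores_collapse_and_sum(self):
        region = box(0, 0, 10, 10)
        surf = mg.build_voronoi(
            stores_df([[2, 2], [2, 2], [8, 8]], [3.0, 4.0, 5.0]), region
        )
        assert len(surf.cells) == 2
        assert sorted(surf.counts) == [5.0, 7.0]

    def test_zero_stores_error(self):
        with pytest.raises(ValueError):
            mg.build_voronoi(stores_df(np.empty((0, 2)), []), box(0, 0, 1, 1))

    def test_store_outside_region_error(self):
        with pytest.raises(ValueError):
            mg.build_voronoi(stores_df([[5, 5]], [1.0]), box(0, 0, 1, 1))

    def test_nearest_store_oracle(self):
        """Cell membership equals brute-force nearest-neighbor assignment."""
        rng = np.random.default_rng(42)
        region = box(0, 0, 1000, 1000)
        pts = rng.uniform(0, 1000, (20, 2))
        surf = mg.build_voronoi(stores_df(pts, np.ones(20)), region)
        samples = rng.uniform(0, 1000, (1000, 2))
        nearest = np.argmin(
            ((samples[:, None, :] - surf.points[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        for s, k in zip(samples, nearest):
            hits = [i for i, c in enumerate(surf.cells)
                    if shapely.contains_xy(c, s[0], s[1])]
            if hits:  # points exactly on edges may miss; interior must agree
                assert hits == [k]

    def test_cells_tile_region(self):
        rng = np.random.default_rng(3)
        region = box(0, 0, 500, 500)
        pts = rng.uniform(0, 500, (15, 2))
        surf = mg.build_voronoi(stores_df(pts, np.ones(15)), region)
        assert sum(c.area for c in surf.cells) == pytest.approx(
            region.area, rel=1e-6
        )


class TestArealInterpolate:
    def village_frame(self, geoms):
        return pd.DataFrame(
            {"village_id": [f"V{i}" for i in range(len(geoms))], "geometry": geoms}
        )

    def test_identity_overlay(self):
        region = box(0, 0, 10, 10)
        surf = mg.VoronoiSurface(
            cells=[region], counts=np.array([105.0]), points=np.array([[5.0, 5.0]])
        )
        out = mg.areal_interpolate(surf, self.village_frame([region]))
        assert out["Y_frac"].iloc[0] == pytest.approx(105.0)
        assert out["Y"].iloc[0] == 105

    def test_half_cell_gets_half_count(self):
        cell = box(0, 0, 10, 10)
        surf = mg.VoronoiSurface(
            cells=[cell], counts=np.array([100.0]), points=np.array([[2.0, 2.0]])
        )
        out = mg.areal_interpolate(surf, self.village_frame([box(0, 0, 5, 10)]))
        assert out["Y_frac"].iloc[0] == pytest.approx(50.0)

    def test_monte_carlo_oracle(self):
        """Random 4-cell / 6-village fixture against a rasterized estimate."""
        rng = np.random.default_rng(11)
        region = box(0, 0, 100, 100)
        cell_pts = rng.uniform(10, 90, (4, 2))
        counts = rng.uniform(10, 100, 4)
        surf = mg.build_voronoi(stores_df(cell_pts, counts), region)
        vil_pts = rng.uniform(0, 100, (6, 2))
        from maskgap.synthgen import _voronoi_cells

        vgeoms = _voronoi_cells(vil_pts, region)
        out = mg.areal_interpolate(surf, self.village_frame(vgeoms))

        # Monte Carlo: sample points uniformly, assign count density
        S = 1_000_000
        pts = rng.uniform(0, 100, (S, 2))
        cell_idx = np.argmin(
            ((pts[:, None, :] - surf.points[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        vil_idx = np.argmin(
            ((pts[:, None, :] - vil_pts[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        dens = surf.counts / np.array([c.area for c in surf.cells])
        mc = np.zeros(6)
        np.add.at(mc, vil_idx, dens[cell_idx])
        mc *= region.area / S
        assert np.allclose(out["Y_frac"], mc, rtol=0.005, atol=0.3)

    def test_mass_conservation_and_linearity(self):
        rng = np.random.default_rng(5)
        region = box(0, 0, 200, 200)
        surf = mg.build_voronoi(
            stores_df(rng.uniform(0, 200, (8, 2)), rng.uniform(1, 50, 8)), region
        )
        from maskgap.synthgen import _voronoi_cells

        vgeoms = _voronoi_cells(rng.uniform(0, 200, (12, 2)), region)
        out = mg.areal_interpolate(surf, self.village_frame(vgeoms))
        assert out["Y_frac"].sum() == pytest.approx(surf.counts.sum(), rel=1e-9)
        surf2 = mg.VoronoiSurface(surf.cells, 2 * surf.counts, surf.points)
        out2 = mg.areal_interpolate(surf2, self.village_frame(vgeoms))
        assert np.allclose(out2["Y_frac"], 2 * out["Y_frac"], rtol=1e-12)


class TestCountStores:
    def test_no_stores_all_zero(self, grid_villages):
        counts = mg.count_stores_in_village(
            stores_df(np.empty((0, 2)), []), grid_villages
        )
        assert (counts == 0).all()

    def test_partition_sums_to_total(self, grid_villages):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 4, (100, 2))
        counts = mg.count_stores_in_village(stores_df(pts, np.ones(100)), grid_villages)
        assert counts.sum() == 100

    def test_boundary_point_assigned_once(self, grid_villages):
        # store exactly on the shared corner of four cells
        counts = mg.count_stores_in_village(
            stores_df([[1.0, 1.0]], [1.0]), grid_villages
        )
        assert counts.sum() == 1
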