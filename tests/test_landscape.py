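import numpy as np
import pytest
from shapely.geometry import LineString, box

from stepsift.landscape import (
    CUT_NEW,
    CUT_NONE,
    CUT_REGEN,
    ConfigError,
    Cutblock,
    CutblockSet,
    LandscapeConfig,
    LinearNetwork,
    classify_cutblocks,
    edge_distances,
    empty_distance_sentinel,
    generate_landscape,
    lf_density,
    load_landscape,
    save_landscape,
    LANDCOVER_CODES,
)
from stepsift.raster import GridRaster, RasterError, distance_transform


class TestGenerateLandscape:
    def test_determinism_byte_identical(self):
        cfg = LandscapeConfig(width_m=5000, height_m=5000)
        a = generate_landscape(cfg, seed=3)
        b = generate_landscape(cfg, seed=3)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name].values, b.layers[name].values)

    def test_cutblock_cover_near_target(self):
        land = generate_landscape(LandscapeConfig(width_m=20_000, height_m=20_000), seed=4)
        frac = (land.layers["cut_class"].values != CUT_NONE).mean()
        assert abs(frac - 0.2) <= 0.05

    def test_landcover_mixture_converges(self):
        cfg = LandscapeConfig(
            width_m=30_000,
            height_m=30_000,
            cutblock_cover=0.0,
            water_fraction=0.0,
            lf_intensity_km_per_km2=0.1,
        )
        land = generate_landscape(cfg, seed=9)
        lc = land.layers["landcover"].values
        for name, target in cfg.landcover_mixture.items():
            realized = (lc == LANDCOVER_CODES[name]).mean()
            assert abs(realized - target) <= 0.02, name

    def test_zero_lf_intensity_gives_sentinel_and_zero_density(self):
        land = generate_landscape(
            LandscapeConfig(width_m=4000, height_m=4000, lf_intensity_km_per_km2=0.0), seed=2
        )
        sentinel = empty_distance_sentinel(land.grid)
        np.testing.assert_array_equal(land.layers["dist_lf"].values, sentinel)
        assert (land.layers["lf_density"].values == 0).all()

    def test_invalid_mixture_and_extent_rejected(self):
        with pytest.raises(ConfigError, match="sums to"):
            generate_landscape(
                LandscapeConfig(landcover_mixture={"pine": 0.5, "coniferous": 0.6})
            )
        with pytest.raises(ConfigError, match="10 x 10"):
            generate_landscape(LandscapeConfig(width_m=500, height_m=500))


class TestLfDensity:
    def grid(self, n=40, cell=50.0):
        return GridRaster(0, 0, cell, np.zeros((n, n)))

    def test_no_lines_zero_everywhere(self):
        d = lf_density(LinearNetwork(lines=[]), self.grid(), radius_m=500)
        assert (d.values == 0).all()

    def test_full_diameter_line_closed_form(self):
        # a straight line through the window centre contributes length 2r,
        # so the density is 2r / (pi r^2); a half-integer radius (in cells)
        # aligns the discrete window with the exact chord length
        g = self.grid(n=41, cell=50.0)
        y_mid = g.origin_y + g.height / 2 - 25.0  # centre row of cells
        line = LineString([(-10_000, y_mid), (10_000, y_mid)])
        r = 525.0
        d = lf_density(LinearNetwork(lines=[line]), g, radius_m=r)
        expected = (2 * r / 1000.0) / (np.pi * r**2 / 1e6)
        centre = d.values[20, 20]
        assert centre == pytest.approx(expected, rel=0.02)

    def test_matches_monte_carlo_estimate(self):
        g = self.grid(n=30, cell=100.0)
        rng = np.random.default_rng(5)
        lines = [
            LineString(rng.uniform(0, 3000, size=(2, 2)))
            for _ in range(6)
        ]
        net = LinearNetwork(lines=lines)
        r = 700.0
        d = lf_density(net, g, radius_m=r)
        # MC oracle: dense points along each line, count within radius
        X, Y = g.cell_centers()
        for (i, j) in [(5, 5), (15, 20), (25, 8)]:
            cx, cy = X[i, j], Y[i, j]
            total = 0.0
            for ln in lines:
                n = max(int(ln.length / 0.5), 2)
                ts = np.linspace(0, 1, n)
                pts = np.array([ln.interpolate(t, normalized=True).coords[0] for t in ts])
                inside = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= r
                total += inside.mean() * ln.length
            expected = (total / 1000.0) / (np.pi * r**2 / 1e6)
            assert d.values[i, j] == pytest.approx(expected, abs=0.02 * max(expected, 1.0) + 0.02)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        lines = [LineString(rng.uniform(0, 2000, size=(2, 2))) for _ in range(4)]
        g0 = GridRaster(0, 0, 100.0, np.zeros((20, 20)))
        d0 = lf_density(LinearNetwork(lines=lines), g0, radius_m=500)
        shift = 12_345.0
        moved = [LineString(np.asarray(ln.coords) + shift) for ln in lines]
        g1 = GridRaster(shift, shift, 100.0, np.zeros((20, 20)))
        d1 = lf_density(LinearNetwork(lines=moved), g1, radius_m=500)
        np.testing.assert_allclose(d0.values, d1.values, rtol=1e-9)

    def test_tiny_radius_warns(self):
        with pytest.warns(UserWarning, match="window"):
            lf_density(LinearNetwork(lines=[]), self.grid(cell=100.0), radius_m=10.0)


class TestClassifyCutblocks:
    def grid(self):
        return GridRaster(0, 0, 100.0, np.zeros((20, 20)))

    @pytest.mark.parametrize(
        "harvest, expected",
        [(2012, CUT_NEW), (2011, CUT_REGEN), (1996, CUT_REGEN), (1990, CUT_NONE)],
    )
    def test_age_windows(self, harvest, expected):
        cuts = CutblockSet([Cutblock(box(200, 200, 900, 900), harvest)])
        cls, size = classify_cutblocks(cuts, 2020, self.grid())
        assert cls.values[12, 5] == expected
        if expected != CUT_NONE:
            assert size.values[12, 5] == pytest.approx(0.7 * 0.7 * 100)  # ha

    def test_negative_age_rejected(self):
        cuts = CutblockSet([Cutblock(box(0, 0, 500, 500), 2025)])
        with pytest.raises(ValueError, match="after reference"):
            classify_cutblocks(cuts, 2020, self.grid())

    def test_partition_into_three_classes(self):
        rng = np.random.default_rng(3)
        blocks = [
            Cutblock(box(x, y, x + 400, y + 400), int(rng.integers(1985, 2021)))
            for x, y in rng.uniform(0, 1600, size=(12, 2))
        ]
        cls, _ = classify_cutblocks(CutblockSet(blocks), 2020, self.grid())
        assert set(np.unique(cls.values)) <= {CUT_NONE, CUT_NEW, CUT_REGEN}


class TestEdgeDistances:
    def test_forest_cell_next_to_open(self):
        lc = np.full((10, 10), LANDCOVER_CODES["coniferous"])
        lc[:, :5] = LANDCOVER_CODES["non_forest"]
        g = GridRaster(0, 0, 100.0, lc)
        cut = g.like(np.zeros((10, 10)))
        ein, eout = edge_distances(g, cut)
        assert ein.values[3, 5] == pytest.approx(100.0)  # forest beside the edge
        assert eout.values[3, 5] == 0.0
        assert eout.values[3, 4] == pytest.approx(100.0)
        # exclusivity: at most one of the pair is nonzero anywhere
        assert (np.minimum(ein.values, eout.values) == 0).all()

    def test_open_cell_matches_distance_transform_oracle(self):
        rng = np.random.default_rng(6)
        lc = np.where(
            rng.random((30, 30)) < 0.5,
            LANDCOVER_CODES["coniferous"],
            LANDCOVER_CODES["non_forest"],
        )
        g = GridRaster(0, 0, 100.0, lc)
        ein, eout = edge_distances(g, g.like(np.zeros((30, 30))))
        forest = lc != LANDCOVER_CODES["non_forest"]
        oracle = distance_transform(g.like(forest)).values
        np.testing.assert_allclose(eout.values[~forest], oracle[~forest])

    def test_uniform_landscape_rejected(self):
        lc = np.full((8, 8), LANDCOVER_CODES["pine"])
        g = GridRaster(0, 0, 100.0, lc)
        with pytest.raises(RasterError, match="edge undefined"):
            edge_distances(g, g.like(np.zeros((8, 8))))

    def test_cutblock_cells_count_as_open(self):
        lc = np.full((10, 10), LANDCOVER_CODES["pine"])
        g = GridRaster(0, 0, 100.0, lc)
        cut = np.zeros((10, 10))
        cut[4:6, 4:6] = CUT_NEW
        ein, eout = edge_distances(g, g.like(cut))
        assert eout.values[4, 4] > 0 or ein.values[4, 4] == 0


class TestLandscapeIO:
    def test_save_load_roundtrip(self, tmp_path):
        land = generate_landscape(LandscapeConfig(width_m=3000, height_m=3000), seed=1)
        save_landscape(land, tmp_path / "land")
        back = load_landscape(tmp_path / "land")
        for name in land.layers:
            np.testing.assert_allclose(
                back.layers[name].values, land.layers[name].values, rtol=1e-9
            )
        assert back.cut_size_mean == pytest.approx(land.cut_size_mean)
        assert len(back.network.lines) == len(land.network.lines)
        assert len(back.cutblocks) == len(land.cutblocks)
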