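"""Synthetic landscape generation and covariate derivation.

Builds the raster covariate stack consumed by the step-selection and
kill-site analyses: patchy land cover, cutblocks of two age classes
(new = 0-8 years since harvest, regenerating = 9-24 years), a linear-feature
network (roads/trails/seismic lines), NDVI, water, and the derived distance,
density and edge layers — all on one aligned grid.  The generator emulates a
heavily logged sub-boreal landscape: large salvage cutblocks connected by a
dense network of linear features.

Land-cover codes: 0 = non-forest, 1 = pine, 2 = deciduous, 3 = mixed forest,
4 = coniferous.  Cutblock cells are re-coded to non-forest (cleared), so the
land-cover dummies of the analyses treat cutblocks as the reference class.
Cut classes: 0 = outside cutblock, 1 = new, 2 = regenerating; cutblocks older
than 24 years fall back to 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box, mapping, shape
import shapely

from .raster import GridRaster, RasterError, distance_transform, read_ascii_grid, write_ascii_grid

LANDCOVER_CODES = {
    "non_forest": 0,
    "pine": 1,
    "deciduous": 2,
    "mixed_forest": 3,
    "coniferous": 4,
}
FOREST_CODES = (1, 2, 3, 4)
CUT_NONE, CUT_NEW, CUT_REGEN = 0, 1, 2

#: cutblock age windows (years since harvest), inclusive
NEW_CUT_AGES = (0, 8)
REGEN_CUT_AGES = (9, 24)

LAYER_NAMES = (
    "landcover",
    "cut_class",
    "cut_size",
    "ndvi",
    "dist_water",
    "dist_lf",
    "lf_density",
    "edge_in",
    "edge_out",
)

#: offset (m) added before log-transforming distances, keeps ln finite at 0
LOG_DISTANCE_OFFSET = 1.0


class ConfigError(ValueError):
    """Invalid landscape or experiment configuration."""


@dataclass
class LinearNetwork:
    """Polyline network of linear features in projected metres."""

    lines: list  # list of shapely LineString
    classes: list = field(default_factory=list)  # per-line tag

    def __post_init__(self):
        for ln in self.lines:
            if len(ln.coords) < 2:
                raise ValueError("polyline needs at least 2 vertices")
            if not np.isfinite(np.asarray(ln.coords)).all():
                raise ValueError("polyline has non-finite coordinates")
        if not self.classes:
            self.classes = ["linear_feature"] * len(self.lines)

    @property
    def total_length_m(self) -> float:
        return float(sum(ln.length for ln in self.lines))


@dataclass
class Cutblock:
    polygon: Polygon
    harvest_year: int

    @property
    def area_ha(self) -> float:
        return self.polygon.area / 1e4

    def __post_init__(self):
        if self.polygon.area <= 0:
            raise ValueError("cutblock polygon must have positive area")
        if not self.polygon.is_simple:
            raise ValueError("cutblock polygon must be simple")


@dataclass
class CutblockSet:
    blocks: list

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)


@dataclass
class LandscapeConfig:
    """Configuration for :func:`generate_landscape`.

    Defaults describe a 30 x 30 km landscape at 100 m resolution with ~20%
    cutblock cover of large (lognormal, median ~50 ha) salvage blocks cut over
    the last 30 years, a linear-feature network of ~0.6 km/km^2, and patchy
    conifer-dominated forest.
    """

    width_m: float = 30_000.0
    height_m: float = 30_000.0
    cell_size: float = 100.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    landcover_mixture: dict = field(
        default_factory=lambda: {
            "non_forest": 0.15,
            "pine": 0.20,
            "deciduous": 0.10,
            "mixed_forest": 0.15,
            "coniferous": 0.40,
        }
    )
    cutblock_cover: float = 0.20
    cutblock_median_ha: float = 50.0
    cutblock_sigma_log: float = 0.6
    harvest_year_span: int = 30  # years before reference year
    reference_year: int = 2020
    lf_intensity_km_per_km2: float = 0.6
    water_fraction: float = 0.03
    ndvi_range: tuple = (0.15, 0.85)
    ndvi_new_cut_drop: float = 0.25
    patch_smooth_cells: float = 6.0
    density_radius_m: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        n_cols = int(round(self.width_m / self.cell_size))
        n_rows = int(round(self.height_m / self.cell_size))
        if n_cols < 10 or n_rows < 10:
            raise ConfigError("extent must cover at least 10 x 10 cells")
        total = sum(self.landcover_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"landcover mixture sums to {total}, expected 1")
        unknown = set(self.landcover_mixture) - set(LANDCOVER_CODES)
        if unknown:
            raise ConfigError(f"unknown landcover classes: {sorted(unknown)}")


@dataclass
class LandscapeStack:
    """Aligned raster layers of every habitat covariate.

    ``layers`` maps each name in :data:`LAYER_NAMES` to a :class:`GridRaster`
    on one shared grid.  ``cut_size_mean``/``cut_size_std`` hold the
    standardisation constants (ha) for the cut-size covariate, computed over
    cutblock cells.
    """

    layers: dict
    network: LinearNetwork | None = None
    cutblocks: CutblockSet | None = None
    cut_size_mean: float = 0.0
    cut_size_std: float = 1.0
    _cov: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        missing = set(LAYER_NAMES) - set(self.layers)
        if missing:
            raise ValueError(f"missing layers: {sorted(missing)}")
        ref = self.grid
        for name, layer in self.layers.items():
            if not ref.same_grid(layer):
                raise ValueError(f"layer {name!r} not on the shared grid")
        for name in ("dist_water", "dist_lf", "lf_density", "edge_in", "edge_out"):
            if np.any(self.layers[name].values < 0):
                raise ValueError(f"layer {name!r} has negative values")

    @property
    def grid(self) -> GridRaster:
        return self.layers["landcover"]

    @property
    def bounds(self):
        return self.grid.bounds

    def covariate_arrays(self) -> dict:
        """Per-cell arrays of every model covariate, derived lazily.

        Distances enter as ln(d + 1 m); cut size as a z-score over cutblock
        cells; land-cover and cut-class layers as 0/1 dummies against their
        reference categories (non-forest, outside-cutblock).
        """
        if self._cov is None:
            lc = self.layers["landcover"].values
            cc = self.layers["cut_class"].values
            size_ha = self.layers["cut_size"].values
            std = self.cut_size_std if self.cut_size_std > 0 else 1.0
            size_z = np.where(size_ha > 0, (size_ha - self.cut_size_mean) / std, 0.0)
            nc = (cc == CUT_NEW).astype(float)
            rc = (cc == CUT_REGEN).astype(float)
            self._cov = {
                "pine": (lc == LANDCOVER_CODES["pine"]).astype(float),
                "deciduous": (lc == LANDCOVER_CODES["deciduous"]).astype(float),
                "mixed_forest": (lc == LANDCOVER_CODES["mixed_forest"]).astype(float),
                "coniferous": (lc == LANDCOVER_CODES["coniferous"]).astype(float),
                "ln_water": np.log(self.layers["dist_water"].values + LOG_DISTANCE_OFFSET),
                "ndvi": self.layers["ndvi"].values.astype(float),
                "ln_edge_in": np.log(self.layers["edge_in"].values + LOG_DISTANCE_OFFSET),
                "ln_edge_out": np.log(self.layers["edge_out"].values + LOG_DISTANCE_OFFSET),
                "lf_density": self.layers["lf_density"].values.astype(float),
                "ln_dist_lf": np.log(self.layers["dist_lf"].values + LOG_DISTANCE_OFFSET),
                "nc": nc,
                "rc": rc,
                "cut_size": size_z,
                "nc_cut_size": nc * size_z,
                "rc_cut_size": rc * size_z,
            }
        return self._cov

    def covariates_at(self, x, y, names=None) -> dict:
        """Covariate values at point coordinates (vectorised)."""
        arrays = self.covariate_arrays()
        row, col = self.grid.cell_of(x, y)
        names = arrays.keys() if names is None else names
        return {name: arrays[name][row, col] for name in names}


# ---------------------------------------------------------------------------
# field helpers

def _gaussian_field(n_rows, n_cols, smooth_cells, rng):
    noise = rng.standard_normal((n_rows, n_cols))
    f = ndimage.gaussian_filter(noise, smooth_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def _classify_by_quantiles(fieldvals, mixture):
    """Partition a continuous field into classes at its quantiles."""
    names = [n for n in LANDCOVER_CODES if mixture.get(n, 0) > 0]
    props = np.array([mixture[n] for n in names])
    edges = np.quantile(fieldvals, np.cumsum(props)[:-1])
    idx = np.searchsorted(edges, fieldvals, side="right")
    out = np.zeros(fieldvals.shape, dtype=int)
    for i, n in enumerate(names):
        out[idx == i] = LANDCOVER_CODES[n]
    return out


def empty_distance_sentinel(grid: GridRaster) -> float:
    """Distance sentinel when a source layer is empty: half the diagonal."""
    return 0.5 * float(np.hypot(grid.width, grid.height))


# ---------------------------------------------------------------------------
# operations

def rasterize_lines(network: LinearNetwork, grid: GridRaster) -> GridRaster:
    """Line length (m) per cell, by dense point sampling along each line."""
    length = np.zeros((grid.n_rows, grid.n_cols))
    step = grid.cell_size / 4.0
    xmin, ymin, xmax, ymax = grid.bounds
    for line in network.lines:
        n = max(int(np.ceil(line.length / step)), 1)
        ds = np.linspace(0, line.length, n + 1)
        mids = 0.5 * (ds[1:] + ds[:-1])
        pts = shapely.line_interpolate_point(line, mids)
        x = shapely.get_x(pts)
        y = shapely.get_y(pts)
        inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
        if not inside.any():
            continue
        row, col = grid.cell_of(x[inside], y[inside])
        seg = np.diff(ds)[inside]
        np.add.at(length, (row, col), seg)
    return grid.like(length)


def lf_density(network: LinearNetwork, grid: GridRaster, radius_m: float = 1000.0) -> GridRaster:
    """Linear-feature density (km/km^2) in a circular moving window.

    Per cell: total line length inside the window of radius ``radius_m``
    centred on the cell centre, divided by the window area.  Outside-landscape
    parts of the window count as zero length but full area.
    """
    if radius_m <= 0:
        raise ConfigError("density window radius must be > 0")
    if radius_m < grid.cell_size / 2:
        warnings.warn("density window smaller than half a cell; may miss all lines")
    length = rasterize_lines(network, grid).values
    r_cells = radius_m / grid.cell_size
    n = int(np.ceil(r_cells))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    kernel = (dx**2 + dy**2) <= r_cells**2
    total = ndimage.convolve(length, kernel.astype(float), mode="constant", cval=0.0)
    area_km2 = np.pi * radius_m**2 / 1e6
    return grid.like((total / 1000.0) / area_km2)


def classify_cutblocks(cuts: CutblockSet, reference_year: int, grid: GridRaster):
    """Rasterise cutblocks into age-class and size layers.

    Age = reference year - harvest year; 0-8 -> new, 9-24 -> regenerating,
    older -> outside-cutblock.  ``cut_size`` carries the block's area (ha) on
    its cells.  Where blocks overlap, the most recent harvest wins.
    """
    cut_class = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    cut_size = np.zeros((grid.n_rows, grid.n_cols))
    cx, cy = grid.cell_centers()
    for blk in sorted(cuts, key=lambda b: b.harvest_year):
        age = reference_year - blk.harvest_year
        if age < 0:
            raise ValueError(f"cutblock harvested in {blk.harvest_year}, after reference year {reference_year}")
        if NEW_CUT_AGES[0] <= age <= NEW_CUT_AGES[1]:
            code = CUT_NEW
        elif REGEN_CUT_AGES[0] <= age <= REGEN_CUT_AGES[1]:
            code = CUT_REGEN
        else:
            code = CUT_NONE
        xmin, ymin, xmax, ymax = blk.polygon.bounds
        sel = (cx >= xmin) & (cx <= xmax) & (cy >= ymin) & (cy <= ymax)
        if not sel.any():
            continue
        inside = shapely.contains_xy(blk.polygon, cx[sel], cy[sel])
        rows, cols = np.nonzero(sel)
        rows, cols = rows[inside], cols[inside]
        cut_class[rows, cols] = code
        cut_size[rows, cols] = blk.area_ha if code != CUT_NONE else 0.0
    return grid.like(cut_class), grid.like(cut_size)


def edge_distances(landcover: GridRaster, cut_class: GridRaster):
    """Distance (m) to the forest/open edge, split by which side a cell is on.

    Forest = {pine, deciduous, mixed, coniferous} outside cutblocks; open =
    non-forest or any cutblock cell (cutblocks are cleared forest).
    ``edge_in`` is the distance to the nearest open cell for forested cells
    (0 on open cells); ``edge_out`` the converse.
    """
    lc = landcover.values
    forest = np.isin(lc, FOREST_CODES) & (cut_class.values == CUT_NONE)
    if forest.all() or not forest.any():
        raise RasterError("uniform landscape: forest/open edge undefined")
    edge_in = np.where(forest, distance_transform(landcover.like(~forest)).values, 0.0)
    edge_out = np.where(~forest, distance_transform(landcover.like(forest)).values, 0.0)
    return landcover.like(edge_in), landcover.like(edge_out)


def _sample_cutblocks(cfg: LandscapeConfig, grid: GridRaster, rng) -> CutblockSet:
    """Place rectangular blocks until the target active-cut cover is reached."""
    target_cells = cfg.cutblock_cover * grid.n_rows * grid.n_cols
    covered = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    xmin, ymin, xmax, ymax = grid.bounds
    blocks = []
    max_age = REGEN_CUT_AGES[1]
    for _ in range(100_000):
        if covered.sum() >= target_cells:
            break
        area_m2 = rng.lognormal(np.log(cfg.cutblock_median_ha * 1e4), cfg.cutblock_sigma_log)
        aspect = rng.uniform(0.5, 2.0)
        w = np.sqrt(area_m2 * aspect)
        h = area_m2 / w
        cx0 = rng.uniform(xmin, xmax)
        cy0 = rng.uniform(ymin, ymax)
        poly = box(cx0 - w / 2, cy0 - h / 2, cx0 + w / 2, cy0 + h / 2).intersection(
            box(xmin, ymin, xmax, ymax)
        )
        if poly.is_empty or poly.area <= 0:
            continue
        year = int(rng.integers(cfg.reference_year - cfg.harvest_year_span, cfg.reference_year + 1))
        blocks.append(Cutblock(polygon=poly, harvest_year=year))
        if cfg.reference_year - year <= max_age:
            # cells whose centre falls inside the (rectangular) block
            bxmin, bymin, bxmax, bymax = poly.bounds
            c0 = int(np.ceil((bxmin - xmin) / grid.cell_size - 0.5))
            c1 = int(np.floor((bxmax - xmin) / grid.cell_size - 0.5))
            rlo = int(np.ceil((bymin - ymin) / grid.cell_size - 0.5))
            rhi = int(np.floor((bymax - ymin) / grid.cell_size - 0.5))
            r0 = grid.n_rows - 1 - rhi
            r1 = grid.n_rows - 1 - rlo
            covered[max(r0, 0) : min(r1, grid.n_rows - 1) + 1, max(c0, 0) : min(c1, grid.n_cols - 1) + 1] = True
    return CutblockSet(blocks)


def _sample_network(cfg: LandscapeConfig, grid: GridRaster, rng) -> LinearNetwork:
    """Poisson chord process hitting a target total length."""
    xmin, ymin, xmax, ymax = grid.bounds
    area_km2 = grid.width * grid.height / 1e6
    target_m = cfg.lf_intensity_km_per_km2 * area_km2 * 1000.0
    extent = box(xmin, ymin, xmax, ymax)
    diag = np.hypot(grid.width, grid.height)
    lines, total = [], 0.0
    while total < target_m:
        px = rng.uniform(xmin, xmax)
        py = rng.uniform(ymin, ymax)
        theta = rng.uniform(0, np.pi)
        dx, dy = np.cos(theta) * diag, np.sin(theta) * diag
        chord = LineString([(px - dx, py - dy), (px + dx, py + dy)]).intersection(extent)
        if chord.is_empty or chord.length == 0:
            continue
        lines.append(chord)
        total += chord.length
    return LinearNetwork(lines=lines)


def generate_landscape(config: LandscapeConfig | None = None, **overrides) -> LandscapeStack:
    """Generate a complete, reproducible synthetic landscape stack.

    Identical (config, seed) produce byte-identical layers.  Keyword
    overrides update a default :class:`LandscapeConfig`.
    """
    cfg = config if config is not None else LandscapeConfig()
    if overrides:
        cfg = LandscapeConfig(**{**asdict(cfg), **overrides})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_cols = int(round(cfg.width_m / cfg.cell_size))
    n_rows = int(round(cfg.height_m / cfg.cell_size))
    grid = GridRaster(cfg.origin_x, cfg.origin_y, cfg.cell_size, np.zeros((n_rows, n_cols)))
    sentinel = empty_distance_sentinel(grid)

    lc_field = _gaussian_field(n_rows, n_cols, cfg.patch_smooth_cells, rng)
    landcover = _classify_by_quantiles(lc_field, cfg.landcover_mixture)

    # water bodies: top quantile of a second smooth field
    if cfg.water_fraction > 0:
        w_field = _gaussian_field(n_rows, n_cols, cfg.patch_smooth_cells * 1.5, rng)
        water = w_field > np.quantile(w_field, 1 - cfg.water_fraction)
        landcover[water] = LANDCOVER_CODES["non_forest"]
        dist_water = distance_transform(grid.like(water)).values
    else:
        dist_water = np.full((n_rows, n_cols), sentinel)

    cuts = _sample_cutblocks(cfg, grid, rng)
    cut_class_r, cut_size_r = classify_cutblocks(cuts, cfg.reference_year, grid)
    landcover[cut_class_r.values != CUT_NONE] = LANDCOVER_CODES["non_forest"]
    landcover_r = grid.like(landcover)

    network = _sample_network(cfg, grid, rng)
    if network.lines:
        lf_len = rasterize_lines(network, grid)
        dist_lf = distance_transform(grid.like(lf_len.values > 0)).values
        density = lf_density(network, grid, cfg.density_radius_m)
    else:
        dist_lf = np.full((n_rows, n_cols), sentinel)
        density = grid.like(np.zeros((n_rows, n_cols)))

    lo, hi = cfg.ndvi_range
    n_field = _gaussian_field(n_rows, n_cols, cfg.patch_smooth_cells, rng)
    u = (n_field - n_field.min()) / (n_field.max() - n_field.min())
    ndvi = lo + (hi - lo) * u
    ndvi[cut_class_r.values == CUT_NEW] -= cfg.ndvi_new_cut_drop
    ndvi = np.clip(ndvi, -1.0, 1.0)

    edge_in, edge_out = edge_distances(landcover_r, cut_class_r)

    layers = {
        "landcover": landcover_r,
        "cut_class": cut_class_r,
        "cut_size": cut_size_r,
        "ndvi": grid.like(ndvi),
        "dist_water": grid.like(dist_water),
        "dist_lf": grid.like(dist_lf),
        "lf_density": density,
        "edge_in": edge_in,
        "edge_out": edge_out,
    }
    sizes = cut_size_r.values[cut_size_r.values > 0]
    mean = float(sizes.mean()) if sizes.size else 0.0
    std = float(sizes.std()) if sizes.size and sizes.std() > 0 else 1.0
    return LandscapeStack(
        layers=layers, network=network, cutblocks=cuts, cut_size_mean=mean, cut_size_std=std
    )


# ---------------------------------------------------------------------------
# I/O: ASCII grids + GeoJSON + YAML manifest

def save_landscape(stack: LandscapeStack, directory) -> None:
    """Write every layer as an ESRI ASCII grid plus a YAML manifest.

    Vectors (linear network, cutblocks) go to GeoJSON when present.
    """
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "layers": {},
        "cut_size_mean": stack.cut_size_mean,
        "cut_size_std": stack.cut_size_std,
        "landcover_codes": dict(LANDCOVER_CODES),
    }
    for name, layer in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(layer, d / fname)
        manifest["layers"][name] = fname
    if stack.network is not None:
        feats = [
            {"type": "Feature", "properties": {"class": c}, "geometry": mapping(ln)}
            for ln, c in zip(stack.network.lines, stack.network.classes)
        ]
        (d / "linear_features.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )
        manifest["linear_features"] = "linear_features.geojson"
    if stack.cutblocks is not None:
        feats = [
            {
                "type": "Feature",
                "properties": {"harvest_year": b.harvest_year},
                "geometry": mapping(b.polygon),
            }
            for b in stack.cutblocks
        ]
        (d / "cutblocks.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )
        manifest["cutblocks"] = "cutblocks.geojson"
    (d / "manifest.yml").write_text(yaml.safe_dump(manifest))


def load_landscape(manifest_path) -> LandscapeStack:
    """Load a landscape stack from a YAML manifest written by save_landscape."""
    from pathlib import Path

    p = Path(manifest_path)
    if p.is_dir():
        p = p / "manifest.yml"
    manifest = yaml.safe_load(p.read_text())
    d = p.parent
    layers = {name: read_ascii_grid(d / fname) for name, fname in manifest["layers"].items()}
    layers["landcover"].values = layers["landcover"].values.astype(int)
    layers["cut_class"].values = layers["cut_class"].values.astype(int)
    network = cutblocks = None
    if "linear_features" in manifest:
        fc = json.loads((d / manifest["linear_features"]).read_text())
        network = LinearNetwork(
            lines=[shape(f["geometry"]) for f in fc["features"]],
            classes=[f["properties"].get("class", "linear_feature") for f in fc["features"]],
        )
    if "cutblocks" in manifest:
        fc = json.loads((d / manifest["cutblocks"]).read_text())
        cutblocks = CutblockSet(
            [
                Cutblock(polygon=shape(f["geometry"]), harvest_year=int(f["properties"]["harvest_year"]))
                for f in fc["features"]
            ]
        )
    return LandscapeStack(
        layers=layers,
        network=network,
        cutblocks=cutblocks,
        cut_size_mean=manifest.get("cut_size_mean", 0.0),
        cut_size_std=manifest.get("cut_size_std", 1.0),
    )
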