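import numpy as np
import pandas as pd
import pytest

from stepsift import LandscapeConfig, generate_landscape
from stepsift.landscape import LANDCOVER_CODES, LandscapeStack
from stepsift.raster import GridRaster


@pytest.fixture(scope="session")
def small_land():
    """A 120 x 120-cell landscape shared by read-only tests."""
    return generate_landscape(LandscapeConfig(width_m=12_000, height_m=12_000), seed=11)


@pytest.fixture(scope="session")
def study_land():
    """A full-size (30 x 30 km) landscape for tests that need study scale."""
    return generate_landscape(seed=5)


def build_stack(
    n=60,
    cell=100.0,
    landcover=None,
    cut_class=None,
    cut_size=None,
    ndvi=0.5,
    dist_water=500.0,
    dist_lf=200.0,
    lf_density=0.5,
    edge_in=0.0,
    edge_out=300.0,
):
    """Hand-built landscape stack with controllable layers (tests only)."""

    def layer(v):
        arr = np.full((n, n), v, dtype=float) if np.isscalar(v) else np.asarray(v, dtype=float)
        return GridRaster(0.0, 0.0, cell, arr)

    if landcover is None:
        landcover = np.full((n, n), LANDCOVER_CODES["coniferous"])
    if cut_class is None:
        cut_class = np.zeros((n, n))
    if cut_size is None:
        cut_size = np.zeros((n, n))
    layers = {
        "landcover": layer(landcover),
        "cut_class": layer(cut_class),
        "cut_size": layer(cut_size),
        "ndvi": layer(ndvi),
        "dist_water": layer(dist_water),
        "dist_lf": layer(dist_lf),
        "lf_density": layer(lf_density),
        "edge_in": layer(edge_in),
        "edge_out": layer(edge_out),
    }
    sizes = layers["cut_size"].values[layers["cut_size"].values > 0]
    mean = float(sizes.mean()) if sizes.size else 0.0
    std = float(sizes.std()) if sizes.size and sizes.std() > 0 else 1.0
    return LandscapeStack(layers=layers, cut_size_mean=mean, cut_size_std=std)


def make_clogit_data(n_strata=50, n_avail=10, beta=(0.8,), seed=0, n_cov=None):
    """Synthetic matched-strata data with known selection coefficients.

    Covariates are iid standard normal; within each stratum the used row is
    drawn with probability proportional to exp(beta' x) among the
    ``n_avail + 1`` candidate rows, so the conditional-logit likelihood is
    exactly well-specified.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = beta.size if n_cov is None else n_cov
    rows = []
    for s in range(n_strata):
        X = rng.standard_normal((n_avail + 1, p))
        eta = X[:, : beta.size] @ beta
        w = np.exp(eta - eta.max())
        used = rng.choice(n_avail + 1, p=w / w.sum())
        for j in range(n_avail + 1):
            rows.append({"stratum": s, "case": int(j == used), **{f"x{k}": X[j, k] for k in range(p)}})
    return pd.DataFrame(rows)


def hourly_fixes(xy, start="2019-05-01 00:00", animal_id="W01", pack_id="P1"):
    """Fix frame from a coordinate sequence at a 60-min cadence."""
    xy = np.asarray(xy, dtype=float)
    t = pd.date_range(start, periods=len(xy), freq="1h")
    return pd.DataFrame(
        {"animal_id": animal_id, "pack_id": pack_id, "t": t, "x": xy[:, 0], "y": xy[:, 1]}
    )
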