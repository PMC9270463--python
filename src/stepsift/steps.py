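"""From raw GPS fixes to matched used/available strata.

The observation model: hourly GPS fixes per animal become *steps* (straight
segments between successive relocations).  Each observed (used) step is
matched with random available steps sharing its start point and time, drawn
from the tentative movement kernel; the stratum of one used plus ten
available steps is the conditioning unit of the likelihood.

Seasons follow the snow calendar: winter = October 1 - March 31, summer =
April 1 - September 30.  Fix filtering removes post-capture disturbance
(first 48 h), den/rendezvous neighbourhoods (1 km), and animals with 7 days
of data or less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import SL_FLOOR_KM, MovementKernel, fit_tentative_kernel
from .landscape import LandscapeStack
from .models import START_EXTRACTED

logger = logging.getLogger(__name__)

SUMMER_MONTHS = (4, 5, 6, 7, 8, 9)  # April 1 - September 30


def season_of(timestamps) -> np.ndarray:
    """Season tag per timestamp: 'summer' (Apr-Sep) or 'winter' (Oct-Mar)."""
    months = pd.DatetimeIndex(timestamps).month
    return np.where(np.isin(months, SUMMER_MONTHS), "summer", "winter")


def sin_hour(hour):
    """Dawn/dusk activity harmonic: sin(4*pi*(hour - 6) / 24).

    Peaks (+1) at 09:00 and 21:00, troughs (-1) at 03:00 and 15:00, zero at
    06:00 — two activity peaks per day.
    """
    h = np.asarray(hour, dtype=float)
    if np.any((h < 0) | (h >= 24)):
        raise ValueError("hour must lie in [0, 24)")
    out = np.sin(4.0 * np.pi * (h - 6.0) / 24.0)
    return float(out) if np.isscalar(hour) else out


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(a, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def preprocess_fixes(
    fixes: pd.DataFrame,
    capture_times: dict | None = None,
    den_sites=None,
    min_days: float = 7.0,
    post_capture_hours: float = 48.0,
    den_radius_m: float = 1000.0,
) -> pd.DataFrame:
    """Filter raw fixes and tag seasons.

    Removes fixes within ``post_capture_hours`` of the animal's capture,
    fixes within ``den_radius_m`` of any den/rendezvous site, and drops
    animals whose remaining data span ``min_days`` days or less (strictly
    more than ``min_days`` is required).  Animals ending up with zero fixes
    are dropped with a logged reason, never an error.

    ``den_sites`` is an iterable of (x, y) or a mapping animal_id -> iterable.
    """
    fixes = fixes.copy()
    fixes["t"] = pd.to_datetime(fixes["t"])
    out = []
    for animal, grp in fixes.groupby("animal_id", sort=False):
        grp = grp.sort_values("t")
        if capture_times and animal in capture_times:
            cutoff = pd.Timestamp(capture_times[animal]) + pd.Timedelta(hours=post_capture_hours)
            grp = grp[grp["t"] >= cutoff]
        dens = den_sites.get(animal, []) if isinstance(den_sites, dict) else (den_sites or [])
        for dx, dy in dens:
            d = np.hypot(grp["x"] - dx, grp["y"] - dy)
            grp = grp[d >= den_radius_m]
        if grp.empty:
            logger.info("animal %s: no fixes left after filtering; dropped", animal)
            continue
        span_days = (grp["t"].iloc[-1] - grp["t"].iloc[0]) / pd.Timedelta(days=1)
        if span_days <= min_days:
            logger.info("animal %s: only %.1f days of data; dropped", animal, span_days)
            continue
        out.append(grp)
    if not out:
        return fixes.iloc[0:0].assign(season=pd.Series(dtype=str))
    result = pd.concat(out, ignore_index=True)
    result["season"] = season_of(result["t"])
    return result


def steps_from_fixes(
    fixes: pd.DataFrame,
    fix_interval_min: float = 60.0,
    tolerance_min: float = 10.0,
    utc_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Build used steps from per-animal fix sequences.

    Consecutive fixes at the nominal interval (+/- tolerance) form a step;
    the turn angle needs the previous step's heading, so steps following a
    gap (or the first step of a burst) are excluded.  Steps whose start and
    end fall in different seasons are dropped.  ``hour`` is local clock time
    at the step start (``utc_offset_hours`` shifts stored UTC stamps).
    """
    rows = []
    stratum = 0
    for animal, grp in fixes.sort_values(["animal_id", "t"]).groupby("animal_id", sort=False):
        if len(grp) < 3:
            logger.info("animal %s: fewer than 3 fixes; no steps", animal)
            continue
        t = grp["t"].to_numpy()
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        dt_min = np.diff(t) / np.timedelta64(1, "m")
        ok = np.abs(dt_min - fix_interval_min) <= tolerance_min
        dx, dy = np.diff(x), np.diff(y)
        heading = np.arctan2(dy, dx)
        sl_km = np.hypot(dx, dy) / 1000.0
        # step i (fix i -> i+1) usable if both it and step i-1 are on-interval
        for i in range(1, len(dt_min)):
            if not (ok[i] and ok[i - 1]):
                continue
            t0 = pd.Timestamp(t[i])
            local = (t0.hour + t0.minute / 60.0 + t0.second / 3600.0 + utc_offset_hours) % 24.0
            s_start = "summer" if t0.month in SUMMER_MONTHS else "winter"
            s_end = "summer" if pd.Timestamp(t[i + 1]).month in SUMMER_MONTHS else "winter"
            if s_start != s_end:
                continue
            rows.append(
                {
                    "stratum": stratum,
                    "case": 1,
                    "animal_id": animal,
                    "season": s_start,
                    "t_start": t0,
                    "x_start": x[i],
                    "y_start": y[i],
                    "x_end": x[i + 1],
                    "y_end": y[i + 1],
                    "heading_prev": heading[i - 1],
                    "sl_km": sl_km[i],
                    "ln_sl": np.log(max(sl_km[i], SL_FLOOR_KM)),
                    "ta": float(wrap_angle(heading[i] - heading[i - 1])),
                    "hour": local,
                    "sin_hour": sin_hour(local),
                }
            )
            stratum += 1
    return pd.DataFrame(rows)


def sample_available_steps(
    used_steps: pd.DataFrame,
    kernel: MovementKernel,
    bounds,
    n_available: int = 10,
    seed: int | np.random.Generator = 0,
    max_rounds: int = 1000,
) -> pd.DataFrame:
    """Match every used step with random available steps from the kernel.

    Available steps share the used step's start point and time; their length
    is gamma-distributed and their heading is the previous heading plus a
    von Mises turn.  Endpoints falling outside ``bounds`` (xmin, ymin, xmax,
    ymax) are resampled; exhausting ``max_rounds`` raises.

    Returns the long frame of strata: one used plus ``n_available`` available
    rows per stratum, ordered by stratum.
    """
    if n_available < 1:
        raise ValueError("n_available must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(used_steps)
    xs = used_steps["x_start"].to_numpy(float)[:, None]
    ys = used_steps["y_start"].to_numpy(float)[:, None]
    h0 = used_steps["heading_prev"].to_numpy(float)[:, None]
    xmin, ymin, xmax, ymax = bounds

    sl = np.empty((n, n_available))
    ta = np.empty((n, n_available))
    xe = np.empty((n, n_available))
    ye = np.empty((n, n_available))
    todo = np.ones((n, n_available), dtype=bool)
    for _ in range(max_rounds):
        m = int(todo.sum())
        if m == 0:
            break
        s, a = kernel.sample_steps(m, rng)
        sl[todo] = s
        ta[todo] = a
        heading = np.broadcast_to(h0, (n, n_available))[todo] + a
        px = np.broadcast_to(xs, (n, n_available))[todo] + s * 1000.0 * np.cos(heading)
        py = np.broadcast_to(ys, (n, n_available))[todo] + s * 1000.0 * np.sin(heading)
        xe[todo] = px
        ye[todo] = py
        inside = (px >= xmin) & (px < xmax) & (py >= ymin) & (py < ymax)
        idx = np.flatnonzero(todo.ravel())
        still = np.zeros(n * n_available, dtype=bool)
        still[idx[~inside]] = True
        todo = still.reshape(n, n_available)
    else:
        raise RuntimeError("exhausted resampling rounds; available endpoints keep leaving the landscape")

    avail = used_steps.loc[used_steps.index.repeat(n_available)].copy()
    avail["case"] = 0
    avail["sl_km"] = sl.ravel()
    avail["ln_sl"] = np.log(np.maximum(sl.ravel(), SL_FLOOR_KM))
    avail["ta"] = wrap_angle(ta.ravel())
    avail["x_end"] = xe.ravel()
    avail["y_end"] = ye.ravel()
    out = pd.concat([used_steps, avail], ignore_index=True)
    return out.sort_values(["stratum", "case"], ascending=[True, False], kind="stable").reset_index(
        drop=True
    )


def extract_covariates(
    steps: pd.DataFrame,
    landscape: LandscapeStack,
    start_terms=START_EXTRACTED,
) -> pd.DataFrame:
    """Attach habitat covariates to a step frame.

    Main-effect covariates are read at the step end; every covariate that
    enters a ln(SL) interaction is additionally read at the step start
    (columns suffixed ``__start``).  Strata whose used endpoint leaves the
    landscape are dropped (logged), matching the nodata policy.
    """
    steps = steps.copy()
    grid = landscape.grid
    inside = grid.contains(steps["x_end"].to_numpy(), steps["y_end"].to_numpy())
    bad = steps.loc[~inside & (steps["case"] == 1), "stratum"].unique()
    if len(bad):
        logger.info("dropping %d strata with out-of-landscape used endpoints", len(bad))
        steps = steps[~steps["stratum"].isin(bad)]
    inside = grid.contains(steps["x_end"].to_numpy(), steps["y_end"].to_numpy())
    if not inside.all():
        raise ValueError("available step endpoints outside the landscape; resample them first")

    end_vals = landscape.covariates_at(steps["x_end"].to_numpy(), steps["y_end"].to_numpy())
    for name, vals in end_vals.items():
        steps[name] = vals
    start_vals = landscape.covariates_at(
        steps["x_start"].to_numpy(), steps["y_start"].to_numpy(), names=start_terms
    )
    for name, vals in start_vals.items():
        steps[f"{name}__start"] = vals
    return steps


def prepare_strata(
    fixes: pd.DataFrame,
    landscape: LandscapeStack,
    n_available: int = 10,
    seed: int | np.random.Generator = 0,
    season: str | None = None,
    kernel: MovementKernel | None = None,
    fix_interval_min: float = 60.0,
    tolerance_min: float = 10.0,
):
    """Full observation pipeline: fixes -> strata with covariates.

    Fits the population-level tentative kernel on the pooled used steps of
    the requested season (unless one is supplied), samples the available
    steps and extracts covariates.

    Returns ``(strata_frame, kernel)``.
    """
    used = steps_from_fixes(fixes, fix_interval_min=fix_interval_min, tolerance_min=tolerance_min)
    if season is not None:
        used = used[used["season"] == season].reset_index(drop=True)
    if used.empty:
        raise ValueError("no usable steps")
    if kernel is None:
        kernel = fit_tentative_kernel(used["sl_km"].to_numpy(), used["ta"].to_numpy())
    strata = sample_available_steps(
        used, kernel, landscape.bounds, n_available=n_available, seed=seed
    )
    strata = extract_covariates(strata, landscape)
    return strata, kernel
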