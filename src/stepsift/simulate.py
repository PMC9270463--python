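"""Generative step-selection simulator with planted kill clusters.

Trajectories are simulated from the same model family the estimator fits:
at each step a finite set of candidate steps is drawn from the movement
kernel (gamma step length, von Mises turn angle) and one is chosen with
probability proportional to exp(beta' x), where x is built with exactly the
estimator's covariate-extraction rules (main effects at the step end,
ln(SL)-interaction covariates at the step start).  The finite candidate set
(default 200) is a discrete approximation of the continuous redistribution
kernel.

Kill events pause the trajectory: the fixes of the dwell period are
scattered around the carcass, producing the spatiotemporal clusters the
kill-site detector must find.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import SL_FLOOR_KM, MovementKernel
from .landscape import LandscapeStack
from .models import global_spec
from .steps import sin_hour

#: tentative/true kernel used by the default presets: mean step 0.585 km/h,
#: mild directional persistence
DEFAULT_KERNEL = MovementKernel(shape=1.3, scale_km=0.45, kappa=0.4)


class SimulationError(RuntimeError):
    pass


def _fold(v, lo, hi):
    """Mirror coordinates into [lo, hi) (reflecting boundary)."""
    period = 2.0 * (hi - lo)
    r = np.mod(np.asarray(v, dtype=float) - lo, period)
    out = lo + np.where(r > (hi - lo), period - r, r)
    return np.minimum(out, hi - 1e-9)


@dataclass
class SelectionParams:
    """Named selection coefficients over the global covariate set."""

    beta: dict

    def __post_init__(self):
        allowed = set(global_spec().terms)
        unknown = set(self.beta) - allowed
        if unknown:
            raise ValueError(f"unresolvable coefficient names: {sorted(unknown)}")
        if not all(np.isfinite(v) for v in self.beta.values()):
            raise ValueError("coefficients must be finite")

    def get(self, term: str) -> float:
        return float(self.beta.get(term, 0.0))


def default_selection_params() -> SelectionParams:
    """The realistic truth preset: published summer population medians.

    The full global-model coefficient vector of the summer wolf analysis
    this package re-implements — selection near linear features and water,
    for edge habitat, high NDVI and new cutblocks, with modest
    movement-rate interactions.  Using the published medians verbatim makes
    the recovery experiments a test under the study's own effect sizes.
    """
    return SelectionParams(
        beta={
            "pine": 0.081,
            "deciduous": 0.145,
            "mixed_forest": 0.131,
            "coniferous": 0.152,
            "ln_water": -0.069,
            "ndvi": 1.217,
            "ln_edge_in": -0.127,
            "ln_edge_out": -0.146,
            "lf_density": -0.086,
            "ln_dist_lf": -0.08,
            "nc": 0.183,
            "rc": -0.211,
            "nc_cut_size": -0.174,
            "rc_cut_size": -0.176,
            "ln_sl": 0.381,
            "ln_sl:sin_hour": 0.067,
            "ln_sl:nc": -0.046,
            "ln_sl:rc": -0.044,
            "ln_sl:nc_cut_size": 0.054,
            "ln_sl:rc_cut_size": 0.009,
            "ln_sl:lf_density": -0.033,
            "ln_sl:ln_dist_lf": -0.051,
        }
    )


def strong_selection_params() -> SelectionParams:
    """A strong-effects truth for model-discrimination experiments.

    Every covariate block carries effects large enough that omitting it
    costs clearly more likelihood than its parameters buy back; used when
    the question is whether AIC selection identifies the full (global)
    structure, not whether realistic effect sizes are recoverable.
    """
    return SelectionParams(
        beta={
            "pine": 0.2,
            "deciduous": 0.2,
            "mixed_forest": 0.2,
            "coniferous": 0.5,
            "ln_water": -0.15,
            "ndvi": 1.5,
            "ln_edge_in": -0.2,
            "ln_edge_out": -0.25,
            "lf_density": -0.3,
            "ln_dist_lf": -0.4,
            "nc": 0.8,
            "rc": 0.6,
            "nc_cut_size": -0.4,
            "rc_cut_size": -0.3,
            "ln_sl": 0.0,
            "ln_sl:sin_hour": 0.07,
            "ln_sl:nc": -0.15,
            "ln_sl:rc": -0.12,
            "ln_sl:nc_cut_size": 0.10,
            "ln_sl:rc_cut_size": 0.08,
            "ln_sl:lf_density": -0.06,
            "ln_sl:ln_dist_lf": -0.08,
        }
    )


@dataclass
class Trajectory:
    """Ordered fixes of one collared animal."""

    animal_id: str
    pack_id: str
    fixes: pd.DataFrame  # columns t, x, y
    fix_interval_min: float = 60.0

    def __post_init__(self):
        t = pd.DatetimeIndex(self.fixes["t"])
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    def as_fix_frame(self) -> pd.DataFrame:
        df = self.fixes.copy()
        df.insert(0, "animal_id", self.animal_id)
        df.insert(1, "pack_id", self.pack_id)
        return df


@dataclass
class KillTruth:
    """Ground-truth kill events planted on a trajectory."""

    events: pd.DataFrame  # columns x, y, t_start, dwell_hours, prey

    def __len__(self):
        return len(self.events)


def _split_params(params: SelectionParams):
    """Split coefficients into end-habitat terms and the ln(SL) channel."""
    end_terms = []
    start_terms = []
    for term, b in params.beta.items():
        if b == 0.0:
            continue
        if term == "ln_sl" or term == "ln_sl:sin_hour":
            continue
        if term.startswith("ln_sl:"):
            start_terms.append((term[len("ln_sl:") :], b))
        else:
            end_terms.append((term, b))
    return end_terms, start_terms


def simulate_trajectory(
    landscape: LandscapeStack,
    kernel: MovementKernel,
    params: SelectionParams,
    start: tuple,
    n_steps: int,
    n_candidates: int = 200,
    seed: int | np.random.Generator = 0,
    start_time="2019-04-02 00:00",
    heading0: float | None = None,
    animal_id: str = "W01",
    pack_id: str = "P1",
    max_rejection_rounds: int = 1000,
    boundary: str = "reject",
) -> Trajectory:
    """Simulate one trajectory from the step-selection generative model.

    Boundary policy: with ``boundary='reject'`` (default) candidates leaving
    the landscape are rejected and redrawn, and ``SimulationError`` is
    raised if ``max_rejection_rounds`` is exhausted for a step; with
    ``'reflect'`` endpoints are mirrored at the landscape edges (suits
    strongly directional kernels, for which rejection can starve in
    corners); with ``'wrap'`` the landscape is a torus, which removes edge
    artifacts entirely (travelling animals neither slow down nor linger at
    walls) at the cost of occasional jumps in the recorded fixes.
    """
    if boundary not in ("reject", "reflect", "wrap"):
        raise ValueError("boundary must be 'reject', 'reflect' or 'wrap'")
    if n_candidates < 20:
        raise ValueError("n_candidates must be >= 20")
    grid = landscape.grid
    if not bool(grid.contains(start[0], start[1])):
        raise ValueError("start position outside the landscape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = landscape.covariate_arrays()
    end_terms, start_terms = _split_params(params)
    b_lnsl = params.get("ln_sl")
    b_lnsl_sin = params.get("ln_sl:sin_hour")
    xmin, ymin, xmax, ymax = grid.bounds

    t0 = pd.Timestamp(start_time)
    dt = pd.Timedelta(minutes=60)
    x, y = float(start[0]), float(start[1])
    heading = float(heading0) if heading0 is not None else float(rng.uniform(-np.pi, np.pi))
    times = [t0]
    xs_out = [x]
    ys_out = [y]

    for i in range(n_steps):
        t = t0 + i * dt
        local_hour = (t.hour + t.minute / 60.0) % 24.0
        sh = sin_hour(local_hour)
        # start-extracted covariates are shared by all candidates of the step
        row, col = grid.cell_of(x, y)
        lnsl_coef = b_lnsl + b_lnsl_sin * sh + sum(
            b * arrays[name][row, col] for name, b in start_terms
        )

        if boundary == "reflect":
            s, a = kernel.sample_steps(n_candidates, rng)
            hd = heading + a
            sl = s
            px = _fold(x + s * 1000.0 * np.cos(hd), xmin, xmax)
            py = _fold(y + s * 1000.0 * np.sin(hd), ymin, ymax)
        elif boundary == "wrap":
            s, a = kernel.sample_steps(n_candidates, rng)
            hd = heading + a
            sl = s
            px = xmin + np.mod(x + s * 1000.0 * np.cos(hd) - xmin, xmax - xmin)
            py = ymin + np.mod(y + s * 1000.0 * np.sin(hd) - ymin, ymax - ymin)
        else:
            sl = np.empty(n_candidates)
            px = np.empty(n_candidates)
            py = np.empty(n_candidates)
            hd = np.empty(n_candidates)
            todo = np.ones(n_candidates, dtype=bool)
            for _ in range(max_rejection_rounds):
                m = int(todo.sum())
                if m == 0:
                    break
                s, a = kernel.sample_steps(m, rng)
                h = heading + a
                cx = x + s * 1000.0 * np.cos(h)
                cy = y + s * 1000.0 * np.sin(h)
                sl[todo], hd[todo], px[todo], py[todo] = s, h, cx, cy
                idx = np.flatnonzero(todo)
                inside = (cx >= xmin) & (cx < xmax) & (cy >= ymin) & (cy < ymax)
                todo[idx[inside]] = False
            if todo.any():
                raise SimulationError("candidate rejection exhausted at the landscape boundary")

        rows, cols = grid.cell_of(px, py)
        score = np.log(np.maximum(sl, SL_FLOOR_KM)) * lnsl_coef
        for name, b in end_terms:
            score = score + b * arrays[name][rows, cols]
        score -= score.max()
        w = np.exp(score)
        choice = rng.choice(n_candidates, p=w / w.sum())
        if boundary == "reflect":
            # realized heading after mirroring, for turn-angle continuity
            nh = np.arctan2(py[choice] - y, px[choice] - x)
            x, y, heading = float(px[choice]), float(py[choice]), float(nh)
        else:  # reject and wrap both keep the drawn heading
            x, y, heading = float(px[choice]), float(py[choice]), float(hd[choice])
        times.append(t + dt)
        xs_out.append(x)
        ys_out.append(y)

    fixes = pd.DataFrame({"t": times, "x": xs_out, "y": ys_out})
    return Trajectory(animal_id=animal_id, pack_id=pack_id, fixes=fixes)


@dataclass
class PopulationPreset:
    """Roster configuration for a multi-animal simulation.

    The default mirrors the study design the package emulates: ten collared
    wolves in five packs, hourly fixes over a multi-month (single-season)
    span.
    """

    n_animals: int = 10
    n_packs: int = 5
    n_steps: int = 2160  # 90 days of hourly fixes
    start_time: str = "2019-04-02 00:00"
    n_candidates: int = 200


def study_roster_preset() -> PopulationPreset:
    return PopulationPreset()


def simulate_population(
    landscape: LandscapeStack,
    kernel: MovementKernel = DEFAULT_KERNEL,
    params: SelectionParams | None = None,
    preset: PopulationPreset | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate the full roster; returns a fix frame for all animals.

    Animals start at random positions within the central 60% of the
    landscape (keeps boundary rejection rare) with pack ids assigned
    round-robin.
    """
    preset = preset or study_roster_preset()
    params = params or default_selection_params()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landscape.bounds
    w, h = xmax - xmin, ymax - ymin
    frames = []
    for i in range(preset.n_animals):
        sx = rng.uniform(xmin + 0.2 * w, xmax - 0.2 * w)
        sy = rng.uniform(ymin + 0.2 * h, ymax - 0.2 * h)
        traj = simulate_trajectory(
            landscape,
            kernel,
            params,
            (sx, sy),
            n_steps=preset.n_steps,
            n_candidates=preset.n_candidates,
            seed=rng,
            start_time=preset.start_time,
            animal_id=f"W{i + 1:02d}",
            pack_id=f"P{i % preset.n_packs + 1}",
        )
        frames.append(traj.as_fix_frame())
    return pd.concat(frames, ignore_index=True)


def logistic_hazard(beta: dict):
    """Per-step kill probability as inverse-logit of a linear predictor.

    ``beta`` maps covariate names (plus optional ``intercept``) to
    coefficients; the returned callable takes a dict of covariate arrays.
    """

    def hazard(cov: dict) -> np.ndarray:
        names = [k for k in beta if k != "intercept"]
        eta = beta.get("intercept", 0.0) + sum(beta[k] * np.asarray(cov[k], float) for k in names)
        return 1.0 / (1.0 + np.exp(-eta))

    return hazard


def plant_kill_clusters(
    traj: Trajectory,
    hazard,
    landscape: LandscapeStack,
    dwell_hours: int = 24,
    radius_m: float = 100.0,
    seed: int | np.random.Generator = 0,
    prey: str = "moose",
) -> tuple[Trajectory, KillTruth]:
    """Insert kill-site dwelling into a trajectory.

    ``hazard`` is a callable mapping end-of-step covariate arrays to per-fix
    kill probabilities (see :func:`logistic_hazard`), or a constant.  At each
    kill the trajectory pauses: ``dwell_hours`` extra hourly fixes are
    scattered uniformly within ``radius_m`` of the carcass, and the rest of
    the trajectory is shifted later in time.
    """
    if dwell_hours < 2:
        raise ValueError("dwell_hours must be >= 2")
    xmin, ymin, xmax, ymax = landscape.bounds
    if radius_m >= min(xmax - xmin, ymax - ymin):
        raise ValueError("scatter radius exceeds the landscape extent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fx = traj.fixes.reset_index(drop=True)
    if callable(hazard):
        cov = landscape.covariates_at(fx["x"].to_numpy(), fx["y"].to_numpy())
        p = np.asarray(hazard(cov), dtype=float)
    elif np.ndim(hazard) == 1:  # explicit per-fix probabilities
        p = np.asarray(hazard, dtype=float)
        if p.size != len(fx):
            raise ValueError("per-fix hazard length must match the trajectory")
    else:
        p = np.asarray(float(hazard))
    p = np.broadcast_to(p, (len(fx),)).copy()
    p[0] = 0.0
    kills = rng.random(len(fx)) < p

    dt = pd.Timedelta(minutes=traj.fix_interval_min)
    rows = []
    events = []
    shift = pd.Timedelta(0)
    for i in range(len(fx)):
        t = fx.loc[i, "t"] + shift
        rows.append({"t": t, "x": fx.loc[i, "x"], "y": fx.loc[i, "y"]})
        if kills[i]:
            kx, ky = float(fx.loc[i, "x"]), float(fx.loc[i, "y"])
            events.append(
                {"x": kx, "y": ky, "t_start": t, "dwell_hours": dwell_hours, "prey": prey}
            )
            for j in range(1, dwell_hours + 1):
                r = radius_m * np.sqrt(rng.random())
                a = rng.uniform(0, 2 * np.pi)
                rows.append(
                    {
                        "t": t + j * dt,
                        "x": np.clip(kx + r * np.cos(a), xmin, xmax - 1e-6),
                        "y": np.clip(ky + r * np.sin(a), ymin, ymax - 1e-6),
                    }
                )
            shift += dwell_hours * dt
    truth = KillTruth(
        events=pd.DataFrame(events, columns=["x", "y", "t_start", "dwell_hours", "prey"])
    )
    if truth.events.empty:
        warnings.warn("hazard produced no kills over the whole trajectory")
        return traj, truth
    out = Trajectory(
        animal_id=traj.animal_id,
        pack_id=traj.pack_id,
        fixes=pd.DataFrame(rows),
        fix_interval_min=traj.fix_interval_min,
    )
    return out, truth


def simulate_killsite_points(
    landscape: LandscapeStack,
    beta_kill: dict,
    n_kill: int = 158,
    n_random: int = 474,
    buffer_m: float = 883.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Labelled kill and random sites with buffer covariates.

    Kill locations are rejection-sampled with acceptance probability
    inverse-logit(beta_kill' x) on buffer covariates; random sites are
    uniform over the study area.  Returns a record frame with ``label``
    (kill = 1, random = 0), coordinates, and the buffer covariates.
    """
    from .killsite import buffer_covariates_frame

    if n_kill < 1 or n_random < 1:
        raise ValueError("n_kill and n_random must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landscape.bounds
    pad = buffer_m  # keep buffers inside the landscape
    hazard = logistic_hazard(beta_kill)

    kept_x, kept_y = [], []
    guard = 0
    while len(kept_x) < n_kill:
        guard += 1
        if guard > 10_000:
            raise SimulationError("kill-site rejection sampling failed to reach n_kill")
        m = max(4 * (n_kill - len(kept_x)), 64)
        cx = rng.uniform(xmin + pad, xmax - pad, size=m)
        cy = rng.uniform(ymin + pad, ymax - pad, size=m)
        covs = buffer_covariates_frame(cx, cy, landscape, buffer_m=buffer_m)
        p = hazard({k: covs[k].to_numpy() for k in covs.columns})
        acc = rng.random(m) < p
        kept_x.extend(cx[acc][: n_kill - len(kept_x)])
        kept_y.extend(cy[acc][: n_kill - len(kept_y)])

    rx = rng.uniform(xmin + pad, xmax - pad, size=n_random)
    ry = rng.uniform(ymin + pad, ymax - pad, size=n_random)
    x = np.r_[kept_x, rx]
    y = np.r_[kept_y, ry]
    rec = buffer_covariates_frame(x, y, landscape, buffer_m=buffer_m)
    rec.insert(0, "x", x)
    rec.insert(1, "y", y)
    rec.insert(2, "label", np.r_[np.ones(n_kill, int), np.zeros(n_random, int)])
    if all(rec[c].nunique() <= 1 for c in rec.columns if c not in ("x", "y", "label")):
        warnings.warn("degenerate landscape: constant covariates at every site")
    return rec


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    """Write a fix frame as CSV with ISO-8601 UTC timestamps."""
    out = fixes.copy()
    out["t"] = pd.DatetimeIndex(out["t"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    fixes = pd.read_csv(path)
    fixes["t"] = pd.to_datetime(fixes["t"]).dt.tz_localize(None)
    return fixes
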