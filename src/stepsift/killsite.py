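"""GPS-cluster kill-site detection and kill vs random site modelling.

Prolonged carcass handling leaves a spatiotemporal cluster of predator GPS
fixes; an iterative-centroid scan detects such clusters as candidate
kill-sites.  Detected (or planted) kill locations are then compared with
random sites via logistic regression on covariates summarised within a
buffer (class proportions, mean NDVI; distance covariates at the point by
default), after screening multicollinearity with variance inflation factors
(VIF > 4 excluded).  Model fit is assessed with k-fold cross-validation and
a Boyce-style binned Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .landscape import LOG_DISTANCE_OFFSET, LandscapeStack
from .models import ModelSpec

logger = logging.getLogger(__name__)

#: class-proportion covariates summarised within the buffer
PROPORTION_TERMS = ("pine", "deciduous", "mixed_forest", "coniferous", "nc", "rc")
#: covariates evaluated at the point itself by default
POINT_TERMS = ("ln_water", "ln_edge_in", "ln_edge_out", "lf_density", "ln_dist_lf")


@dataclass
class Cluster:
    """A spatiotemporal aggregation of one animal's GPS fixes."""

    animal_id: str
    centroid_x: float
    centroid_y: float
    t_first: pd.Timestamp
    t_last: pd.Timestamp
    n_fixes: int
    member_index: list


class GPSClusterDetector(BaseEstimator):
    """Iterative-centroid spatiotemporal cluster scan.

    Seeds a cluster on each unassigned fix in time order, absorbs later
    fixes lying within ``radius_m`` of the running centroid and within
    ``window_hours`` of the last absorbed fix (recomputing the centroid on
    each absorption), and emits clusters with at least ``min_fixes``
    members.  Deterministic given the input order.

    Attributes
    ----------
    clusters_ : list of :class:`Cluster`
    labels_ : ndarray of cluster index per fix (-1 = unclustered)
    """

    def __init__(self, radius_m: float = 300.0, window_hours: float = 96.0, min_fixes: int = 4):
        self.radius_m = radius_m
        self.window_hours = window_hours
        self.min_fixes = min_fixes

    def fit(self, fixes: pd.DataFrame):
        if self.radius_m <= 0 or self.window_hours <= 0 or self.min_fixes <= 0:
            raise ValueError("radius_m, window_hours and min_fixes must be > 0")
        self.clusters_ = []
        self.labels_ = np.full(len(fixes), -1, dtype=int)
        if len(fixes) == 0:
            return self
        pos = fixes.reset_index(drop=True)
        window = pd.Timedelta(hours=self.window_hours)
        for animal, grp in pos.groupby("animal_id", sort=False):
            idx = grp.index.to_numpy()
            t = pd.DatetimeIndex(grp["t"])
            x = grp["x"].to_numpy(float)
            y = grp["y"].to_numpy(float)
            assigned = np.zeros(len(grp), dtype=bool)
            for i in range(len(grp)):
                if assigned[i]:
                    continue
                members = [i]
                cx, cy = x[i], y[i]
                t_last = t[i]
                for j in range(i + 1, len(grp)):
                    if assigned[j]:
                        continue
                    if t[j] - t_last > window:
                        break
                    if np.hypot(x[j] - cx, y[j] - cy) <= self.radius_m:
                        members.append(j)
                        cx = x[members].mean()
                        cy = y[members].mean()
                        t_last = t[j]
                if len(members) >= self.min_fixes:
                    assigned[members] = True
                    cid = len(self.clusters_)
                    self.labels_[idx[members]] = cid
                    self.clusters_.append(
                        Cluster(
                            animal_id=animal,
                            centroid_x=float(cx),
                            centroid_y=float(cy),
                            t_first=t[members[0]],
                            t_last=t_last,
                            n_fixes=len(members),
                            member_index=[int(idx[m]) for m in members],
                        )
                    )
        return self

    def fit_predict(self, fixes: pd.DataFrame) -> np.ndarray:
        return self.fit(fixes).labels_


def find_clusters(
    fixes: pd.DataFrame,
    radius_m: float = 300.0,
    window_hours: float = 96.0,
    min_fixes: int = 4,
) -> list[Cluster]:
    """Detect candidate kill-site clusters (see :class:`GPSClusterDetector`)."""
    det = GPSClusterDetector(radius_m=radius_m, window_hours=window_hours, min_fixes=min_fixes)
    return det.fit(fixes.sort_values(["animal_id", "t"])).clusters_


def match_clusters_to_truth(clusters, truth_events: pd.DataFrame, radius_m: float = 300.0):
    """Recall/precision of detected clusters against planted kill events.

    A cluster matches an event when its centroid lies within ``radius_m`` of
    the event and their time ranges overlap the event's dwell window.
    """
    matched_events = np.zeros(len(truth_events), dtype=bool)
    matched_clusters = np.zeros(len(clusters), dtype=bool)
    for ci, cl in enumerate(clusters):
        for ei, ev in truth_events.iterrows():
            d = np.hypot(cl.centroid_x - ev["x"], cl.centroid_y - ev["y"])
            t_end = ev["t_start"] + pd.Timedelta(hours=float(ev["dwell_hours"]))
            overlap = (cl.t_first <= t_end) and (cl.t_last >= ev["t_start"])
            if d <= radius_m and overlap:
                matched_events[ei] = True
                matched_clusters[ci] = True
    recall = float(matched_events.mean()) if len(truth_events) else float("nan")
    precision = float(matched_clusters.mean()) if clusters else float("nan")
    return {"recall": recall, "precision": precision, "n_clusters": len(clusters), "n_events": len(truth_events)}


# ---------------------------------------------------------------------------
# buffer covariates

def _buffer_offsets(cell_size: float, buffer_m: float):
    r_cells = buffer_m / cell_size
    n = int(np.ceil(r_cells))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    keep = (dx**2 + dy**2) <= r_cells**2
    return dy[keep], dx[keep]


def buffer_covariates_frame(
    x,
    y,
    landscape: LandscapeStack,
    buffer_m: float = 883.0,
    distance_mode: str = "point",
) -> pd.DataFrame:
    """Buffer-summarised covariates for many points at once.

    Class proportions are fractions of valid buffer cells; NDVI is the
    buffer mean.  Distance-type covariates (water, edges, linear features)
    are read at the point itself by default (``distance_mode='point'``) or
    buffer-averaged with ``'buffer'``.  Note that point-mode edge distances
    are complementary (a site is either in forest or in the open, so one of
    the pair is zero), which VIF screening tends to flag; buffer averaging
    instead smooths the class proportions into near-collinearity.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be > 0")
    if distance_mode not in ("point", "buffer"):
        raise ValueError("distance_mode must be 'point' or 'buffer'")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    grid = landscape.grid
    arrays = landscape.covariate_arrays()
    row, col = grid.cell_of(x, y)
    dy, dx = _buffer_offsets(grid.cell_size, buffer_m)
    rows = row[:, None] + dy[None, :]
    cols = col[:, None] + dx[None, :]
    valid = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not valid.any(axis=1).all():
        raise ValueError("a buffer contains zero valid cells")
    rows_c = np.clip(rows, 0, grid.n_rows - 1)
    cols_c = np.clip(cols, 0, grid.n_cols - 1)
    n_valid = valid.sum(axis=1)

    out = {}
    for name in PROPORTION_TERMS + ("ndvi",):
        vals = arrays[name][rows_c, cols_c]
        out[name] = np.where(valid, vals, 0.0).sum(axis=1) / n_valid
    if distance_mode == "point":
        inside = grid.contains(x, y)
        if not inside.all():
            raise ValueError("point outside the landscape")
        for name in POINT_TERMS:
            out[name] = arrays[name][row, col]
    else:
        for name in POINT_TERMS:
            vals = arrays[name][rows_c, cols_c]
            out[name] = np.where(valid, vals, 0.0).sum(axis=1) / n_valid
    return pd.DataFrame(out)


def buffer_covariates(point, landscape: LandscapeStack, buffer_m: float = 883.0, **kw) -> dict:
    """Buffer covariates for a single (x, y) point."""
    frame = buffer_covariates_frame([point[0]], [point[1]], landscape, buffer_m=buffer_m, **kw)
    return {k: float(v) for k, v in frame.iloc[0].items()}


# ---------------------------------------------------------------------------
# VIF screening

def vif_filter(design: pd.DataFrame, threshold: float = 4.0):
    """Iteratively drop terms with VIF strictly above the threshold.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing term j on the remaining
    terms (with intercept).  The largest offender is removed and VIFs are
    recomputed until all remaining VIFs are <= threshold (a VIF of exactly
    the threshold is retained).  Perfectly collinear terms get infinite VIF.

    Returns ``(retained_terms, report)`` where report lists each term's
    final (or at-removal) VIF and whether it was removed.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF screening needs at least 2 candidate terms")
    if len(design) <= len(cols):
        raise ValueError("need more rows than candidate terms")
    removed = {}
    current = cols.copy()

    def vifs(names):
        X = design[names].to_numpy(float)
        out = {}
        for j, name in enumerate(names):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(len(X)), others])
            yj = X[:, j]
            resid = yj - A @ np.linalg.lstsq(A, yj, rcond=None)[0]
            sst = np.sum((yj - yj.mean()) ** 2)
            if sst == 0:
                out[name] = np.inf
                continue
            r2 = 1.0 - resid @ resid / sst
            out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while len(current) >= 2:
        v = vifs(current)
        worst = max(v, key=v.get)
        # strictly greater than the threshold; a float-noise guard keeps a
        # VIF of exactly the threshold on the retained side
        if v[worst] > threshold + 1e-9:
            removed[worst] = v[worst]
            current.remove(worst)
        else:
            break
    final = vifs(current) if len(current) >= 2 else {current[0]: 1.0}
    report = pd.DataFrame(
        [
            {"term": t, "vif": removed.get(t, final.get(t, np.nan)), "removed": t in removed}
            for t in cols
        ]
    )
    return current, report


# ---------------------------------------------------------------------------
# logistic model

class KillSiteLogistic(BaseEstimator):
    """Maximum-likelihood logistic regression of kill vs random labels.

    A thin estimator around the IRLS/Newton logistic fit of statsmodels,
    exposing the per-term coefficient, standard error and z = beta/SE.

    Attributes
    ----------
    coef_ : ndarray (without intercept)
    intercept_ : float
    se_, z_ : dict by term (including "intercept")
    loglik_, aic_ : float
    converged_ : bool
    """

    def __init__(self, max_iter: int = 200):
        self.max_iter = max_iter

    def fit(self, X, y, term_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        labels = np.unique(y)
        if not np.isin(labels, [0, 1]).all() or labels.size < 2:
            raise ValueError("need both kill (1) and random (0) labels")
        names = list(term_names) if term_names is not None else [f"x{j}" for j in range(X.shape[1])]
        # constant columns are unidentifiable next to the intercept: fit
        # without them, report coefficient 0 with undefined SE
        live = np.flatnonzero(X.std(axis=0) > 0)
        if live.size < X.shape[1]:
            warnings.warn("constant covariate columns excluded from the logistic fit")
        exog = sm.add_constant(X[:, live], has_constant="add")
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, exog).fit(disp=0, maxiter=self.max_iter)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:  # perfect separation
                res = sm.Logit(y, exog).fit(disp=0, maxiter=self.max_iter, method="bfgs")
                converged = False
        if not converged:
            warnings.warn("kill-site logistic did not converge (possible separation)")
        full_names = ["intercept"] + names
        self.term_names_ = names
        params = np.zeros(X.shape[1] + 1)
        bse = np.full(X.shape[1] + 1, np.nan)
        params[0], bse[0] = res.params[0], res.bse[0]
        params[1 + live] = res.params[1:]
        bse[1 + live] = res.bse[1:]
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.params_ = dict(zip(full_names, params))
        self.se_ = dict(zip(full_names, bse))
        self.z_ = {
            k: self.params_[k] / self.se_[k] if self.se_[k] > 0 else np.nan for k in full_names
        }
        self.loglik_ = float(res.llf)
        self.aic_ = float(res.aic)
        self.converged_ = converged
        return self

    def predict_proba_1(self, X):
        eta = self.intercept_ + np.asarray(X, dtype=float) @ self.coef_
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class KillSiteFit:
    """Fitted kill-site logistic model for one candidate spec."""

    spec_name: str
    terms: tuple
    beta: dict
    se: dict
    z: dict
    loglik: float
    aic: float
    converged: bool
    model: KillSiteLogistic

    def to_dict(self) -> dict:
        return {
            "spec_name": self.spec_name,
            "terms": list(self.terms),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "z": {k: float(v) for k, v in self.z.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
        }


def fit_killsite_logistic(records: pd.DataFrame, spec: ModelSpec) -> KillSiteFit:
    """Fit one candidate model to labelled kill/random records."""
    X = records[list(spec.terms)].to_numpy(float)
    est = KillSiteLogistic().fit(X, records["label"].to_numpy(), term_names=list(spec.terms))
    return KillSiteFit(
        spec_name=spec.name,
        terms=tuple(spec.terms),
        beta=est.params_,
        se=est.se_,
        z=est.z_,
        loglik=est.loglik_,
        aic=est.aic_,
        converged=est.converged_,
        model=est,
    )


def compare_killsite_models(records: pd.DataFrame, specs) -> pd.DataFrame:
    """Fit every candidate spec and rank by AIC."""
    rows = []
    for spec in specs:
        fit = fit_killsite_logistic(records, spec)
        rows.append({"spec_name": spec.name, "aic": fit.aic, "loglik": fit.loglik, "k": len(spec.terms) + 1})
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# k-fold Spearman validation

def _binned_spearman(p_kill, p_random, n_bins):
    """Boyce-style area-adjusted Spearman over score bins.

    Bins are equal-count quantile bins of the held-out random-site scores;
    the statistic is the Spearman correlation between bin rank and the
    area-adjusted kill frequency (kill share / random share per bin).
    Duplicate quantile edges merge adjacent bins (logged).
    """
    from scipy.stats import spearmanr

    edges = np.quantile(p_random, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size - 1 < n_bins:
        logger.info("merged %d empty score bins", n_bins - (edges.size - 1))
    if edges.size < 3:
        return np.nan
    edges[0], edges[-1] = -np.inf, np.inf
    kb = np.clip(np.searchsorted(edges, p_kill, side="right") - 1, 0, edges.size - 2)
    rb = np.clip(np.searchsorted(edges, p_random, side="right") - 1, 0, edges.size - 2)
    nb = edges.size - 1
    kill_share = np.bincount(kb, minlength=nb) / max(len(p_kill), 1)
    rand_share = np.bincount(rb, minlength=nb) / max(len(p_random), 1)
    adjusted = kill_share / np.where(rand_share > 0, rand_share, np.nan)
    keep = ~np.isnan(adjusted)
    if keep.sum() < 3:
        return np.nan
    rho, _ = spearmanr(np.arange(nb)[keep], adjusted[keep])
    return float(rho)


def kfold_spearman(
    records: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    n_bins: int = 10,
    seed: int | np.random.Generator = 0,
) -> dict:
    """k-fold cross-validated Spearman rank correlation of a kill-site model.

    Folds are stratified by label so every training set sees both classes.
    Per fold the model is refitted on the training records and held-out kill
    sites are scored against held-out random sites with the binned
    area-adjusted Spearman statistic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = records.reset_index(drop=True)
    fold = np.empty(len(records), dtype=int)
    for label in (0, 1):
        idx = np.flatnonzero(records["label"].to_numpy() == label)
        fold[idx[rng.permutation(idx.size)]] = np.arange(idx.size) % k
    rhos = []
    for f in range(k):
        train = records[fold != f]
        test = records[fold == f]
        fit = fit_killsite_logistic(train, spec)
        p = fit.model.predict_proba_1(test[list(spec.terms)].to_numpy(float))
        rho = _binned_spearman(
            p[test["label"].to_numpy() == 1], p[test["label"].to_numpy() == 0], n_bins
        )
        rhos.append(rho)
    rhos = np.asarray(rhos, dtype=float)
    return {"mean_rs": float(np.nanmean(rhos)), "fold_rs": rhos.tolist(), "k": k, "n_bins": n_bins}
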