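"""Conditional logistic regression for matched used/available strata.

The estimation core of the step-selection analysis.  Each stratum holds one
used step and its matched available steps; the conditional log-likelihood is

    l(beta) = sum_s [ beta' x_used(s) - ln sum_{j in s} exp(beta' x_j) ]

maximised by damped Newton iterations (step-halving line search, analytic
gradient and Hessian).  The coefficient covariance is the inverse observed
information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .models import ModelSpec, design_matrix


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient within strata (unidentifiable terms)."""


class ConvergenceWarning(UserWarning):
    pass


def _group_starts(groups: np.ndarray) -> np.ndarray:
    """Start indices of contiguous runs in a sorted group vector."""
    return np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])


class ConditionalLogisticRegression(BaseEstimator):
    """Conditional logit MLE over matched strata.

    Parameters
    ----------
    tol : float
        Per-stratum gradient infinity-norm convergence tolerance: the fit
        converges when ``max|g| <= tol * max(1, n_strata)``.  (The summed
        gradient scales with the number of strata, and its floating-point
        floor with the magnitude of the log-likelihood.)
    max_iter : int
        Maximum Newton iterations.
    rank_tol : float
        Threshold on within-stratum variation below which a column is
        declared stratum-constant (unidentifiable).

    Attributes
    ----------
    coef_ : ndarray of shape (n_terms,)
    cov_ : ndarray of shape (n_terms, n_terms)
        Inverse observed information; symmetric PSD when converged.
    loglik_ : float
    null_loglik_ : float
        Log-likelihood at beta = 0 (uniform choice within each stratum).
    aic_ : float
    n_strata_ : int
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, rank_tol: float = 1e-10):
        self.tol = tol
        self.max_iter = max_iter
        self.rank_tol = rank_tol

    # -- likelihood pieces ----------------------------------------------------

    @staticmethod
    def _loglik(eta, y, starts):
        emax = np.maximum.reduceat(eta, starts)
        rep = np.diff(np.r_[starts, eta.size])
        ez = np.exp(eta - np.repeat(emax, rep))
        lse = np.log(np.add.reduceat(ez, starts)) + emax
        return float(eta[y == 1].sum() - lse.sum()), ez / np.repeat(np.add.reduceat(ez, starts), rep)

    def fit(self, X, y, groups, term_names=None):
        """Fit the conditional logit.

        Parameters
        ----------
        X : array-like of shape (n_rows, n_terms)
        y : array-like of 0/1 case flags; exactly one 1 per group.
        groups : array-like of stratum identifiers.
        term_names : optional sequence naming the columns (for diagnostics).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups).ravel()
        if X.ndim != 2 or X.shape[0] != y.size or y.size != groups.size:
            raise ValueError("X, y and groups must have matching first dimensions")
        names = list(term_names) if term_names is not None else [f"x{j}" for j in range(X.shape[1])]

        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        starts = _group_starts(groups)
        rep = np.diff(np.r_[starts, y.size])
        used_per = np.add.reduceat(y, starts)
        if not np.all(used_per == 1):
            raise ValueError("every stratum must contain exactly one used row")
        if np.any(rep < 2):
            raise ValueError("every stratum needs at least one available row")

        # identifiability: centre within strata
        means = np.add.reduceat(X, starts, axis=0) / rep[:, None]
        Xc = X - np.repeat(means, rep, axis=0)
        span = np.abs(Xc).max(axis=0)
        dead = np.flatnonzero(span < self.rank_tol)
        if dead.size:
            raise RankDeficiencyError(
                "stratum-constant (unidentifiable) terms: " + ", ".join(names[j] for j in dead)
            )
        scale = Xc.std(axis=0)
        r = np.linalg.matrix_rank(Xc / scale, tol=1e-8)
        if r < X.shape[1]:
            raise RankDeficiencyError(
                f"design matrix rank {r} < {X.shape[1]} columns; collinear terms among: "
                + ", ".join(names)
            )

        n_strata = starts.size
        gtol = self.tol * max(1.0, float(n_strata))
        beta = np.zeros(X.shape[1])
        ll, pi = self._loglik(X @ beta, y, starts)
        self.null_loglik_ = -float(np.log(rep).sum())
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            g = X.T @ (y - pi)
            if np.max(np.abs(g)) < gtol:
                converged = True
                break
            A = np.add.reduceat(pi[:, None] * X, starts, axis=0)  # per-stratum E[x]
            H = (X * pi[:, None]).T @ X - A.T @ A
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # step-halving line search; slack relative to the ll magnitude
            slack = 1e-10 * (1.0 + abs(ll))
            t = 1.0
            for _ in range(40):
                cand = beta + t * step
                ll_new, pi_new = self._loglik(X @ cand, y, starts)
                if ll_new >= ll - slack:
                    break
                t /= 2.0
            if ll_new < ll - slack:
                break
            beta, ll, pi = cand, ll_new, pi_new
        else:
            it = self.max_iter

        g = X.T @ (y - pi)
        if not converged and np.max(np.abs(g)) < gtol:
            converged = True
        if not converged:
            warnings.warn(
                "conditional logit did not converge (possible complete separation)",
                ConvergenceWarning,
            )
        A = np.add.reduceat(pi[:, None] * X, starts, axis=0)
        H = (X * pi[:, None]).T @ X - A.T @ A
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((X.shape[1], X.shape[1]), np.nan)

        self.coef_ = beta
        self.cov_ = 0.5 * (cov + cov.T)
        self.loglik_ = ll
        self.aic_ = 2.0 * X.shape[1] - 2.0 * ll
        self.n_strata_ = int(n_strata)
        self.converged_ = bool(converged)
        self.n_iter_ = int(it)
        self.term_names_ = names
        return self

    def decision_function(self, X):
        """Linear predictor beta' x."""
        return np.asarray(X, dtype=float) @ self.coef_

    def loglik_at(self, beta, X, y, groups):
        """Conditional log-likelihood at an arbitrary coefficient vector."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups).ravel()
        order = np.argsort(groups, kind="stable")
        starts = _group_starts(groups[order])
        ll, _ = self._loglik(X[order] @ np.asarray(beta, float), y[order], starts)
        return ll


@dataclass
class FittedModel:
    """Per-individual conditional-logistic fit for one candidate spec."""

    animal_id: str
    season: str
    spec_name: str
    terms: tuple
    beta: dict
    loglik: float
    aic: float
    cov: np.ndarray
    n_strata: int
    converged: bool

    @property
    def coef_array(self) -> np.ndarray:
        return np.array([self.beta[t] for t in self.terms])

    def se(self) -> dict:
        s = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return dict(zip(self.terms, s))

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "season": self.season,
            "spec_name": self.spec_name,
            "terms": list(self.terms),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_strata": int(self.n_strata),
            "converged": bool(self.converged),
        }


def fit_clogit(steps, spec: ModelSpec, animal_id: str = "", season: str = "", **kwargs) -> FittedModel:
    """Fit one candidate model to a step design frame.

    ``steps`` must carry ``stratum``, ``case`` and every covariate column the
    spec's terms resolve to (see :func:`stepsift.models.term_column`).
    """
    X = design_matrix(steps, spec)
    est = ConditionalLogisticRegression(**kwargs).fit(
        X, steps["case"].to_numpy(), steps["stratum"].to_numpy(), term_names=spec.terms
    )
    return FittedModel(
        animal_id=animal_id,
        season=season,
        spec_name=spec.name,
        terms=spec.terms,
        beta=dict(zip(spec.terms, est.coef_)),
        loglik=est.loglik_,
        aic=est.aic_,
        cov=est.cov_,
        n_strata=est.n_strata_,
        converged=est.converged_,
    )
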