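"""Population-level inference from per-individual step-selection fits.

Two-stage design: conditional-logistic models are fitted per individual,
then population coefficients come from a bootstrap that resamples *animals*
with replacement (each animal equally likely regardless of how many fitted
models it contributes), averaging coefficients within each repetition and
summarising with the median and 2.5th/97.5th quantiles over (by default)
2000 repetitions.

Derived quantities: log relative selection strength (log-RSS) between two
covariate vectors, and expected displacement rate from the updated gamma
kernel (shape corrected by the ln(SL) coefficients, scale untouched because
no untransformed-SL term appears in the model space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clogit import ConditionalLogisticRegression, FittedModel
from .kernels import MovementKernel
from .models import ModelSpec, design_matrix
from .steps import sin_hour


class ContractError(ValueError):
    """Inputs violate an interface contract (e.g. movement terms differ)."""


@dataclass
class PopulationSummary:
    """Bootstrap summary of population-level coefficients."""

    table: pd.DataFrame  # columns term, lower, median, upper
    n_reps: int
    quantiles: tuple
    n_animals: int
    draws: np.ndarray | None = field(default=None, repr=False)

    def beta_median(self) -> dict:
        return dict(zip(self.table["term"], self.table["median"]))

    def interval(self, term: str) -> tuple:
        row = self.table.set_index("term").loc[term]
        return float(row["lower"]), float(row["upper"])


def bootstrap_population(
    models: list[FittedModel],
    n_reps: int = 2000,
    seed: int | np.random.Generator = 0,
    quantiles: tuple = (0.025, 0.975),
) -> PopulationSummary:
    """Equal-probability animal bootstrap of coefficient vectors.

    Each repetition draws ``n_animals`` animals with replacement; an animal
    drawn into a slot contributes one of its fitted models chosen uniformly
    (so an animal's multiple models share its sampling weight).  Coefficient
    vectors are aligned by term name and averaged within the repetition.
    """
    if not models:
        raise ValueError("no fitted models")
    terms = models[0].terms
    for m in models:
        if m.terms != terms:
            raise ContractError(
                f"term mismatch across animals: {m.animal_id} has {m.terms}, expected {terms}"
            )
    by_animal: dict = {}
    for m in models:
        by_animal.setdefault(m.animal_id, []).append(m.coef_array)
    animals = list(by_animal)
    if len(animals) < 2:
        raise ValueError("bootstrap needs at least 2 animals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_animals = len(animals)
    draws = np.empty((n_reps, len(terms)))
    for r in range(n_reps):
        picks = rng.integers(0, n_animals, size=n_animals)
        acc = np.zeros(len(terms))
        for a in picks:
            coefs = by_animal[animals[a]]
            acc += coefs[rng.integers(0, len(coefs))] if len(coefs) > 1 else coefs[0]
        draws[r] = acc / n_animals
    lo, hi = quantiles
    table = pd.DataFrame(
        {
            "term": list(terms),
            "lower": np.quantile(draws, lo, axis=0),
            "median": np.median(draws, axis=0),
            "upper": np.quantile(draws, hi, axis=0),
        }
    )
    return PopulationSummary(
        table=table, n_reps=n_reps, quantiles=quantiles, n_animals=n_animals, draws=draws
    )


def _beta_of(source) -> dict:
    if isinstance(source, FittedModel):
        return source.beta
    if isinstance(source, PopulationSummary):
        return source.beta_median()
    return dict(source)


def log_rss(source, x1: dict, x2: dict) -> float:
    """Log relative selection strength of location x1 over location x2.

    ``log-RSS = beta' (x1 - x2)`` over habitat terms; movement terms
    (ln_sl and its interactions' ln_sl side, sin_hour) must be identical in
    the two vectors.  Exponentiate for RSS.
    """
    beta = _beta_of(source)
    for key in ("ln_sl", "sin_hour"):
        if x1.get(key, 0.0) != x2.get(key, 0.0):
            raise ContractError(f"movement term {key!r} differs between x1 and x2")
    total = 0.0
    for term, b in beta.items():
        if term == "ln_sl":
            continue
        if term.startswith("ln_sl:"):
            inner = term[len("ln_sl:") :]
            v1 = x1.get("ln_sl", 0.0) * x1.get(inner, 0.0)
            v2 = x2.get("ln_sl", 0.0) * x2.get(inner, 0.0)
        else:
            v1, v2 = x1.get(term, 0.0), x2.get(term, 0.0)
        total += b * (v1 - v2)
    return float(total)


def displacement_rate(source, kernel: MovementKernel, covariates_at_start: dict, hour) -> float:
    """Expected displacement (km/h at hourly fixes) from the updated kernel.

    The fitted ln(SL) coefficients correct the tentative gamma shape:
    ``k(x, hour) = k0 + b_lnSL + b_lnSL:sin_hour * sin(hour) + sum_z b_lnSL:z * z``
    with every z read at the step start; the expected step length is
    ``k * theta0``.
    """
    beta = _beta_of(source)
    sh = sin_hour(hour)
    k = kernel.shape + beta.get("ln_sl", 0.0) + beta.get("ln_sl:sin_hour", 0.0) * sh
    for term, b in beta.items():
        if term.startswith("ln_sl:") and term != "ln_sl:sin_hour":
            inner = term[len("ln_sl:") :]
            k += b * covariates_at_start.get(inner, 0.0)
    if k <= 0:
        raise ValueError(f"updated gamma shape {k:.4f} <= 0 at these covariates")
    return float(k * kernel.scale_km)


def _normalized_ranks(scores: np.ndarray, case: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Per-stratum rank of the used step among its candidates, in [0, 1].

    1 = used step beats every available step; 0.5 = indistinguishable from
    random scoring.  Ties count half.
    """
    out = []
    order = np.argsort(strata, kind="stable")
    scores, case, strata = scores[order], case[order], strata[order]
    starts = np.flatnonzero(np.r_[True, strata[1:] != strata[:-1]])
    ends = np.r_[starts[1:], strata.size]
    for s, e in zip(starts, ends):
        sc = scores[s:e]
        used = sc[case[s:e] == 1][0]
        avail = sc[case[s:e] == 0]
        out.append((np.sum(avail < used) + 0.5 * np.sum(avail == used)) / avail.size)
    return np.asarray(out)


def cross_validate_steps(
    strata: pd.DataFrame,
    spec: ModelSpec,
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Step-ID cross-validation of a candidate model.

    Folds partition strata (step IDs) — a stratum is never split.  Each fold
    is scored by the mean normalized rank of its used steps among their
    candidates under the linear predictor fitted on the remaining folds.

    Returns {"mean_rank": float, "fold_ranks": list, "fold_assignment": dict}.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.asarray(sorted(strata["stratum"].unique()))
    perm = rng.permutation(ids.size)
    fold_of = {int(ids[perm[i]]): i % n_folds for i in range(ids.size)}
    if min(np.bincount(list(fold_of.values()), minlength=n_folds)) == 0:
        raise ValueError("a fold has zero strata; reduce n_folds")
    fold_ranks = []
    fold_col = strata["stratum"].map(fold_of).to_numpy()
    for f in range(n_folds):
        train = strata[fold_col != f]
        test = strata[fold_col == f]
        X_tr = design_matrix(train, spec)
        est = ConditionalLogisticRegression().fit(
            X_tr, train["case"].to_numpy(), train["stratum"].to_numpy(), term_names=spec.terms
        )
        scores = est.decision_function(design_matrix(test, spec))
        ranks = _normalized_ranks(
            scores, test["case"].to_numpy(), test["stratum"].to_numpy()
        )
        fold_ranks.append(float(ranks.mean()))
    return {
        "mean_rank": float(np.mean(fold_ranks)),
        "fold_ranks": fold_ranks,
        "fold_assignment": fold_of,
    }
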