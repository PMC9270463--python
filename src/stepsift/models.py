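"""Candidate model specifications and AIC-based model comparison.

The step-selection candidate set contains seven competing hypotheses built
from three covariate blocks — prey/natural habitat, the linear-feature (LF)
network, and cutblocks — every one of which also carries ln(SL) and the
ln(SL):sin(hour) harmonic to absorb time-of-day variation in movement rates.
The kill-site candidate set re-expresses the same family on buffer
covariates, without movement terms.

Interaction terms are written ``ln_sl:<covariate>``; the covariate side of a
ln(SL) interaction is extracted at the *start* of the step (column
``<covariate>__start`` in the design frame), all main effects at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASE_TERMS = ("ln_sl", "ln_sl:sin_hour")
PREY_TERMS = (
    "pine",
    "deciduous",
    "mixed_forest",
    "coniferous",
    "ln_water",
    "ndvi",
    "ln_edge_in",
    "ln_edge_out",
)
LF_TERMS = ("lf_density", "ln_dist_lf", "ln_sl:ln_dist_lf", "ln_sl:lf_density")
CUT_TERMS = (
    "nc",
    "rc",
    "nc_cut_size",
    "rc_cut_size",
    "ln_sl:nc",
    "ln_sl:rc",
    "ln_sl:nc_cut_size",
    "ln_sl:rc_cut_size",
)

#: habitat covariates that appear on the start side of a ln(SL) interaction
START_EXTRACTED = ("ln_dist_lf", "lf_density", "nc", "rc", "nc_cut_size", "rc_cut_size")


@dataclass(frozen=True)
class ModelSpec:
    """A named, ordered term list for one candidate model."""

    name: str
    terms: tuple

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in spec {self.name!r}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def habitat_terms(self) -> tuple:
        return tuple(t for t in self.terms if not t.startswith("ln_sl"))

    def movement_terms(self) -> tuple:
        return tuple(t for t in self.terms if t.startswith("ln_sl"))


def candidate_model_set() -> list[ModelSpec]:
    """The seven step-selection candidate models.

    Every spec includes ln(SL) and ln(SL):sin(hour); the Global model is the
    union of all three covariate blocks (22 terms).
    """
    return [
        ModelSpec("Prey", BASE_TERMS + PREY_TERMS),
        ModelSpec("LF network", BASE_TERMS + LF_TERMS),
        ModelSpec("Cutblock", BASE_TERMS + CUT_TERMS),
        ModelSpec("Prey + LF network", BASE_TERMS + PREY_TERMS + LF_TERMS),
        ModelSpec("Prey + Cutblock", BASE_TERMS + PREY_TERMS + CUT_TERMS),
        ModelSpec("LFN + Cutblock", BASE_TERMS + LF_TERMS + CUT_TERMS),
        ModelSpec("Global", BASE_TERMS + PREY_TERMS + LF_TERMS + CUT_TERMS),
    ]


def global_spec() -> ModelSpec:
    return candidate_model_set()[-1]


KILL_PREY_TERMS = PREY_TERMS
KILL_LF_TERMS = ("lf_density", "ln_dist_lf")
KILL_CUT_TERMS = ("nc", "rc")


def killsite_model_set() -> list[ModelSpec]:
    """The candidate family re-expressed on kill-site buffer covariates.

    Land-cover and cut-class terms become within-buffer proportions; there
    are no movement (step-level) terms.  Cut-size terms are dropped: buffer
    proportions, not per-block sizes, describe a site.
    """
    return [
        ModelSpec("Prey", KILL_PREY_TERMS),
        ModelSpec("LF network", KILL_LF_TERMS),
        ModelSpec("Cutblock", KILL_CUT_TERMS),
        ModelSpec("Prey + LF network", KILL_PREY_TERMS + KILL_LF_TERMS),
        ModelSpec("Prey + Cutblock", KILL_PREY_TERMS + KILL_CUT_TERMS),
        ModelSpec("LFN + Cutblock", KILL_LF_TERMS + KILL_CUT_TERMS),
        ModelSpec("Global", KILL_PREY_TERMS + KILL_LF_TERMS + KILL_CUT_TERMS),
    ]


def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve one model term against a step/record design frame."""
    if term == "ln_sl":
        return df["ln_sl"].to_numpy(float)
    if term.startswith("ln_sl:"):
        inner = term[len("ln_sl:") :]
        if inner == "sin_hour":
            return (df["ln_sl"] * df["sin_hour"]).to_numpy(float)
        col = f"{inner}__start" if f"{inner}__start" in df.columns else inner
        return (df["ln_sl"] * df[col]).to_numpy(float)
    return df[term].to_numpy(float)


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Build the (n_rows, n_terms) design matrix for a spec."""
    return np.column_stack([term_column(df, t) for t in spec.terms])


def akaike_weights(aics) -> np.ndarray:
    """``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_selection_aic(fitted_models) -> pd.DataFrame:
    """AIC table with Akaike weights and per-animal best model.

    ``fitted_models`` is an iterable of fitted results carrying
    ``animal_id``, ``season``, ``spec_name``, ``aic`` and ``n_strata``.
    Models for the same animal-season must be fitted on identical strata.

    Returns a frame with one row per (animal, season, spec): ``aic``,
    ``delta_aic``, ``weight`` and ``best`` (bool).
    """
    rows = [
        {
            "animal_id": m.animal_id,
            "season": m.season,
            "spec_name": m.spec_name,
            "aic": m.aic,
            "n_strata": m.n_strata,
        }
        for m in fitted_models
    ]
    df = pd.DataFrame(rows)
    out = []
    for (animal, season), grp in df.groupby(["animal_id", "season"], sort=False):
        if grp["n_strata"].nunique() != 1:
            raise ValueError(
                f"models for animal {animal!r} season {season!r} were fitted on different data"
            )
        grp = grp.copy()
        grp["delta_aic"] = grp["aic"] - grp["aic"].min()
        grp["weight"] = akaike_weights(grp["aic"].to_numpy())
        grp["best"] = grp["aic"] == grp["aic"].min()
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def weight_distribution(aic_table: pd.DataFrame) -> pd.DataFrame:
    """Across-animal summary of Akaike weights per spec (the Fig.-2 analogue)."""
    return (
        aic_table.groupby("spec_name")["weight"]
        .agg(["mean", "median", "max"])
        .sort_values("mean", ascending=False)
        .reset_index()
    )
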