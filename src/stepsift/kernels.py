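"""Movement kernels: gamma step lengths and von Mises turn angles.

The tentative kernel proposes available steps; after a conditional-logistic
fit, the gamma shape is corrected by the ln(SL) coefficients (shape update
``k = k0 + beta_lnSL + sum_z beta_{lnSL:z} z``).  The turn-angle kernel has
mean 0 and is never updated (no cos(TA) terms appear in the model space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

#: cap applied to fitted von Mises concentration (near-degenerate headings)
KAPPA_CAP = 500.0

#: floor (km) applied to step lengths before ln(); half a typical GPS error
SL_FLOOR_KM = 0.005


class DegenerateDataError(ValueError):
    """Raised when kernel fitting receives degenerate inputs."""


@dataclass
class MovementKernel:
    """Tentative movement kernel.

    Parameters
    ----------
    shape : float
        Gamma shape ``k0`` of the step-length distribution (> 0).
    scale_km : float
        Gamma scale ``theta0`` in kilometres (> 0).
    kappa : float
        von Mises concentration of turn angles, mean fixed at 0 (>= 0).
    """

    shape: float
    scale_km: float
    kappa: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale_km <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def mean_step_km(self) -> float:
        return self.shape * self.scale_km

    def sample_steps(self, n, rng):
        """Draw (step lengths km, turn angles rad) of size n."""
        sl = rng.gamma(self.shape, self.scale_km, size=n)
        ta = rng.vonmises(0.0, self.kappa, size=n) if self.kappa > 0 else rng.uniform(-np.pi, np.pi, size=n)
        return sl, ta

    def updated_shape(self, beta_ln_sl: float, interaction_terms=()) -> float:
        """Post-fit gamma shape ``k0 + beta_lnSL + sum beta_z * z``.

        ``interaction_terms`` is an iterable of (coefficient, covariate value)
        pairs for every ln(SL) interaction (including sin_hour).
        """
        k = self.shape + beta_ln_sl + sum(b * z for b, z in interaction_terms)
        return k


def fit_gamma_sl(step_lengths_km) -> tuple[float, float]:
    """Gamma MLE (shape, scale) for step lengths, location fixed at 0."""
    sl = np.asarray(step_lengths_km, dtype=float)
    sl = np.maximum(sl, SL_FLOOR_KM)
    if sl.size < 30:
        raise DegenerateDataError("need at least 30 steps to fit the gamma kernel")
    if np.std(sl) < 1e-12 * max(1.0, float(np.mean(sl))):
        raise DegenerateDataError("step lengths have zero variance")
    shape, _, scale = stats.gamma.fit(sl, floc=0.0)
    return float(shape), float(scale)


def fit_vonmises_ta(turn_angles) -> float:
    """von Mises concentration MLE with the mean direction fixed at 0.

    Solves ``I1(kappa)/I0(kappa) = mean(cos(theta))``; negative mean
    resultants (angles concentrated away from 0) clamp to kappa = 0.
    """
    ta = np.asarray(turn_angles, dtype=float)
    if ta.size < 30:
        raise DegenerateDataError("need at least 30 turn angles to fit kappa")
    rbar = float(np.mean(np.cos(ta)))
    if rbar <= 0:
        return 0.0

    def a1(kappa):
        return special.i1e(kappa) / special.i0e(kappa)

    if a1(KAPPA_CAP) <= rbar:
        warnings.warn("turn angles nearly identical; capping kappa")
        return KAPPA_CAP
    return float(optimize.brentq(lambda k: a1(k) - rbar, 1e-12, KAPPA_CAP))


def fit_tentative_kernel(step_lengths_km, turn_angles) -> MovementKernel:
    """Fit the population-level tentative kernel by maximum likelihood.

    Step lengths pooled across individuals (per season, by the caller);
    gamma fitted to SL, von Mises (mean 0) to turn angles.
    """
    shape, scale = fit_gamma_sl(step_lengths_km)
    kappa = fit_vonmises_ta(turn_angles)
    return MovementKernel(shape=shape, scale_km=scale, kappa=kappa)
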