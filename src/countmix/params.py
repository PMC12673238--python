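"""Parameter blocks for the abundance, detection and availability processes.

Abundance follows a log-linear model

    log lambda_i = alpha1[species] + alpha2[site] + alpha3 * year
                   + alpha4[species] * restored_i

with species intercepts alpha1 ~ N(mu_alpha1, sigma_alpha1), species
restoration slopes alpha4 ~ N(mu_alpha4, sigma_alpha4) and site intercepts
alpha2 ~ N(0, sigma_alpha2). Detection is logit-linear with the analogous
beta block. Availability (the closure-violation process) is a per-individual,
per-survey Bernoulli with logit-linear probability theta0 + theta1 * restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

POISSON = "poisson"


def _check_sd(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite nonnegative number, got {value!r}")


@dataclass(frozen=True)
class AbundanceParams:
    """Community-level parameters of the log-linear abundance model."""

    mu_alpha1: float = 2.0
    sigma_alpha1: float = 0.5
    sigma_alpha2: float = 0.25
    alpha3: float = 0.25
    mu_alpha4: float = 1.0
    sigma_alpha4: float = 0.25
    #: NB dispersion; variance = lambda + lambda^2/phi. The string
    #: ``"poisson"`` selects a Poisson abundance distribution (phi -> inf).
    phi: float | str = POISSON

    def __post_init__(self):
        for name in ("sigma_alpha1", "sigma_alpha2", "sigma_alpha4"):
            _check_sd(name, getattr(self, name))
        if not self.is_poisson and not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError(f"phi must be positive or 'poisson', got {self.phi!r}")

    @property
    def is_poisson(self) -> bool:
        return isinstance(self.phi, str) and self.phi == POISSON


@dataclass(frozen=True)
class DetectionParams:
    """Community-level parameters of the logit-linear detection model."""

    mu_beta1: float = -2.0
    sigma_beta1: float = 0.5
    sigma_beta2: float = 0.25
    beta3: float = 0.25
    mu_beta4: float = 0.0
    sigma_beta4: float = 0.0

    def __post_init__(self):
        for name in ("sigma_beta1", "sigma_beta2", "sigma_beta4"):
            _check_sd(name, getattr(self, name))


@dataclass(frozen=True)
class AvailabilityParams:
    """Logit-linear per-individual, per-survey availability (temporary
    emigration). ``None`` in simulator signatures means closure holds
    (availability probability 1)."""

    theta0: float = 0.0
    theta1: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.theta0) and np.isfinite(self.theta1)):
            raise ValueError("theta0 and theta1 must be finite")

    def prob(self, restored) -> np.ndarray:
        """Availability probability for units with the given restored flag."""
        return expit(self.theta0 + self.theta1 * np.asarray(restored, dtype=float))


@dataclass(frozen=True)
class EffectTables:
    """Realized random effects: one row per species / per site."""

    species: pd.DataFrame  # columns alpha1, alpha4, beta1, beta4
    sites: pd.DataFrame  # columns alpha2, beta2


def linear_predictors(
    units: pd.DataFrame,
    ap: AbundanceParams,
    dp: DetectionParams | None,
    effects: EffectTables,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-unit (log lambda, logit p) from parameters and realized effects.

    ``units`` must have columns site, species, year, restored. Returns
    ``logit_p = None`` when ``dp`` is None (GLMM use).
    """
    sp = units["species"].to_numpy()
    site = units["site"].to_numpy()
    year = units["year"].to_numpy(dtype=float)
    restored = units["restored"].to_numpy(dtype=float)
    spt, sit = effects.species, effects.sites
    log_lam = (
        spt["alpha1"].to_numpy()[sp]
        + sit["alpha2"].to_numpy()[site]
        + ap.alpha3 * year
        + spt["alpha4"].to_numpy()[sp] * restored
    )
    if dp is None:
        return log_lam, None
    logit_p = (
        spt["beta1"].to_numpy()[sp]
        + sit["beta2"].to_numpy()[site]
        + dp.beta3 * year
        + spt["beta4"].to_numpy()[sp] * restored
    )
    return log_lam, logit_p
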