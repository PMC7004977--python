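"""Shared containers for abundance and density estimates.

All three estimators report through these types so that downstream
modules (effort surfaces, decision tree) can treat them uniformly.
Abundance-based methods are converted to density by dividing by an
effective sampled area (see :mod:`wildens.costs` for buffered areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class AbundanceEstimate:
    """Point estimate of abundance with uncertainty.

    ``ci95`` is a (lo, hi) tuple.  ``n_observed`` is the number of
    distinct individuals actually detected; a valid estimate can never
    fall below it.
    """

    N_hat: float
    se: float
    ci95: tuple[float, float]
    converged: bool
    log_likelihood: float
    n_observed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if self.converged and not (lo <= self.N_hat <= hi):
            raise ValueError(
                f"confidence interval ({lo}, {hi}) does not bracket N_hat={self.N_hat}"
            )
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")


@dataclass
class DensityEstimate:
    """Density (animals per km^2) with uncertainty.

    ``method`` is one of ``fecal_cr``, ``camera_secr``, ``removal``.
    ``area_km2`` is recorded when the density was obtained by dividing
    an abundance estimate by a buffered effective area; SECR estimates
    carry ``area_km2=None`` because density is estimated directly.
    """

    D_hat: float
    se: float
    ci95: tuple[float, float]
    method: str
    habitat: str | None = None
    area_km2: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.D_hat < 0:
            raise ValueError("density cannot be negative")
        lo, hi = self.ci95
        if self.converged and not (lo <= self.D_hat <= hi):
            raise ValueError("confidence interval does not bracket D_hat")


def abundance_to_density(
    est: AbundanceEstimate, area_km2: float, method: str, habitat: str | None = None
) -> DensityEstimate:
    """Convert abundance to density by dividing all summaries by area."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    lo, hi = est.ci95
    return DensityEstimate(
        D_hat=est.N_hat / area_km2,
        se=est.se / area_km2,
        ci95=(lo / area_km2, hi / area_km2),
        method=method,
        habitat=habitat,
        area_km2=area_km2,
        converged=est.converged,
    )


def lognormal_ci(N_hat: float, se: float, n_observed: int = 0) -> tuple[float, float]:
    """Lognormal 95% interval on (N_hat - n), conventional for closed CR.

    Falls back to a symmetric normal interval when the estimate equals
    the observed count (zero excess).
    """
    f0 = N_hat - n_observed
    if f0 <= 0 or se == 0:
        return (max(n_observed, N_hat - 1.959964 * se), N_hat + 1.959964 * se)
    import math

    c = math.exp(1.959964 * math.sqrt(math.log(1.0 + (se / f0) ** 2)))
    return (n_observed + f0 / c, n_observed + f0 * c)


__all__ = [
    "AbundanceEstimate",
    "DensityEstimate",
    "abundance_to_density",
    "lognormal_ci",
    "replace",
]
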