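"""Tissue-mimicking Intralipid/India-ink mixture design.

A scattering stock (Intralipid) and an absorbing stock (India ink) are
diluted to reach target optical properties.  The absorption of the
scatterer and the scattering of the absorber are assumed negligible, so
the two fractions decouple and each is a simple ratio of the target
coefficient to the measured per-fraction coefficient of its stock.

The per-fraction effective attenuation of a stock is measured by a
transmission-dilution series: collimated transmission through a fixed
path ``d`` at fractional concentration ``f`` follows the effective single
exponential ``T = exp(-mu_eff d f)``, fitted by ordinary least squares in
log-transmission space (which linearizes the model).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .light_transport import mu_eff

__all__ = [
    "MixtureRecipe",
    "TransmissionSeries",
    "fit_attenuation",
    "design_mixture",
]


@dataclass(frozen=True)
class TransmissionSeries:
    """Transmission fractions at fractional stock concentrations.

    ``fractions`` are dimensionless volume fractions of the stock in the
    final mixture (sorted ascending); ``transmission`` are the measured
    fractions in (0, 1] relative to the dye-free reference;
    ``path_length_cm`` is the fixed cuvette path.
    """

    fractions: tuple[float, ...]
    transmission: tuple[float, ...]
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        t = np.asarray(self.transmission, dtype=float)
        if f.size != t.size:
            raise ValueError("fractions and transmission differ in length")
        if np.any(np.diff(f) < 0):
            raise ValueError("fractions must be sorted ascending")
        if np.any(t > 1.0):
            raise ValueError("transmission fractions must be <= 1")
        if np.any(t <= 0.0):
            raise ValueError("transmission fractions must be > 0")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be > 0")


@dataclass(frozen=True)
class MixtureRecipe:
    """Chosen stock fractions and the optical properties they predict."""

    scatter_coeff_per_fraction: float   # 1/cm at f = 1
    absorb_coeff_per_fraction: float    # 1/cm at f = 1
    scatter_fraction: float
    absorb_fraction: float
    predicted_mu_a: float
    predicted_mu_s_prime: float

    @property
    def predicted_mu_eff(self) -> float:
        return mu_eff(self.predicted_mu_a, self.predicted_mu_s_prime)


def fit_attenuation(series: TransmissionSeries) -> float:
    """Effective attenuation (1/cm) from a transmission-dilution series.

    Fits ``T = exp(-mu_eff d f)`` by least squares in log space.  The
    model has no intercept (T = 1 at f = 0 by construction), so the
    estimate is the through-origin regression slope of ``-ln T`` on
    ``d f``.
    """
    f = np.asarray(series.fractions, dtype=float)
    if f.size < 3:
        raise ValueError("need >= 3 transmission points")
    t = np.asarray(series.transmission, dtype=float)
    x = series.path_length_cm * f
    y = -np.log(t)
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x, y) / denom)


def design_mixture(
    target_mu_a: float,
    target_mu_s_prime: float,
    scatter_coeff_per_fraction: float,
    absorb_coeff_per_fraction: float,
) -> MixtureRecipe:
    """Stock fractions achieving the target optical properties.

    Each fraction is target / per-fraction coefficient; a required
    fraction above 1 (stock not concentrated enough) is an infeasible
    recipe.
    """
    if target_mu_a <= 0 or target_mu_s_prime <= 0:
        raise ValueError("targets must be > 0")
    if scatter_coeff_per_fraction <= 0 or absorb_coeff_per_fraction <= 0:
        raise ValueError("per-fraction coefficients must be > 0")
    fs = target_mu_s_prime / scatter_coeff_per_fraction
    fa = target_mu_a / absorb_coeff_per_fraction
    if fs > 1 or fa > 1:
        raise ValueError(
            f"infeasible recipe: required fractions ({fs:.3g}, {fa:.3g}) exceed 1"
        )
    return MixtureRecipe(
        scatter_coeff_per_fraction=scatter_coeff_per_fraction,
        absorb_coeff_per_fraction=absorb_coeff_per_fraction,
        scatter_fraction=fs,
        absorb_fraction=fa,
        predicted_mu_a=fa * absorb_coeff_per_fraction,
        predicted_mu_s_prime=fs * scatter_coeff_per_fraction,
    )
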