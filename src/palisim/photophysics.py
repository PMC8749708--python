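"""Methylene-blue triplet-state kinetics and Stern-Volmer oxygen calibration.

The triplet state of methylene blue (MB) is populated by a short pump pulse
and decays at a rate ``kt`` that increases linearly with the oxygen partial
pressure through collisional quenching (the Stern-Volmer relation
``kt = kQ * pO2 + k0``).  This module provides the pumping kinetics, the
monomer-dimer equilibrium that sets the photoactive dye fraction, the
calibration/inversion between decay rate and pO2, and a simple
flash-photolysis transmission model used for rate validation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import constants as c

__all__ = [
    "PhotophysicalParams",
    "SternVolmerCal",
    "triplet_population",
    "pump_rate",
    "stern_volmer_rate",
    "calibrate_stern_volmer",
    "invert_to_pO2",
    "monomer_fraction",
    "triplet_absorption_coeff",
    "simulate_flash_photolysis",
]


@dataclass(frozen=True)
class PhotophysicalParams:
    """Photophysical parameters of the triplet-forming dye.

    Parameters
    ----------
    eta : float
        Triplet quantum yield (dimensionless, 0 < eta <= 1).
    sigma_g : float
        Ground-state absorption cross-section at the pump wavelength (cm^2).
    eps_triplet : float
        Decadic molar extinction coefficient of the triplet state at the
        probe wavelength (1/(M cm)).
    pump_pulse_duration : float
        Pump pulse duration (s).
    k_dim : float
        Monomer-dimer equilibrium constant K = [D]/[M]^2 (1/M).
    total_conc : float
        Total dye concentration (M).
    """

    eta: float = c.MB_TRIPLET_QUANTUM_YIELD
    sigma_g: float = c.MB_GROUND_CROSS_SECTION_CM2
    eps_triplet: float = c.MB_EXTINCTION_TRIPLET_830
    pump_pulse_duration: float = c.PUMP_PULSE_DURATION_S
    k_dim: float = c.MB_DIMERIZATION_K
    total_conc: float = c.MB_TOTAL_CONC_M

    def __post_init__(self) -> None:
        for name in ("eta", "sigma_g", "eps_triplet", "pump_pulse_duration",
                     "total_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.eta > 1:
            raise ValueError("triplet quantum yield eta must be <= 1")
        if self.k_dim < 0:
            raise ValueError("k_dim must be >= 0")

    @classmethod
    def from_yaml(cls, path=None) -> "PhotophysicalParams":
        """Load parameters from a YAML mapping (defaults to the shipped
        methylene-blue constants file)."""
        import yaml
        from importlib import resources

        if path is None:
            text = (
                resources.files("palisim") / "data" / "mb_defaults.yaml"
            ).read_text()
        else:
            with open(path) as f:
                text = f.read()
        raw = yaml.safe_load(text) or {}
        return cls(**{k: float(v) for k, v in raw.items()})


@dataclass(frozen=True)
class SternVolmerCal:
    """Stern-Volmer calibration kt = kQ * pO2 + k0.

    Attributes
    ----------
    kQ : float
        Oxygen quenching constant (1/(s mm Hg)).
    k0 : float
        Oxygen-independent triplet decay rate (1/s).
    """

    kQ: float = c.SV_KQ_1_S_MMHG
    k0: float = c.SV_K0_1_S

    def __post_init__(self) -> None:
        if self.kQ <= 0 or self.k0 <= 0:
            raise ValueError("kQ and k0 must be > 0")


def triplet_population(beta, n, alpha, t):
    """Triplet concentration after pumping at rate ``beta`` for time ``t``.

    Solves the two-state pumping model (ground -> triplet at rate ``beta``,
    triplet -> ground at rate ``alpha``) in closed form:

        nt = beta * n / (alpha + beta) * (1 - exp(-(alpha + beta) * t))

    Parameters are broadcast like NumPy ufuncs, so ``beta`` may be a
    per-voxel array.  The limit alpha + beta -> 0 returns 0.

    Parameters
    ----------
    beta : array_like
        Pumping rate into the triplet state (1/s), >= 0.
    n : float
        Total photoactive (monomer) dye concentration (M).
    alpha : float
        Triplet decay rate during the pulse (1/s), >= 0.
    t : float
        Pump pulse duration (s), >= 0.

    Returns
    -------
    ndarray or float
        Triplet concentration (M), in [0, n).
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or alpha < 0 or t < 0 or n < 0:
        raise ValueError("triplet_population arguments must be >= 0")
    total = alpha + beta
    with np.errstate(divide="ignore", invalid="ignore"):
        nt = np.where(
            total > 0,
            beta * n / np.where(total > 0, total, 1.0) * (-np.expm1(-total * t)),
            0.0,
        )
    if nt.ndim == 0:
        return float(nt)
    return nt


def pump_rate(params: PhotophysicalParams, fluence_rate, wavelength_nm: float):
    """Pumping rate beta = eta * sigma_g * phi / (h * nu) (1/s).

    Parameters
    ----------
    params : PhotophysicalParams
    fluence_rate : array_like
        Optical fluence rate phi at the pump wavelength (W/cm^2), >= 0.
    wavelength_nm : float
        Pump wavelength (nm), used to compute the photon energy h*nu.
    """
    fluence_rate = np.asarray(fluence_rate, dtype=float)
    if np.any(fluence_rate < 0):
        raise ValueError("fluence_rate must be >= 0")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    photon_energy = c.PLANCK_J_S * c.SPEED_OF_LIGHT_M_S / (wavelength_nm * 1e-9)
    beta = params.eta * params.sigma_g * fluence_rate / photon_energy
    if beta.ndim == 0:
        return float(beta)
    return beta


def stern_volmer_rate(cal: SternVolmerCal, pO2) -> float:
    """Triplet decay rate kt = kQ * pO2 + k0 (1/s) at partial pressure pO2."""
    pO2 = np.asarray(pO2, dtype=float)
    if np.any(pO2 < 0):
        raise ValueError("pO2 must be >= 0")
    kt = cal.kQ * pO2 + cal.k0
    return float(kt) if kt.ndim == 0 else kt


def calibrate_stern_volmer(points: Sequence[tuple[float, float]]) -> SternVolmerCal:
    """Least-squares Stern-Volmer calibration from (pO2, kt) pairs.

    With exactly two points the line interpolates them exactly; with more,
    this is the ordinary least-squares line.

    Raises
    ------
    ValueError
        Fewer than two points, or all pO2 values identical (degenerate).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (pO2, kt) points")
    pO2, kt = pts[:, 0], pts[:, 1]
    if np.ptp(pO2) == 0:
        raise ValueError("degenerate calibration: all pO2 values identical")
    kQ, k0 = np.polyfit(pO2, kt, 1)
    return SternVolmerCal(kQ=float(kQ), k0=float(k0))


def invert_to_pO2(cal: SternVolmerCal, kt: float) -> tuple[float, bool]:
    """Invert a measured decay rate to pO2 = (kt - k0) / kQ (mm Hg).

    Returns
    -------
    (pO2, clamped)
        ``clamped`` is True when ``kt < k0`` (physically impossible negative
        oxygen); the returned pressure is then clamped to 0.  A relative
        rate deficit below 1e-9 of k0 is treated as rounding, not flagged.
    """
    pO2 = (kt - cal.k0) / cal.kQ
    if pO2 < 0:
        return 0.0, (cal.k0 - kt) > 1e-9 * cal.k0
    return float(pO2), False


def monomer_fraction(total_conc: float, k_dim: float) -> float:
    """Equilibrium fraction of dye present as photoactive monomer.

    The monomer-dimer equilibrium D = K m^2 with mass balance
    total = m + 2 K m^2 is solved for the monomer concentration m; the
    returned value is m / total in (0, 1].
    """
    if total_conc <= 0:
        raise ValueError("total_conc must be > 0")
    if k_dim < 0:
        raise ValueError("k_dim must be >= 0")
    if k_dim == 0:
        return 1.0
    # positive root of 2K m^2 + m - total = 0, in the cancellation-free form
    # m = 2 * total / (1 + sqrt(1 + 8 K total))
    x = k_dim * total_conc
    return float(2.0 / (1.0 + np.sqrt(1.0 + 8.0 * x)))


def triplet_absorption_coeff(conc_triplet, eps_triplet: float):
    """Natural absorption coefficient mu_a = ln(10) * eps * c (1/cm).

    ``eps_triplet`` is decadic by the usual spectroscopic convention, hence
    the explicit ln(10) conversion to the natural coefficient expected by
    the photoacoustic pressure relation.
    """
    conc_triplet = np.asarray(conc_triplet, dtype=float)
    if np.any(conc_triplet < 0) or eps_triplet < 0:
        raise ValueError("concentration and eps_triplet must be >= 0")
    mua = c.LN10 * eps_triplet * conc_triplet
    return float(mua) if mua.ndim == 0 else mua


def simulate_flash_photolysis(
    params: PhotophysicalParams,
    kt: float,
    path_length_cm: float,
    initial_triplet: float,
    times_s,
    baseline_mua: float = 0.0,
) -> np.ndarray:
    """Probe-beam transmission during triplet decay (flash photolysis).

    After the pump pulse the triplet population decays as
    ``T0 * exp(-kt t)`` and the probe transmission through a cuvette of
    path length L recovers as ``T(t) = exp(-mu_a(t) * L)`` relative to the
    dye-free baseline.

    Parameters
    ----------
    params : PhotophysicalParams
        Supplies the triplet extinction coefficient.
    kt : float
        Triplet decay rate (1/s).
    path_length_cm : float
        Probe path length through the sample (cm), > 0.
    initial_triplet : float
        Triplet concentration at t = 0 (M).
    times_s : array_like
        Sample times (s), sorted ascending.
    baseline_mua : float, optional
        Triplet-independent background absorption (1/cm).

    Returns
    -------
    ndarray
        Transmission fraction at each time, monotonically recovering
        toward the baseline ``exp(-baseline_mua * L)``.
    """
    times = np.asarray(times_s, dtype=float)
    if path_length_cm <= 0:
        raise ValueError("path_length must be > 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if initial_triplet < 0:
        raise ValueError("initial_triplet must be >= 0")
    conc = initial_triplet * np.exp(-kt * times)
    mua = baseline_mua + triplet_absorption_coeff(conc, params.eps_triplet)
    return np.exp(-np.asarray(mua) * path_length_cm)
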