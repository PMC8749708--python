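"""Photon-packet Monte Carlo fluence simulation in a voxelized phantom.

The tissue is a rectangular voxel grid with a spherical dye-loaded node
embedded below the illuminated (z = 0) surface.  Light transport uses the
standard photon-packet scheme: packets are launched over a circular beam,
scattering lengths are sampled from the local scattering coefficient,
directions from the Henyey-Greenstein phase function, and packet weight is
attenuated continuously by absorption along each sub-step.  Fluence is
scored with a track-length estimator, which stays well defined in
non-absorbing voxels and reduces exactly to the incident fluence in the
vacuum limit.  Boundaries are refractive-index matched: packets that leave
the grid escape.

Diffusion theory supplies the closed-form effective attenuation
coefficient ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))`` used to validate the
deep-fluence slope of the Monte Carlo.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from . import constants as c
from .photophysics import triplet_absorption_coeff

__all__ = [
    "OpticalProperties",
    "BeamSpec",
    "VoxelPhantom",
    "FluenceMap",
    "build_phantom",
    "monte_carlo_fluence",
    "mu_eff",
    "update_probe_absorption",
]

_WEIGHT_MIN = 1e-4
_ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties at one wavelength.

    mu_a and mu_s_prime are in 1/cm; g is the Henyey-Greenstein anisotropy.
    The full scattering coefficient used by the transport kernel is
    ``mu_s = mu_s_prime / (1 - g)``.
    """

    mu_a: float
    mu_s_prime: float
    g: float = c.ANISOTROPY_G
    wavelength: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("mu_a and mu_s_prime must be >= 0")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must be in (-1, 1)")

    @property
    def mu_s(self) -> float:
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_eff(self) -> float:
        return mu_eff(self.mu_a, self.mu_s_prime)


@dataclass(frozen=True)
class BeamSpec:
    """Circular surface beam, axis normal to the z = 0 face.

    pulse_fluence is in mJ/cm^2 per pulse; pulse_duration in seconds.
    """

    radius_mm: float = c.BEAM_RADIUS_MM
    pulse_fluence_mj_cm2: float = c.PUMP_FLUENCE_MJ_CM2
    wavelength: float = c.PUMP_WAVELENGTH_NM
    pulse_duration: float = c.PUMP_PULSE_DURATION_S

    def __post_init__(self) -> None:
        if self.pulse_fluence_mj_cm2 <= 0 or self.radius_mm <= 0:
            raise ValueError("beam radius and pulse fluence must be > 0")

    @property
    def pulse_energy_mj(self) -> float:
        """Total pulse energy (mJ) entering the surface."""
        area_cm2 = math.pi * (self.radius_mm / 10.0) ** 2
        return self.pulse_fluence_mj_cm2 * area_cm2


@dataclass
class VoxelPhantom:
    """Voxel grid of optical properties with an embedded spherical node.

    The grid spans ``shape * voxel_mm`` millimetres with the illuminated
    surface at z = 0 and depth increasing with the third axis.  Background
    optical properties are stored per wavelength; per-voxel absorption
    overrides (used for the triplet-updated probe run) take precedence
    over the analytic background + node composition.
    """

    shape: tuple[int, int, int]
    voxel_mm: float
    optics: dict[float, OpticalProperties]
    node_center_mm: tuple[float, float, float]
    node_radius_mm: float
    node_conc: float = c.MB_TOTAL_CONC_M
    node_extinction: dict[float, float] = field(default_factory=dict)
    mua_override: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be > 0")
        ext = np.asarray(self.extent_mm)
        ctr = np.asarray(self.node_center_mm)
        if self.node_radius_mm < 0:
            raise ValueError("node radius must be >= 0")
        if np.any(ctr - self.node_radius_mm < 0) or np.any(
            ctr + self.node_radius_mm > ext
        ):
            raise ValueError("node extends outside the phantom grid")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_mm for s in self.shape)

    @property
    def node_depth_mm(self) -> float:
        return self.node_center_mm[2]

    def voxel_centers(self):
        """Coordinate vectors (mm) of voxel centers along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * self.voxel_mm for n in self.shape
        )

    def node_mask(self) -> np.ndarray:
        """Boolean mask of voxels whose centers fall inside the node."""
        if self.node_radius_mm == 0:
            return np.zeros(self.shape, dtype=bool)
        xs, ys, zs = self.voxel_centers()
        dx = xs[:, None, None] - self.node_center_mm[0]
        dy = ys[None, :, None] - self.node_center_mm[1]
        dz = zs[None, None, :] - self.node_center_mm[2]
        return dx * dx + dy * dy + dz * dz <= self.node_radius_mm**2

    def _background(self, wavelength: float) -> OpticalProperties:
        try:
            return self.optics[wavelength]
        except KeyError:
            raise KeyError(
                f"no optical properties defined at {wavelength} nm"
            ) from None

    def mua_map(self, wavelength: float) -> np.ndarray:
        """Per-voxel absorption coefficient (1/cm) at ``wavelength``.

        The map is background tissue absorption plus, inside the node, the
        ground-state absorption of the photoactive dye (decadic extinction
        from ``node_extinction``); an explicit override replaces all of it.
        """
        if wavelength in self.mua_override:
            return self.mua_override[wavelength].copy()
        bg = self._background(wavelength)
        mua = np.full(self.shape, bg.mu_a)
        eps = self.node_extinction.get(wavelength, 0.0)
        if eps and self.node_radius_mm > 0:
            mua[self.node_mask()] += triplet_absorption_coeff(
                self.node_conc, eps
            )
        return mua

    def dye_mua(self, wavelength: float) -> np.ndarray:
        """Per-voxel dye-only absorption (1/cm): the node's ground-state
        dye contribution, zero elsewhere."""
        mua = np.zeros(self.shape)
        eps = self.node_extinction.get(wavelength, 0.0)
        if eps and self.node_radius_mm > 0:
            mua[self.node_mask()] = triplet_absorption_coeff(
                self.node_conc, eps
            )
        return mua

    def mus_map(self, wavelength: float) -> np.ndarray:
        bg = self._background(wavelength)
        return np.full(self.shape, bg.mu_s)


@dataclass
class FluenceMap:
    """Per-voxel optical fluence (J/cm^2 per pulse) on the phantom grid."""

    values: np.ndarray
    wavelength: float
    n_photons: int
    seed: int
    voxel_mm: float
    energy_budget: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("fluence values must be finite and >= 0")


def mu_eff(mu_a: float, mu_s_prime: float) -> float:
    """Diffusion-theory effective attenuation sqrt(3 mu_a (mu_a + mu_s')) in 1/cm."""
    if mu_a < 0 or mu_s_prime < 0:
        raise ValueError("optical coefficients must be >= 0")
    return math.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))


def build_phantom(
    depth_mm: float,
    node_radius_mm: float = c.NODE_RADIUS_MM,
    node_conc: float = c.MB_TOTAL_CONC_M,
    monomer_conc: Optional[float] = None,
    grid_size_mm: tuple[float, float, float] = c.GRID_SIZE_MM,
    voxel_mm: float = c.VOXEL_SIZE_MM,
    optics: Optional[dict[float, OpticalProperties]] = None,
    dye_extinction_pump: float = c.MB_EXTINCTION_GROUND_660,
) -> VoxelPhantom:
    """Build the neck-tissue phantom with a dye-loaded node at ``depth_mm``.

    The node center sits on the beam axis (lateral grid center) at
    ``depth_mm`` below the illuminated surface.  ``monomer_conc`` is the
    photoactive monomer concentration inside the node; only the monomer
    absorbs at the pump wavelength (dimers merely sequester dye).  When not
    given it defaults to ``node_conc`` (no dimerization correction here;
    the acquisition layer applies the monomer fraction).
    """
    if optics is None:
        optics = {
            c.PUMP_WAVELENGTH_NM: OpticalProperties(
                c.TISSUE_MUA_660, c.TISSUE_MUSP_660, wavelength=c.PUMP_WAVELENGTH_NM
            ),
            c.PROBE_WAVELENGTH_NM: OpticalProperties(
                c.TISSUE_MUA_830, c.TISSUE_MUSP_830, wavelength=c.PROBE_WAVELENGTH_NM
            ),
        }
    shape = tuple(int(round(s / voxel_mm)) for s in grid_size_mm)
    center = (grid_size_mm[0] / 2.0, grid_size_mm[1] / 2.0, depth_mm)
    conc = node_conc if monomer_conc is None else monomer_conc
    wavelengths = sorted(optics)
    pump_wl = wavelengths[0]
    return VoxelPhantom(
        shape=shape,
        voxel_mm=voxel_mm,
        optics=dict(optics),
        node_center_mm=center,
        node_radius_mm=node_radius_mm,
        node_conc=conc,
        node_extinction={pump_wl: dye_extinction_pump},
    )


@njit(cache=True, fastmath=True)
def _mc_kernel(mua, mus, g, dv_cm, n_photons, beam_radius_cm, cx, cy, seed):
    """Single-threaded photon-packet transport; returns track-length tally
    (weight * cm per voxel) and the energy budget
    (absorbed, escaped, roulette_net)."""
    nx, ny, nz = mua.shape
    tally = np.zeros((nx, ny, nz))
    np.random.seed(seed)
    absorbed = 0.0
    escaped = 0.0
    roulette_net = 0.0
    inv_dv = 1.0 / dv_cm
    nudge = 1e-9 * dv_cm
    big = 1e30
    for _ in range(n_photons):
        r = beam_radius_cm * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = cx + r * math.cos(phi)
        y = cy + r * math.sin(phi)
        z = nudge
        ux = 0.0
        uy = 0.0
        uz = 1.0
        inv_ux = big
        inv_uy = big
        inv_uz = 1.0
        ix = int(x * inv_dv)
        iy = int(y * inv_dv)
        iz = 0
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            escaped += 1.0
            continue
        w = 1.0
        tau = -math.log(np.random.random())
        while True:
            m_s = mus[ix, iy, iz]
            m_a = mua[ix, iy, iz]
            # distance to the voxel boundary along the current direction
            if ux > 0.0:
                dx_b = ((ix + 1) * dv_cm - x) * inv_ux
            elif ux < 0.0:
                dx_b = (ix * dv_cm - x) * inv_ux
            else:
                dx_b = big
            if uy > 0.0:
                dy_b = ((iy + 1) * dv_cm - y) * inv_uy
            elif uy < 0.0:
                dy_b = (iy * dv_cm - y) * inv_uy
            else:
                dy_b = big
            if uz > 0.0:
                dz_b = ((iz + 1) * dv_cm - z) * inv_uz
            elif uz < 0.0:
                dz_b = (iz * dv_cm - z) * inv_uz
            else:
                dz_b = big
            axis = 0
            d_bound = dx_b
            if dy_b < d_bound:
                d_bound = dy_b
                axis = 1
            if dz_b < d_bound:
                d_bound = dz_b
                axis = 2
            if d_bound < 0.0:
                d_bound = 0.0
            d_scat = tau / m_s if m_s > 0.0 else big
            scatter_here = d_scat <= d_bound
            ds = d_scat if scatter_here else d_bound
            # continuous absorption along the sub-step, track-length fluence
            if m_a > 0.0:
                lost = w * -math.expm1(-m_a * ds)
                tally[ix, iy, iz] += lost / m_a
                absorbed += lost
                w -= lost
            else:
                tally[ix, iy, iz] += w * ds
            if scatter_here:
                x += ux * ds
                y += uy * ds
                z += uz * ds
                tau = -math.log(np.random.random())
                # Henyey-Greenstein deflection
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    cost = 2.0 * np.random.random() - 1.0
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
                sint = math.sqrt(1.0 - cost * cost)
                psi = 2.0 * math.pi * np.random.random()
                cosp = math.cos(psi)
                sinp = math.sin(psi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    uz_n = -sint * cosp * den + uz * cost
                    ux, uy, uz = ux_n, uy_n, uz_n
                norm = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
                ux *= norm
                uy *= norm
                uz *= norm
                inv_ux = 1.0 / ux if ux != 0.0 else big
                inv_uy = 1.0 / uy if uy != 0.0 else big
                inv_uz = 1.0 / uz if uz != 0.0 else big
                if w < _WEIGHT_MIN:
                    if np.random.random() < _ROULETTE_SURVIVAL:
                        gained = w * (1.0 / _ROULETTE_SURVIVAL - 1.0)
                        roulette_net -= gained
                        w += gained
                    else:
                        roulette_net += w
                        break
            else:
                tau -= m_s * d_bound
                if tau < 0.0:
                    tau = 0.0
                x += ux * d_bound
                y += uy * d_bound
                z += uz * d_bound
                # step the crossed index; kill the packet when it leaves
                if axis == 0:
                    ix += 1 if ux > 0.0 else -1
                    if ix < 0 or ix >= nx:
                        escaped += w
                        break
                elif axis == 1:
                    iy += 1 if uy > 0.0 else -1
                    if iy < 0 or iy >= ny:
                        escaped += w
                        break
                else:
                    iz += 1 if uz > 0.0 else -1
                    if iz < 0 or iz >= nz:
                        escaped += w
                        break
    return tally, absorbed, escaped, roulette_net


def monte_carlo_fluence(
    phantom: VoxelPhantom,
    beam: BeamSpec,
    n_photons: int,
    seed: int,
    mua_map: Optional[np.ndarray] = None,
) -> FluenceMap:
    """Run the photon-packet Monte Carlo and return the fluence map.

    The map is normalized so that the total launched energy equals the
    beam pulse fluence times the beam area; voxel values are therefore
    J/cm^2 per pulse.  Results are bit-identical for a fixed seed.

    Parameters
    ----------
    phantom : VoxelPhantom
    beam : BeamSpec
        Beam centered on the phantom's lateral center.
    n_photons : int
        Number of photon packets (>= 1).
    seed : int
        Seed for the transport RNG.
    mua_map : ndarray, optional
        Explicit absorption map (1/cm) overriding
        ``phantom.mua_map(beam.wavelength)``.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mua = phantom.mua_map(beam.wavelength) if mua_map is None else mua_map
    mus = phantom.mus_map(beam.wavelength)
    if np.any(mua < 0) or np.any(mus < 0):
        raise ValueError("optical properties must be >= 0")
    g = phantom._background(beam.wavelength).g
    dv_cm = phantom.voxel_mm / 10.0
    ext = phantom.extent_mm
    tally, absorbed, escaped, roulette_net = _mc_kernel(
        np.ascontiguousarray(mua, dtype=np.float64),
        np.ascontiguousarray(mus, dtype=np.float64),
        float(g),
        dv_cm,
        int(n_photons),
        beam.radius_mm / 10.0,
        ext[0] / 20.0,
        ext[1] / 20.0,
        int(seed) & 0x7FFFFFFF,
    )
    energy_j = beam.pulse_energy_mj * 1e-3
    per_photon_j = energy_j / n_photons
    fluence = tally * per_photon_j / dv_cm**3
    budget = {
        "launched": float(n_photons),
        "absorbed": float(absorbed),
        "escaped": float(escaped),
        "roulette_net": float(roulette_net),
    }
    return FluenceMap(
        values=fluence,
        wavelength=beam.wavelength,
        n_photons=int(n_photons),
        seed=int(seed),
        voxel_mm=phantom.voxel_mm,
        energy_budget=budget,
    )


def update_probe_absorption(
    phantom: VoxelPhantom,
    triplet_map: np.ndarray,
    eps_triplet: float,
    wavelength: float = c.PROBE_WAVELENGTH_NM,
) -> VoxelPhantom:
    """Return a phantom whose probe-wavelength absorption includes the
    pumped triplet population.

    ``triplet_map`` is the per-voxel triplet concentration (M); it must be
    zero outside the node.  The new phantom's probe mu_a is the background
    map plus ``ln(10) * eps_triplet * triplet_map``.
    """
    triplet_map = np.asarray(triplet_map, dtype=float)
    if triplet_map.shape != phantom.shape:
        raise ValueError("triplet_map shape does not match phantom grid")
    if np.any(triplet_map < 0):
        raise ValueError("triplet concentrations must be >= 0")
    outside = ~phantom.node_mask()
    if np.any(triplet_map[outside] != 0):
        raise ValueError("triplet_map must be zero outside the node")
    mua = phantom.mua_map(wavelength) + triplet_absorption_coeff(
        triplet_map, eps_triplet
    )
    override = dict(phantom.mua_override)
    override[wavelength] = mua
    return replace(phantom, mua_override=override)
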