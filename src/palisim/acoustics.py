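"""Photoacoustic pressure generation, transducer projection, and noise.

The absorbed optical energy density ``mu_a * phi`` (J/cm^3) converts to an
initial pressure ``P = Gamma * mu_a * phi`` through the dimensionless
Grueneisen parameter; with mu_a in 1/cm and phi in J/cm^2 the numerical
value of P is in MPa (1 J/cm^3 = 1 MPa).

Detection by a focused single-element transducer is modeled as a far-field
time-of-flight projection: each voxel contributes its pressure at delay
``r / c`` with 1/r spherical spreading and an aperture (directivity)
weight, and the summed trace is band-limited by a zero-phase Gaussian
response around the transducer center frequency.  Tissue acoustic
attenuation is neglected.

Receiver noise is additive zero-mean Gaussian whose per-sample standard
deviation is the noise-equivalent pressure (NEP); ``compute_nep`` estimates
the NEP of a real receiver from a paired transducer/hydrophone measurement
as ``NEP = Unoise * Hsig / Usig``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import constants as c
from .light_transport import FluenceMap

__all__ = [
    "TransducerSpec",
    "PressureMap",
    "RFTrace",
    "NoiseModel",
    "initial_pressure",
    "project_to_transducer",
    "add_noise",
    "compute_nep",
    "snr",
]


@dataclass(frozen=True)
class TransducerSpec:
    """Focused single-element transducer.

    ``position_mm`` is the element center; the focal point lies
    ``focal_length_mm`` along the +z axis from it (pointing into the
    phantom).  The default geometry focuses on the node center from
    directly above.
    """

    center_frequency_mhz: float = c.XDCR_CENTER_FREQ_MHZ
    fractional_bandwidth: float = c.XDCR_FRACTIONAL_BW
    element_diameter_mm: float = c.XDCR_ELEMENT_DIAMETER_MM
    focal_length_mm: float = c.XDCR_FOCAL_LENGTH_MM
    position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sampling_rate_mhz: float = c.SAMPLING_RATE_MHZ

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0:
            raise ValueError("center_frequency must be > 0")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.focal_length_mm <= 0 or self.element_diameter_mm <= 0:
            raise ValueError("transducer geometry must be positive")

    @property
    def focus_mm(self) -> tuple[float, float, float]:
        x, y, z = self.position_mm
        return (x, y, z + self.focal_length_mm)

    @classmethod
    def focused_on(cls, focus_mm, **kwargs) -> "TransducerSpec":
        """Transducer placed on the z axis above ``focus_mm`` so that the
        focal point coincides with it."""
        fl = kwargs.pop("focal_length_mm", c.XDCR_FOCAL_LENGTH_MM)
        x, y, z = focus_mm
        return cls(
            focal_length_mm=fl, position_mm=(x, y, z - fl), **kwargs
        )


@dataclass
class PressureMap:
    """Per-voxel initial pressure (MPa) on the phantom grid."""

    values: np.ndarray
    voxel_mm: float
    grueneisen: float = c.GRUENEISEN

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("initial pressure must be >= 0")


@dataclass
class RFTrace:
    """Sampled receive trace in pressure-equivalent units.

    Time origin is at laser firing; sample ``i`` is at
    ``i / sampling_rate`` microseconds.
    """

    samples: np.ndarray
    sampling_rate_mhz: float = c.SAMPLING_RATE_MHZ
    speed_of_sound: float = c.SPEED_OF_SOUND_M_S
    focus_warning: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(~np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_mhz

    def window_slice(self, window_us: tuple[float, float]) -> slice:
        lo, hi = window_us
        fs = self.sampling_rate_mhz
        i0 = max(0, int(math.floor(lo * fs)))
        i1 = min(self.samples.size, int(math.ceil(hi * fs)) + 1)
        return slice(i0, i1)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian receiver noise of std ``nep`` (MPa) per sample."""

    nep: float = c.NEP_MPA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nep < 0:
            raise ValueError("nep must be >= 0")


def initial_pressure(
    grueneisen: float, mua_map: np.ndarray, fluence_map: FluenceMap
) -> PressureMap:
    """Initial pressure P = Gamma * mu_a * phi, voxelwise, in MPa.

    ``mua_map`` (1/cm) selects which absorber generates the signal (e.g.,
    the triplet-state contribution only); it must share the fluence grid.
    """
    mua_map = np.asarray(mua_map, dtype=float)
    if mua_map.shape != fluence_map.values.shape:
        raise ValueError("mu_a map and fluence map grids do not match")
    values = grueneisen * mua_map * fluence_map.values
    return PressureMap(
        values=values, voxel_mm=fluence_map.voxel_mm, grueneisen=grueneisen
    )


def _gaussian_bandpass(samples: np.ndarray, fs_mhz: float, f0_mhz: float,
                       fractional_bw: float) -> np.ndarray:
    """Zero-phase Gaussian band-pass around f0 (applied in the frequency
    domain, so pulse arrival times are preserved)."""
    n = samples.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_mhz)
    fwhm = fractional_bw * f0_mhz
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    h = np.exp(-0.5 * ((freqs - f0_mhz) / sigma) ** 2)
    return np.fft.irfft(np.fft.rfft(samples) * h, n)


def project_to_transducer(
    pressure: PressureMap,
    xdcr: TransducerSpec,
    sos: float = c.SPEED_OF_SOUND_M_S,
    n_samples: Optional[int] = None,
) -> RFTrace:
    """Far-field time-of-flight projection of an initial pressure map.

    Each voxel contributes ``p * V / (4 pi r)`` at delay ``r / sos`` with a
    cosine directivity weight inside the aperture half-angle
    ``atan((D/2) / F)``; contributions are linearly interpolated onto the
    sample grid and the trace is band-limited by the transducer response.
    Output units are MPa * mm^2 (uncalibrated receive units).
    """
    vals = pressure.values
    dv = pressure.voxel_mm
    shape = vals.shape
    pos = np.asarray(xdcr.position_mm, dtype=float)
    focus = np.asarray(xdcr.focus_mm)
    extent = np.asarray(shape) * dv
    focus_warning = bool(np.any(focus < 0) or np.any(focus > extent))

    fs = xdcr.sampling_rate_mhz
    sos_mm_us = sos / 1000.0  # mm per us
    if n_samples is None:
        diag = float(np.linalg.norm(extent))
        standoff = float(np.linalg.norm(pos - extent / 2.0)) + diag
        n_samples = int(math.ceil((standoff / sos_mm_us) * fs)) + 64

    trace = np.zeros(n_samples)
    nz_idx = np.nonzero(vals)
    if nz_idx[0].size:
        coords = (
            np.stack(nz_idx, axis=1).astype(float) + 0.5
        ) * dv  # voxel centers, mm
        rel = coords - pos
        r = np.linalg.norm(rel, axis=1)
        axis = (focus - pos) / np.linalg.norm(focus - pos)
        cos_theta = (rel @ axis) / r
        theta_max = math.atan2(xdcr.element_diameter_mm / 2.0,
                               xdcr.focal_length_mm)
        weight = np.where(cos_theta >= math.cos(theta_max), cos_theta, 0.0)
        amp = vals[nz_idx] * dv**3 * weight / (4.0 * math.pi * r)
        t_idx = (r / sos_mm_us) * fs
        i0 = np.floor(t_idx).astype(int)
        frac = t_idx - i0
        valid = i0 < n_samples - 1
        np.add.at(trace, i0[valid], amp[valid] * (1.0 - frac[valid]))
        np.add.at(trace, i0[valid] + 1, amp[valid] * frac[valid])
        trace = _gaussian_bandpass(
            trace, fs, xdcr.center_frequency_mhz, xdcr.fractional_bandwidth
        )
    return RFTrace(
        samples=trace,
        sampling_rate_mhz=fs,
        speed_of_sound=sos,
        focus_warning=focus_warning,
    )


def add_noise(trace: RFTrace, noise: NoiseModel) -> RFTrace:
    """Add i.i.d. zero-mean Gaussian samples with std ``noise.nep``."""
    if noise.nep == 0:
        return RFTrace(trace.samples.copy(), trace.sampling_rate_mhz,
                       trace.speed_of_sound, trace.focus_warning)
    rng = np.random.default_rng(noise.seed)
    noisy = trace.samples + rng.normal(0.0, noise.nep, trace.samples.size)
    return RFTrace(noisy, trace.sampling_rate_mhz, trace.speed_of_sound,
                   trace.focus_warning)


def compute_nep(
    u_trace: RFTrace,
    h_trace: RFTrace,
    arrival_window_us: tuple[float, float],
) -> float:
    """Noise-equivalent pressure NEP = Unoise * Hsig / Usig.

    ``Unoise`` is the RMS of the transducer trace before the arrival
    window, ``Hsig``/``Usig`` the peak-to-peak of the calibrated hydrophone
    / transducer responses within it.
    """
    lo, hi = arrival_window_us
    pre = u_trace.samples[: u_trace.window_slice((0.0, lo)).stop - 1]
    if pre.size == 0:
        raise ValueError("no pre-arrival segment before the window")
    u_sig = u_trace.samples[u_trace.window_slice((lo, hi))]
    h_sig = h_trace.samples[h_trace.window_slice((lo, hi))]
    if u_sig.size == 0 or h_sig.size == 0:
        raise ValueError("arrival window contains no samples")
    usig = float(np.ptp(u_sig))
    if usig == 0:
        raise ValueError("no detectable transducer signal in the window")
    unoise = float(np.sqrt(np.mean(pre**2)))
    hsig = float(np.ptp(h_sig))
    return unoise * hsig / usig


def snr(
    trace: RFTrace,
    signal_window_us: tuple[float, float],
    noise_window_us: tuple[float, float],
) -> float:
    """Peak-to-peak signal over twice the RMS noise (dimensionless).

    Returns ``inf`` when the noise window is exactly silent.
    """
    s_lo, s_hi = signal_window_us
    n_lo, n_hi = noise_window_us
    if not (s_hi <= n_lo or n_hi <= s_lo):
        raise ValueError("signal and noise windows must be disjoint")
    sig = trace.samples[trace.window_slice(signal_window_us)]
    noi = trace.samples[trace.window_slice(noise_window_us)]
    if sig.size == 0 or noi.size == 0:
        raise ValueError("zero-length window")
    rms = float(np.sqrt(np.mean(noi**2)))
    ptp = float(np.ptp(sig))
    if rms == 0:
        return math.inf
    return ptp / (2.0 * rms)
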