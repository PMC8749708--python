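"""Pump-probe acquisition protocol and triplet decay-rate recovery.

An acquisition steps a pump-probe delay through a log-spaced schedule.  At
each delay the probe photoacoustic amplitude tracks the remaining triplet
population ``exp(-kt * tau)``.  Each recorded frame also contains the pump
laser's own photoacoustic artifact (ground-state dye and tissue
absorption), which is measured separately in pump-only frames and
subtracted.  Amplitudes are normalized by pulse energy, averaged over
repeated frames, background-subtracted against the longest delay (where
the triplet state has fully decayed), and fitted with a single or double
exponential; the fitted (for the double model: slower) rate is the triplet
decay rate used for Stern-Volmer oxygen inversion.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from . import constants as c
from .acoustics import (
    NoiseModel,
    RFTrace,
    TransducerSpec,
    initial_pressure,
    project_to_transducer,
    snr as _snr,
)
from .light_transport import (
    BeamSpec,
    VoxelPhantom,
    monte_carlo_fluence,
    update_probe_absorption,
)
from .photophysics import (
    PhotophysicalParams,
    SternVolmerCal,
    monomer_fraction,
    pump_rate,
    stern_volmer_rate,
    triplet_absorption_coeff,
    triplet_population,
)
from .seeds import stage_seed

__all__ = [
    "DelaySchedule",
    "PaliFrame",
    "PaliDataset",
    "DecayFit",
    "CleanTraces",
    "delay_schedule",
    "simulate_clean_traces",
    "acquire_from_traces",
    "simulate_acquisition",
    "subtract_pump_artifact",
    "subtract_background",
    "normalize_by_energy",
    "extract_amplitude",
    "fit_decay",
]

RATE_BOUNDS = (1e2, 1e8)


@dataclass(frozen=True)
class DelaySchedule:
    """Strictly increasing pump-probe delays in microseconds."""

    delays_us: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.delays_us)
        if d.size < 2 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("delays must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.delays_us)


def delay_schedule(
    n: int = c.N_DELAYS,
    t_min_us: float = c.DELAY_MIN_US,
    t_max_us: float = c.DELAY_MAX_US,
) -> DelaySchedule:
    """Geometric progression of ``n`` delays from t_min to t_max inclusive."""
    if n < 2:
        raise ValueError("need at least 2 delays")
    if not 0 < t_min_us < t_max_us:
        raise ValueError("require 0 < t_min < t_max")
    return DelaySchedule(tuple(np.geomspace(t_min_us, t_max_us, n)))


@dataclass
class PaliFrame:
    """One recorded RF frame (possibly an average of repeated firings).

    ``pulse_energy`` is the energy of the analysed laser pulse (probe for
    pump-probe frames, pump for pump-only frames) in mJ; ``pump_energy``
    additionally records the pump pulse energy for artifact rescaling.
    """

    rf: RFTrace
    delay_us: float
    kind: str  # "pump-probe" | "pump-only"
    pulse_energy: float
    pump_energy: float
    replicate: int = 0
    n_averaged: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("pump-probe", "pump-only"):
            raise ValueError("kind must be 'pump-probe' or 'pump-only'")
        if self.pulse_energy <= 0 or self.pump_energy <= 0:
            raise ValueError("pulse energies must be > 0")


@dataclass
class PaliDataset:
    """Per-delay corrected photoacoustic amplitudes from one acquisition."""

    delays_us: np.ndarray
    amplitude: np.ndarray          # background-subtracted
    amplitude_raw: np.ndarray      # before background subtraction
    stderr: np.ndarray
    included: np.ndarray           # bool; reference delay excluded
    snr: float
    kt_truth: float
    pO2_truth: float
    seed: int
    config: dict = field(default_factory=dict)

    def fit(self, model: str = "auto") -> "DecayFit":
        return fit_decay(
            self.delays_us[self.included],
            self.amplitude[self.included],
            model=model,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "delay_us": self.delays_us,
                "amplitude": self.amplitude,
                "stderr": self.stderr,
                "included": self.included,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DecayFit:
    """Result of a single/double exponential decay fit.

    For the double model the recorded decay rate is the slower of the two
    fitted rates, which is the one governed by oxygen quenching of the
    monomer triplet state.
    """

    model: str
    params: dict
    selected_rate: float
    rss: float
    converged: bool
    degenerate: bool = False
    n_points: int = 0
    f_pvalue: Optional[float] = None

    def summary(self) -> str:
        lines = [
            f"decay fit ({self.model} exponential, n={self.n_points})",
            *(f"  {k} = {v:.6g}" for k, v in self.params.items()),
            f"  selected rate = {self.selected_rate:.6g} 1/s",
            f"  rss = {self.rss:.3g}  converged = {self.converged}"
            + ("  DEGENERATE" if self.degenerate else ""),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Frame-level corrections
# ---------------------------------------------------------------------------

def normalize_by_energy(frame: PaliFrame) -> PaliFrame:
    """Divide the RF samples by the frame's pulse energy."""
    if frame.pulse_energy <= 0:
        raise ValueError("pulse energy must be > 0")
    rf = RFTrace(
        frame.rf.samples / frame.pulse_energy,
        frame.rf.sampling_rate_mhz,
        frame.rf.speed_of_sound,
        frame.rf.focus_warning,
    )
    return PaliFrame(
        rf=rf,
        delay_us=frame.delay_us,
        kind=frame.kind,
        pulse_energy=1.0,
        pump_energy=frame.pump_energy,
        replicate=frame.replicate,
        n_averaged=frame.n_averaged,
    )


def subtract_pump_artifact(
    pump_probe: PaliFrame, pump_only: PaliFrame
) -> RFTrace:
    """Remove the pump laser's photoacoustic artifact from a frame.

    The pump-only frame measures the artifact at its own pump energy; it
    is rescaled to the pump-probe frame's pump energy, subtracted
    samplewise, and the residual (the probe signal) is normalized by the
    probe pulse energy.
    """
    if pump_probe.kind != "pump-probe" or pump_only.kind != "pump-only":
        raise ValueError("expected a pump-probe and a pump-only frame")
    if pump_probe.delay_us != pump_only.delay_us:
        raise ValueError("frame delays do not match")
    if (
        pump_probe.rf.sampling_rate_mhz != pump_only.rf.sampling_rate_mhz
        or pump_probe.rf.samples.size != pump_only.rf.samples.size
    ):
        raise ValueError("frame sampling does not match")
    artifact = pump_only.rf.samples * (
        pump_probe.pump_energy / pump_only.pump_energy
    )
    corrected = (pump_probe.rf.samples - artifact) / pump_probe.pulse_energy
    return RFTrace(
        corrected,
        pump_probe.rf.sampling_rate_mhz,
        pump_probe.rf.speed_of_sound,
        pump_probe.rf.focus_warning,
    )


def subtract_background(
    amplitudes, reference_index: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the reference-delay amplitude from all entries.

    The reference is the longest scheduled delay, where the triplet state
    has fully decayed and the remaining signal is delay-independent
    background.  Returns the corrected amplitudes and a boolean mask that
    excludes the reference entry from subsequent fitting.
    """
    amps = np.asarray(amplitudes, dtype=float)
    ref = amps[reference_index]
    corrected = amps - ref
    included = np.ones(amps.size, dtype=bool)
    included[reference_index] = False
    return corrected, included


def extract_amplitude(trace: RFTrace, gate_us: tuple[float, float]) -> float:
    """Peak-to-peak amplitude within a time gate on the trace."""
    sl = trace.window_slice(gate_us)
    seg = trace.samples[sl]
    if seg.size == 0:
        raise ValueError("gate contains no samples")
    return float(np.ptp(seg))


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------

def _loglinear_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Rate estimate from a log-linear regression on the positive points."""
    pos = y > 1e-12
    if pos.sum() < 2 or np.ptp(t[pos]) == 0:
        return 1e4
    slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
    return float(np.clip(-slope, *RATE_BOUNDS))


def _fit_single(s: np.ndarray, y: np.ndarray):
    def resid(x):
        return x[0] * np.exp(-x[1] * s) - y

    def jac(x):
        e = np.exp(-x[1] * s)
        return np.column_stack([e, -x[0] * s * e])

    x0 = [max(y[0], 1e-6), _loglinear_rate(s, y)]
    res = optimize.least_squares(
        resid, x0, jac=jac,
        bounds=([0.0, RATE_BOUNDS[0]], [np.inf, RATE_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return res


def _fit_double(s: np.ndarray, y: np.ndarray):
    def resid(x):
        a, b, cc = x
        return a * np.exp(-b * s) + (1.0 - a) * np.exp(-cc * s) - y

    def jac(x):
        a, b, cc = x
        eb = np.exp(-b * s)
        ec = np.exp(-cc * s)
        return np.column_stack([eb - ec, -a * s * eb, -(1.0 - a) * s * ec])

    n3 = max(2, len(s) // 3)
    b0 = _loglinear_rate(s[:n3], y[:n3] / max(y[0], 1e-12))
    c0 = _loglinear_rate(s[-n3:], y[-n3:])
    if b0 <= c0:
        b0 = min(c0 * 10.0, RATE_BOUNDS[1])
    x0 = [0.5, b0, c0]
    res = optimize.least_squares(
        resid, x0, jac=jac,
        bounds=([0.0, RATE_BOUNDS[0], RATE_BOUNDS[0]],
                [1.0, RATE_BOUNDS[1], RATE_BOUNDS[1]]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return res


def _near_bounds(rate: float) -> bool:
    return rate <= RATE_BOUNDS[0] * 1.001 or rate >= RATE_BOUNDS[1] * 0.999


def fit_decay(delays_us, amplitudes, model: str = "auto") -> DecayFit:
    """Fit an exponential decay to per-delay amplitudes.

    Amplitudes are normalized to the earliest-delay value and time is
    measured from the earliest delay, which makes the fit invariant to
    uniform amplitude rescaling and keeps the double model's unit-sum
    amplitude constraint well posed.  Models:

    - ``single``: A exp(-b s)
    - ``double``: a exp(-b s) + (1 - a) exp(-c s), a in [0, 1]; the
      *slower* of (b, c) is recorded as the triplet decay rate.
    - ``auto``: fits both and keeps the double model when an F-test on the
      residual sum of squares prefers it at alpha = 0.05.

    Rates are bounded to [1e2, 1e8] 1/s (damped least squares with a
    trust-region reflective step).  A non-converged or bound-limited fit
    is returned flagged, never raised.
    """
    delays = np.asarray(delays_us, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if delays.shape != amps.shape or delays.ndim != 1:
        raise ValueError("delays and amplitudes must be matching 1-D arrays")
    n = delays.size
    if model not in ("single", "double", "auto"):
        raise ValueError("model must be 'single', 'double' or 'auto'")
    if model == "single" and n < 3:
        raise ValueError("single-exponential fit needs >= 3 points")
    if model in ("double", "auto") and n < 5:
        if model == "double":
            raise ValueError("double-exponential fit needs >= 5 points")
        model = "single"
        if n < 3:
            raise ValueError("decay fit needs >= 3 points")

    scale = amps[0]
    if scale == 0 or np.ptp(amps) == 0:
        return DecayFit(
            model="single",
            params={"A": 0.0, "b": RATE_BOUNDS[0]},
            selected_rate=RATE_BOUNDS[0],
            rss=float(np.sum((amps - amps.mean()) ** 2)),
            converged=False,
            degenerate=True,
            n_points=n,
        )
    y = amps / scale
    s = (delays - delays[0]) * 1e-6  # seconds from the earliest delay

    res_s = _fit_single(s, y)
    rss_s = float(2.0 * res_s.cost)
    fit_s = DecayFit(
        model="single",
        params={"A": float(res_s.x[0]), "b": float(res_s.x[1])},
        selected_rate=float(res_s.x[1]),
        rss=rss_s,
        converged=bool(res_s.success),
        degenerate=_near_bounds(float(res_s.x[1])),
        n_points=n,
    )
    if model == "single":
        return fit_s

    res_d = _fit_double(s, y)
    a, b, cc = (float(v) for v in res_d.x)
    rss_d = float(2.0 * res_d.cost)
    slow = min(b, cc)
    fit_d = DecayFit(
        model="double",
        params={"a": a, "b": b, "c": cc},
        selected_rate=slow,
        rss=rss_d,
        converged=bool(res_d.success),
        degenerate=_near_bounds(slow),
        n_points=n,
    )
    if model == "double":
        return fit_d

    # auto: F-test on the RSS reduction (2 extra parameters)
    dof = n - 3
    if rss_d <= 0 or dof <= 0:
        pval = 0.0 if rss_d < rss_s else 1.0
    else:
        f = max(rss_s - rss_d, 0.0) / 2.0 / (rss_d / dof)
        pval = float(stats.f.sf(f, 2, dof))
    fit_d.f_pvalue = pval
    fit_s.f_pvalue = pval
    # a mixture whose second component carries negligible weight, or whose
    # slow rate ran into a bound, is effectively single-exponential
    if min(a, 1.0 - a) < 0.05 or fit_d.degenerate:
        return fit_s
    return fit_d if pval < 0.05 else fit_s


# ---------------------------------------------------------------------------
# Forward acquisition
# ---------------------------------------------------------------------------

@dataclass
class CleanTraces:
    """Noise-free per-pulse traces shared by all frames of one condition."""

    signal: RFTrace        # probe signal at zero delay (full triplet)
    artifact: RFTrace      # pump photoacoustic artifact
    kt_truth: float
    pump_energy: float     # nominal, mJ
    probe_energy: float    # nominal, mJ
    arrival_us: float
    pump_budget: dict = field(default_factory=dict)
    probe_budget: dict = field(default_factory=dict)


def pump_absorption_map(
    phantom: VoxelPhantom, photophys: PhotophysicalParams
) -> np.ndarray:
    """Pump-wavelength absorption map: tissue plus the photoactive monomer
    fraction of the dye inside the node (1/cm)."""
    pump_wl = sorted(phantom.optics)[0]
    node = phantom.node_mask()
    m_frac = monomer_fraction(photophys.total_conc, photophys.k_dim)
    mua_pump = np.full(phantom.shape, phantom.optics[pump_wl].mu_a)
    mua_pump[node] += triplet_absorption_coeff(
        m_frac * photophys.total_conc,
        phantom.node_extinction.get(pump_wl, 0.0) or c.MB_EXTINCTION_GROUND_660,
    )
    return mua_pump


def compute_pump_fluence(
    phantom: VoxelPhantom,
    beam_pump: BeamSpec,
    photophys: PhotophysicalParams,
    n_photons: int,
    seed: int,
):
    """Pump-wavelength Monte Carlo fluence with the monomer-corrected
    node absorption (independent of the triplet decay rate)."""
    return monte_carlo_fluence(
        phantom, beam_pump, n_photons, stage_seed(seed, "pump_mc"),
        mua_map=pump_absorption_map(phantom, photophys),
    )


def simulate_clean_traces(
    phantom: VoxelPhantom,
    beam_pump: BeamSpec,
    beam_probe: BeamSpec,
    photophys: PhotophysicalParams,
    cal_truth: SternVolmerCal,
    pO2_truth: float,
    n_photons: int,
    seed: int,
    xdcr: Optional[TransducerSpec] = None,
    grueneisen: float = c.GRUENEISEN,
    sos: float = c.SPEED_OF_SOUND_M_S,
    pump_fluence=None,
) -> CleanTraces:
    """Run the optical/acoustic forward model once for a phantom condition.

    Pipeline: pump Monte Carlo -> triplet population from the pumping
    kinetics -> probe Monte Carlo with triplet-updated absorption ->
    initial pressure from the triplet absorption -> transducer projection.
    The pump artifact trace is projected from the total absorption at the
    pump wavelength.  ``pump_fluence`` may carry a precomputed pump run
    (it does not depend on the oxygenation).
    """
    if pO2_truth < 0:
        raise ValueError("pO2 must be >= 0")
    kt = stern_volmer_rate(cal_truth, pO2_truth)
    if xdcr is None:
        xdcr = TransducerSpec.focused_on(phantom.node_center_mm)

    wavelengths = sorted(phantom.optics)
    probe_wl = wavelengths[-1]
    node = phantom.node_mask()
    m_frac = monomer_fraction(photophys.total_conc, photophys.k_dim)
    n_monomer = m_frac * photophys.total_conc
    mua_pump = pump_absorption_map(phantom, photophys)

    pump_fl = pump_fluence
    if pump_fl is None:
        pump_fl = monte_carlo_fluence(
            phantom, beam_pump, n_photons, stage_seed(seed, "pump_mc"),
            mua_map=mua_pump,
        )

    fl_rate = pump_fl.values[node] / beam_pump.pulse_duration  # W/cm^2
    beta = pump_rate(photophys, fl_rate, beam_pump.wavelength)
    nt = triplet_population(
        beta, n_monomer, kt, photophys.pump_pulse_duration
    )
    triplet_map = np.zeros(phantom.shape)
    triplet_map[node] = nt

    probe_phantom = update_probe_absorption(
        phantom, triplet_map, photophys.eps_triplet, probe_wl
    )
    probe_fl = monte_carlo_fluence(
        probe_phantom, beam_probe, n_photons, stage_seed(seed, "probe_mc")
    )

    mua_triplet = triplet_absorption_coeff(triplet_map, photophys.eps_triplet)
    p_signal = initial_pressure(grueneisen, mua_triplet, probe_fl)
    sig_trace = project_to_transducer(p_signal, xdcr, sos)

    p_artifact = initial_pressure(grueneisen, mua_pump, pump_fl)
    art_trace = project_to_transducer(
        p_artifact, xdcr, sos, n_samples=sig_trace.samples.size
    )

    arrival_us = xdcr.focal_length_mm / (sos / 1000.0)
    return CleanTraces(
        signal=sig_trace,
        artifact=art_trace,
        kt_truth=float(kt),
        pump_energy=beam_pump.pulse_energy_mj,
        probe_energy=beam_probe.pulse_energy_mj,
        arrival_us=arrival_us,
        pump_budget=pump_fl.energy_budget,
        probe_budget=probe_fl.energy_budget,
    )


def acquire_from_traces(
    clean: CleanTraces,
    schedule: DelaySchedule,
    n_averages: int = c.N_AVERAGES,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    gate_half_width_us: float = 3.0,
    energy_jitter: float = 0.0,
    pO2_truth: float = float("nan"),
    replicate: int = 0,
    amplitude_method: str = "projection",
) -> PaliDataset:
    """Generate one averaged acquisition from precomputed clean traces.

    For every delay a pump-probe and a pump-only frame are formed; the
    averaged frame is simulated directly with the noise standard deviation
    reduced by sqrt(n_averages) (exact for Gaussian noise).  The
    correction chain is: pump-artifact subtraction with energy rescaling,
    probe-energy normalization, per-delay amplitude extraction in a gate
    around the focal arrival time, and background subtraction at the
    longest delay.

    ``amplitude_method`` selects the per-delay amplitude estimator:

    - ``"projection"`` (default): linear projection of the gated trace
      onto the known transient shape (matched filter), scaled to
      peak-to-peak units.  Linear in the data, hence unbiased under
      additive Gaussian noise.
    - ``"ptp"``: raw peak-to-peak within the gate.  Simple and
      template-free, but its noise floor biases weak delays.
    """
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if amplitude_method not in ("projection", "ptp"):
        raise ValueError("amplitude_method must be 'projection' or 'ptp'")
    rng = np.random.default_rng(seed)
    delays = np.asarray(schedule.delays_us, dtype=float)
    fs = clean.signal.sampling_rate_mhz
    sos = clean.signal.speed_of_sound
    nep_avg = noise.nep / math.sqrt(n_averages)
    jit_avg = energy_jitter / math.sqrt(n_averages)
    gate = (
        clean.arrival_us - gate_half_width_us,
        clean.arrival_us + gate_half_width_us,
    )
    noise_window = (0.0, max(clean.arrival_us - 3.0, 1.0 / fs))

    gate_slice = clean.signal.window_slice(gate)
    template = clean.signal.samples[gate_slice]
    t_norm = float(np.dot(template, template))
    t_ptp = float(np.ptp(template))
    use_projection = amplitude_method == "projection" and t_norm > 0

    amplitudes = np.empty(delays.size)
    stderrs = np.empty(delays.size)
    snr_first: float = math.nan
    n_samp = clean.signal.samples.size
    for i, tau in enumerate(delays):
        decay = math.exp(-clean.kt_truth * tau * 1e-6)

        def draw_energy(nominal: float) -> float:
            if jit_avg == 0:
                return nominal
            return float(nominal * max(rng.normal(1.0, jit_avg), 1e-3))

        e_pump_pp = draw_energy(clean.pump_energy)
        e_probe_pp = draw_energy(clean.probe_energy)
        e_pump_po = draw_energy(clean.pump_energy)

        pp_samples = (
            clean.artifact.samples * (e_pump_pp / clean.pump_energy)
            + clean.signal.samples * decay * (e_probe_pp / clean.probe_energy)
        )
        po_samples = clean.artifact.samples * (e_pump_po / clean.pump_energy)
        if nep_avg > 0:
            pp_samples = pp_samples + rng.normal(0.0, nep_avg, n_samp)
            po_samples = po_samples + rng.normal(0.0, nep_avg, n_samp)

        pp = PaliFrame(
            rf=RFTrace(pp_samples, fs, sos),
            delay_us=tau, kind="pump-probe",
            pulse_energy=e_probe_pp, pump_energy=e_pump_pp,
            replicate=replicate, n_averaged=n_averages,
        )
        po = PaliFrame(
            rf=RFTrace(po_samples, fs, sos),
            delay_us=tau, kind="pump-only",
            pulse_energy=e_pump_po, pump_energy=e_pump_po,
            replicate=replicate, n_averaged=n_averages,
        )
        corrected = subtract_pump_artifact(pp, po)
        if use_projection:
            seg = corrected.samples[gate_slice]
            amplitudes[i] = float(np.dot(seg, template)) / t_norm * t_ptp
        else:
            amplitudes[i] = extract_amplitude(corrected, gate)
        pre = corrected.samples[corrected.window_slice(noise_window)]
        stderrs[i] = math.sqrt(2.0) * float(np.sqrt(np.mean(pre**2)))
        if i == 0:
            # a noiseless acquisition has no noise floor at all
            snr_first = (math.inf if noise.nep == 0
                         else _snr(corrected, gate, noise_window))

    bg_amplitude, included = subtract_background(amplitudes)
    return PaliDataset(
        delays_us=delays,
        amplitude=bg_amplitude,
        amplitude_raw=amplitudes,
        stderr=stderrs,
        included=included,
        snr=snr_first,
        kt_truth=clean.kt_truth,
        pO2_truth=pO2_truth,
        seed=seed,
        config={
            "n_averages": n_averages,
            "nep": noise.nep,
            "energy_jitter": energy_jitter,
            "gate_half_width_us": gate_half_width_us,
        },
    )


def simulate_acquisition(
    phantom: VoxelPhantom,
    beam_pump: BeamSpec,
    beam_probe: BeamSpec,
    photophys: PhotophysicalParams,
    cal_truth: SternVolmerCal,
    pO2_truth: float,
    schedule: DelaySchedule,
    n_averages: int = c.N_AVERAGES,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_photons: int = 100_000,
    xdcr: Optional[TransducerSpec] = None,
    grueneisen: float = c.GRUENEISEN,
    sos: float = c.SPEED_OF_SOUND_M_S,
    gate_half_width_us: float = 3.0,
    energy_jitter: float = 0.0,
    amplitude_method: str = "projection",
) -> PaliDataset:
    """Full forward simulation of one PALI acquisition.

    Combines :func:`simulate_clean_traces` (Monte Carlo light transport,
    triplet pumping, probe-absorption update, acoustic projection) with
    :func:`acquire_from_traces` (per-delay decay scaling, noise, and the
    correction chain).  Deterministic for a fixed seed.
    """
    clean = simulate_clean_traces(
        phantom, beam_pump, beam_probe, photophys, cal_truth, pO2_truth,
        n_photons=n_photons, seed=seed, xdcr=xdcr,
        grueneisen=grueneisen, sos=sos,
    )
    return acquire_from_traces(
        clean, schedule, n_averages=n_averages, noise=noise,
        seed=stage_seed(seed, "noise"),
        gate_half_width_us=gate_half_width_us,
        energy_jitter=energy_jitter, pO2_truth=pO2_truth,
        amplitude_method=amplitude_method,
    )
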