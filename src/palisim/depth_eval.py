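"""Depth-sweep experiment and imaging-depth criteria.

The sweep repeats the full forward simulation for a ladder of node depths
and two oxygenation levels, recovers the triplet decay rate per replicate,
and evaluates two depth limits:

- *clinical imaging depth*: the shallowest depth at which the mean
  recovered rate deviates from the truth by more than 10 mm Hg worth of
  decay rate (``|mean - truth| / kQ > 10``), the error level at which
  metastatic and normal nodes can no longer be separated;
- *measurement depth limit*: the shallowest depth at which zero error
  lies beyond two standard deviations of the replicate percent errors,
  i.e. the measurement is no longer statistically reliable.

Depths are scanned shallow to deep; both the first exceedance and the
bracketing interval between swept depths are reported.  A sweep that never
exceeds a criterion returns ``inf`` (beyond the swept range).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants as c
from .acoustics import NoiseModel, TransducerSpec
from .light_transport import BeamSpec, OpticalProperties, build_phantom
from .photophysics import PhotophysicalParams, SternVolmerCal
from .pipeline import (
    DelaySchedule,
    acquire_from_traces,
    compute_pump_fluence,
    delay_schedule,
    fit_decay,
    simulate_clean_traces,
)
from .seeds import stage_seed

__all__ = [
    "DepthSweepConfig",
    "DepthSweepResult",
    "run_depth_sweep",
    "decay_error_mmHg",
    "clinical_imaging_depth",
    "measurement_depth_limit",
    "snr_profile",
]

BEYOND_RANGE = math.inf
"""Sentinel for a depth criterion never exceeded within the swept range."""


@dataclass
class DepthSweepConfig:
    """Configuration of the depth-sweep experiment."""

    depths_mm: Sequence[float] = c.SWEEP_DEPTHS_MM
    pO2_levels: Sequence[float] = c.SWEEP_PO2_MMHG
    replicates: int = c.N_REPLICATES
    n_photons: int = 100_000
    n_averages: int = c.N_AVERAGES
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    schedule: Optional[DelaySchedule] = None
    cal_truth: SternVolmerCal = field(default_factory=SternVolmerCal)
    photophys: PhotophysicalParams = field(default_factory=PhotophysicalParams)
    fit_model: str = "auto"
    node_radius_mm: float = c.NODE_RADIUS_MM
    voxel_mm: float = c.VOXEL_SIZE_MM
    grid_size_mm: tuple[float, float, float] = c.GRID_SIZE_MM
    energy_jitter: float = 0.0
    amplitude_method: str = "projection"
    truth_mode: str = "calibration"  # or "water" (phantom-emulation mode)

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_mm, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be sorted ascending")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for SD-based metrics")
        if self.schedule is None:
            self.schedule = delay_schedule()
        if self.truth_mode not in ("calibration", "water"):
            raise ValueError("truth_mode must be 'calibration' or 'water'")


@dataclass
class DepthSweepResult:
    """Replicate-level and summarized outcomes of a depth sweep.

    ``cells`` has one row per (depth, pO2, replicate) with the recovered
    rate and SNR; ``summary`` one row per (depth, pO2) with the mean rate,
    SD, percent error versus the ground-truth rate, and the error mapped
    to mm Hg through the truth calibration.
    """

    cells: pd.DataFrame
    summary: pd.DataFrame
    cal_truth: SternVolmerCal
    config: DepthSweepConfig

    def criteria(self, threshold_mmhg: float = c.CLINICAL_ERROR_THRESHOLD_MMHG) -> dict:
        """Both depth criteria with bracketing intervals, per oxygenation."""
        out = {}
        for pO2 in sorted(self.summary["pO2"].unique()):
            cd, cd_bracket = clinical_imaging_depth(
                self, threshold_mmhg=threshold_mmhg, pO2=pO2, with_bracket=True
            )
            md, md_bracket = measurement_depth_limit(
                self, pO2=pO2, with_bracket=True
            )
            out[pO2] = {
                "clinical_imaging_depth_mm": cd,
                "clinical_bracket_mm": cd_bracket,
                "measurement_depth_limit_mm": md,
                "measurement_bracket_mm": md_bracket,
            }
        return out


def decay_error_mmHg(
    measured_kt: float, true_kt: float, cal: SternVolmerCal
) -> float:
    """Decay-rate error expressed in oxygen partial pressure (mm Hg)."""
    return abs(measured_kt - true_kt) / cal.kQ


def run_depth_sweep(config: DepthSweepConfig) -> DepthSweepResult:
    """Run the full pipeline over all (depth, pO2, replicate) cells.

    Per depth the pump Monte Carlo phantom is rebuilt; per oxygenation the
    triplet map and probe run are recomputed (the pumping kinetics depend
    weakly on the decay rate); replicates share the clean traces and
    differ in their noise stream, mirroring repeated acquisitions on one
    physical setup.  A failed fit in one cell is recorded, not fatal.
    """
    rows = []
    beam_pump = BeamSpec(
        pulse_fluence_mj_cm2=c.PUMP_FLUENCE_MJ_CM2,
        wavelength=c.PUMP_WAVELENGTH_NM,
    )
    beam_probe = BeamSpec(
        pulse_fluence_mj_cm2=c.PROBE_FLUENCE_MJ_CM2,
        wavelength=c.PROBE_WAVELENGTH_NM,
    )
    water_truth: dict[float, float] = {}
    if config.truth_mode == "water":
        water_truth = _water_ground_truth(config, beam_pump, beam_probe)
    for d_idx, depth in enumerate(config.depths_mm):
        phantom = build_phantom(
            depth_mm=float(depth),
            node_radius_mm=config.node_radius_mm,
            voxel_mm=config.voxel_mm,
            grid_size_mm=config.grid_size_mm,
            node_conc=config.photophys.total_conc,
        )
        xdcr = TransducerSpec.focused_on(phantom.node_center_mm)
        pump_fl = compute_pump_fluence(
            phantom, beam_pump, config.photophys, config.n_photons,
            stage_seed(config.seed, "sweep", d_idx * 100 + 99),
        )
        for p_idx, pO2 in enumerate(config.pO2_levels):
            cond_seed = stage_seed(config.seed, "sweep", d_idx * 100 + p_idx)
            clean = simulate_clean_traces(
                phantom, beam_pump, beam_probe, config.photophys,
                config.cal_truth, float(pO2),
                n_photons=config.n_photons, seed=cond_seed, xdcr=xdcr,
                pump_fluence=pump_fl,
            )
            for rep in range(config.replicates):
                ds = acquire_from_traces(
                    clean, config.schedule,
                    n_averages=config.n_averages,
                    noise=config.noise,
                    seed=stage_seed(cond_seed, "replicate", rep),
                    energy_jitter=config.energy_jitter,
                    pO2_truth=float(pO2),
                    replicate=rep,
                    amplitude_method=config.amplitude_method,
                )
                try:
                    fit = ds.fit(model=config.fit_model)
                    rate = fit.selected_rate
                    converged = fit.converged
                    model = fit.model
                except Exception:  # recorded, not fatal
                    rate, converged, model = math.nan, False, "failed"
                rows.append(
                    {
                        "depth_mm": float(depth),
                        "pO2": float(pO2),
                        "replicate": rep,
                        "rate": rate,
                        "kt_truth": water_truth.get(float(pO2),
                                                    clean.kt_truth),
                        "snr": ds.snr,
                        "converged": converged,
                        "model": model,
                    }
                )
    cells = pd.DataFrame(rows)

    def _summarize(g: pd.DataFrame) -> pd.Series:
        truth = g["kt_truth"].iloc[0]
        rates = g["rate"].dropna()
        mean = rates.mean() if len(rates) else math.nan
        sd = rates.std(ddof=1) if len(rates) > 1 else math.nan
        pct = (rates - truth) / truth * 100.0
        return pd.Series(
            {
                "kt_truth": truth,
                "mean_rate": mean,
                "sd_rate": sd,
                "pct_error": abs(mean - truth) / truth * 100.0,
                "pct_error_mean": pct.mean(),
                "pct_error_sd": pct.std(ddof=1) if len(pct) > 1 else math.nan,
                "error_mmHg": math.nan,
                "mean_snr": g["snr"].mean(),
            }
        )

    summary = (
        cells.groupby(["depth_mm", "pO2"], sort=True)
        .apply(_summarize, include_groups=False)
        .reset_index()
    )
    cal = config.cal_truth
    summary["error_mmHg"] = (
        (summary["mean_rate"] - summary["kt_truth"]).abs() / cal.kQ
    )
    return DepthSweepResult(
        cells=cells, summary=summary, cal_truth=cal, config=config
    )


def _water_ground_truth(
    config: DepthSweepConfig, beam_pump: BeamSpec, beam_probe: BeamSpec
) -> dict[float, float]:
    """Mean fitted rate per oxygenation with the scattering fluid replaced
    by water (clear, essentially non-attenuating background): the
    operational ground truth of the benchtop phantom experiment."""
    water = {
        c.PUMP_WAVELENGTH_NM: OpticalProperties(
            3e-3, 1e-3, wavelength=c.PUMP_WAVELENGTH_NM
        ),
        c.PROBE_WAVELENGTH_NM: OpticalProperties(
            3e-2, 1e-3, wavelength=c.PROBE_WAVELENGTH_NM
        ),
    }
    phantom = build_phantom(
        depth_mm=float(config.depths_mm[0]),
        node_radius_mm=config.node_radius_mm,
        voxel_mm=config.voxel_mm,
        grid_size_mm=config.grid_size_mm,
        node_conc=config.photophys.total_conc,
        optics=water,
    )
    xdcr = TransducerSpec.focused_on(phantom.node_center_mm)
    truth = {}
    for p_idx, pO2 in enumerate(config.pO2_levels):
        cond_seed = stage_seed(config.seed, "sweep", 9000 + p_idx)
        clean = simulate_clean_traces(
            phantom, beam_pump, beam_probe, config.photophys,
            config.cal_truth, float(pO2),
            n_photons=config.n_photons, seed=cond_seed, xdcr=xdcr,
        )
        rates = []
        for rep in range(config.replicates):
            ds = acquire_from_traces(
                clean, config.schedule, n_averages=config.n_averages,
                noise=config.noise,
                seed=stage_seed(cond_seed, "replicate", rep),
                pO2_truth=float(pO2), replicate=rep,
                amplitude_method=config.amplitude_method,
            )
            fit = ds.fit(model=config.fit_model)
            if fit.converged and not fit.degenerate:
                rates.append(fit.selected_rate)
        truth[float(pO2)] = (
            float(np.mean(rates)) if rates else clean.kt_truth
        )
    return truth


def _first_exceedance(
    depths: np.ndarray, exceeds: np.ndarray, with_bracket: bool
):
    idx = np.nonzero(exceeds)[0]
    if idx.size == 0:
        depth = BEYOND_RANGE
        bracket = (float(depths[-1]), BEYOND_RANGE)
    else:
        i = int(idx[0])
        depth = float(depths[i])
        bracket = (float(depths[i - 1]) if i > 0 else 0.0, depth)
    return (depth, bracket) if with_bracket else depth


def clinical_imaging_depth(
    result: DepthSweepResult,
    threshold_mmhg: float = c.CLINICAL_ERROR_THRESHOLD_MMHG,
    pO2: Optional[float] = None,
    with_bracket: bool = False,
):
    """Shallowest swept depth whose mean error exceeds ``threshold_mmhg``.

    Returns the beyond-range sentinel (``inf``) when no swept depth
    exceeds the threshold.  With ``pO2=None`` a dict per oxygenation is
    returned.
    """
    if pO2 is None:
        return {
            p: clinical_imaging_depth(result, threshold_mmhg, p, with_bracket)
            for p in sorted(result.summary["pO2"].unique())
        }
    sub = result.summary[result.summary["pO2"] == pO2].sort_values("depth_mm")
    if len(sub) < 2:
        raise ValueError("need >= 2 swept depths")
    exceeds = (sub["error_mmHg"] > threshold_mmhg).to_numpy()
    exceeds |= ~np.isfinite(sub["error_mmHg"].to_numpy())
    return _first_exceedance(
        sub["depth_mm"].to_numpy(), exceeds, with_bracket
    )


def measurement_depth_limit(
    result: DepthSweepResult,
    pO2: Optional[float] = None,
    with_bracket: bool = False,
):
    """Shallowest swept depth where 0% error lies beyond two SD of the
    replicate percent errors (``|mean pct error| - 2 SD > 0``)."""
    if pO2 is None:
        return {
            p: measurement_depth_limit(result, p, with_bracket)
            for p in sorted(result.summary["pO2"].unique())
        }
    sub = result.summary[result.summary["pO2"] == pO2].sort_values("depth_mm")
    mean = sub["pct_error_mean"].to_numpy()
    sd = sub["pct_error_sd"].to_numpy()
    exceeds = np.abs(mean) - 2.0 * sd > 0
    exceeds |= ~np.isfinite(mean) | ~np.isfinite(sd)
    return _first_exceedance(
        sub["depth_mm"].to_numpy(), exceeds, with_bracket
    )


def snr_profile(result: DepthSweepResult) -> pd.DataFrame:
    """Mean SNR per (depth, pO2), with a monotone non-increase check."""
    prof = (
        result.cells.groupby(["depth_mm", "pO2"], sort=True)["snr"]
        .mean()
        .reset_index(name="mean_snr")
    )
    flags = []
    for p, g in prof.groupby("pO2"):
        vals = g.sort_values("depth_mm")["mean_snr"].to_numpy()
        with np.errstate(invalid="ignore"):
            flags.append((p, bool(np.all(np.diff(vals) <= 0))))
    prof.attrs["monotone_non_increasing"] = dict(flags)
    return prof
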