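"""File I/O: HDF5 array containers and CSV import/export.

Fluence maps and RF traces are stored in HDF5 with their grid/sampling
metadata.  CSV dialects:

- decay data: columns ``delay_us, amplitude`` (optional ``stderr``)
- RF traces (transducer/hydrophone pairs): columns ``time_s, amplitude``
- flash photolysis: columns ``time_s, transmission``
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .acoustics import RFTrace
from .light_transport import FluenceMap

__all__ = [
    "save_fluence",
    "load_fluence",
    "save_rf_trace",
    "load_rf_trace",
    "read_decay_csv",
    "read_trace_csv",
    "read_flash_photolysis_csv",
]


def save_fluence(path, fmap: FluenceMap) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("fluence", data=fmap.values)
        d.attrs["wavelength_nm"] = fmap.wavelength
        d.attrs["n_photons"] = fmap.n_photons
        d.attrs["seed"] = fmap.seed
        d.attrs["voxel_mm"] = fmap.voxel_mm
        for k, v in fmap.energy_budget.items():
            d.attrs[f"budget_{k}"] = v


def load_fluence(path) -> FluenceMap:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["fluence"]
        budget = {
            k[len("budget_"):]: float(v)
            for k, v in d.attrs.items()
            if k.startswith("budget_")
        }
        return FluenceMap(
            values=d[()],
            wavelength=float(d.attrs["wavelength_nm"]),
            n_photons=int(d.attrs["n_photons"]),
            seed=int(d.attrs["seed"]),
            voxel_mm=float(d.attrs["voxel_mm"]),
            energy_budget=budget,
        )


def save_rf_trace(path, trace: RFTrace) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=trace.samples)
        d.attrs["sampling_rate_mhz"] = trace.sampling_rate_mhz
        d.attrs["speed_of_sound"] = trace.speed_of_sound


def load_rf_trace(path) -> RFTrace:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["rf"]
        return RFTrace(
            samples=d[()],
            sampling_rate_mhz=float(d.attrs["sampling_rate_mhz"]),
            speed_of_sound=float(d.attrs["speed_of_sound"]),
        )


def read_decay_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a per-delay decay CSV (``delay_us, amplitude``)."""
    df = pd.read_csv(path)
    for col in ("delay_us", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"decay CSV missing required column {col!r}")
    if "included" in df.columns:
        df = df[df["included"].astype(bool)]
    return df["delay_us"].to_numpy(float), df["amplitude"].to_numpy(float)


def read_trace_csv(path) -> RFTrace:
    """Read an RF trace CSV (``time_s, amplitude``), inferring the
    sampling rate from the time column."""
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("time_s must be uniformly sampled")
    fs_mhz = 1e-6 / dt[0]
    return RFTrace(df["amplitude"].to_numpy(float), sampling_rate_mhz=fs_mhz)


def read_flash_photolysis_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a flash-photolysis CSV (``time_s, transmission``)."""
    df = pd.read_csv(path)
    for col in ("time_s", "transmission"):
        if col not in df.columns:
            raise ValueError(
                f"flash-photolysis CSV missing required column {col!r}"
            )
    return df["time_s"].to_numpy(float), df["transmission"].to_numpy(float)
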