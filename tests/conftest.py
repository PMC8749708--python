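import numpy as np
import pytest

import palisim as ps


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small default-optics phantom with the node at 4 mm (coarse voxels)."""
    return ps.build_phantom(
        depth_mm=4.0, node_radius_mm=2.0, grid_size_mm=(20.0, 20.0, 16.0),
        voxel_mm=0.8,
    )


@pytest.fixture(scope="session")
def pump_beam():
    return ps.BeamSpec(radius_mm=5.0, pulse_fluence_mj_cm2=10.0,
                       wavelength=660.0)


@pytest.fixture(scope="session")
def probe_beam():
    return ps.BeamSpec(radius_mm=5.0, pulse_fluence_mj_cm2=15.0,
                       wavelength=830.0)


@pytest.fixture(scope="session")
def synthetic_clean_traces():
    """Analytic clean traces (no Monte Carlo): a band-limited pulse at the
    focal arrival plus a distinct pump artifact."""
    from palisim.pipeline import CleanTraces

    fs = 40.0
    n = 1600
    t = np.arange(n) / fs
    arrival = 25.0 / 1.54
    sig = np.exp(-0.5 * ((t - arrival) / 0.25) ** 2) * np.sin(
        2 * np.pi * 5.0 * (t - arrival)
    )
    art = 3.0 * np.exp(-0.5 * ((t - 13.0) / 0.4) ** 2) * np.sin(
        2 * np.pi * 5.0 * (t - 13.0)
    )
    return CleanTraces(
        signal=ps.RFTrace(sig, sampling_rate_mhz=fs),
        artifact=ps.RFTrace(art, sampling_rate_mhz=fs),
        kt_truth=6.05e5,
        pump_energy=31.4,
        probe_energy=47.1,
        arrival_us=arrival,
    )
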