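"""Depth-criteria arithmetic and miniature sweep integration tests."""
import math

import numpy as np
import pandas as pd
import pytest

import palisim as ps
from palisim.depth_eval import BEYOND_RANGE, DepthSweepResult


def synthetic_result(depths, errors_mmhg, pct_mean=None, pct_sd=None,
                     pO2=150.0):
    """Build a DepthSweepResult directly from per-depth summary values."""
    n = len(depths)
    pct_mean = pct_mean if pct_mean is not None else [0.0] * n
    pct_sd = pct_sd if pct_sd is not None else [1.0] * n
    cal = ps.SternVolmerCal()
    truth = ps.stern_volmer_rate(cal, pO2)
    summary = pd.DataFrame(
        {
            "depth_mm": depths,
            "pO2": pO2,
            "kt_truth": truth,
            "mean_rate": truth + np.asarray(errors_mmhg) * cal.kQ,
            "sd_rate": 1.0,
            "pct_error": np.abs(errors_mmhg) * cal.kQ / truth * 100,
            "pct_error_mean": pct_mean,
            "pct_error_sd": pct_sd,
            "error_mmHg": errors_mmhg,
            "mean_snr": np.linspace(100, 10, n),
        }
    )
    cells = pd.DataFrame(
        {
            "depth_mm": np.repeat(depths, 2),
            "pO2": pO2,
            "replicate": np.tile([0, 1], n),
            "rate": truth,
            "kt_truth": truth,
            "snr": np.repeat(np.linspace(100, 10, n), 2),
            "converged": True,
            "model": "single",
        }
    )
    cfg = ps.DepthSweepConfig(depths_mm=list(depths))
    return DepthSweepResult(cells=cells, summary=summary, cal_truth=cal,
                            config=cfg)


class TestDecayErrorMmHg:
    def test_exact_measurement(self):
        cal = ps.SternVolmerCal()
        assert ps.decay_error_mmHg(1e5, 1e5, cal) == 0.0

    def test_threshold_scale(self):
        cal = ps.SternVolmerCal()
        assert ps.decay_error_mmHg(1e5 + 10 * cal.kQ, 1e5, cal) == pytest.approx(10.0)

    def test_shift_invariance(self):
        cal = ps.SternVolmerCal()
        assert ps.decay_error_mmHg(1.2e5, 1e5, cal) == pytest.approx(
            ps.decay_error_mmHg(1.2e5 + 5e4, 1e5 + 5e4, cal)
        )


class TestClinicalImagingDepth:
    def test_step_case(self):
        res = synthetic_result([4, 7, 10, 13], [2.0, 4.0, 12.0, 30.0])
        depth, bracket = ps.clinical_imaging_depth(
            res, pO2=150.0, with_bracket=True
        )
        assert depth == 10.0
        assert bracket == (7.0, 10.0)

    def test_all_below_threshold_sentinel(self):
        res = synthetic_result([4, 7, 10], [1.0, 2.0, 3.0])
        assert ps.clinical_imaging_depth(res, pO2=150.0) == BEYOND_RANGE

    def test_zero_threshold(self):
        res = synthetic_result([4, 7, 10], [0.0, 0.5, 3.0])
        assert ps.clinical_imaging_depth(res, threshold_mmhg=0.0,
                                         pO2=150.0) == 7.0


class TestMeasurementDepthLimit:
    def test_zero_mean_error_sentinel(self):
        res = synthetic_result([4, 7, 10], [0, 0, 0],
                               pct_mean=[0, 0, 0], pct_sd=[3, 3, 3])
        assert ps.measurement_depth_limit(res, pO2=150.0) == BEYOND_RANGE

    def test_mean8_sd3_unreliable(self):
        # 0% lies beyond two SD: 8 - 2*3 > 0
        res = synthetic_result([4, 7], [0, 0], pct_mean=[0.0, 8.0],
                               pct_sd=[3.0, 3.0])
        assert ps.measurement_depth_limit(res, pO2=150.0) == 7.0

    def test_mean5_sd3_reliable(self):
        res = synthetic_result([4, 7], [0, 0], pct_mean=[5.0, 5.0],
                               pct_sd=[3.0, 3.0])
        assert ps.measurement_depth_limit(res, pO2=150.0) == BEYOND_RANGE


@pytest.fixture(scope="module")
def noiseless_sweep():
    cfg = ps.DepthSweepConfig(
        depths_mm=[4.0, 8.0], pO2_levels=[0.0, 150.0], replicates=2,
        n_photons=3000, noise=ps.NoiseModel(nep=0.0), seed=21,
        voxel_mm=0.8, grid_size_mm=(24.0, 24.0, 16.0),
        node_radius_mm=2.0, fit_model="single",
    )
    return cfg, ps.run_depth_sweep(cfg)


@pytest.fixture(scope="module")
def noisy_sweep():
    cfg = ps.DepthSweepConfig(
        depths_mm=[4.0, 8.0, 12.0], pO2_levels=[150.0], replicates=4,
        n_photons=20_000, noise=ps.NoiseModel(nep=ps.constants.NEP_MPA),
        seed=5, voxel_mm=0.8, grid_size_mm=(30.0, 30.0, 18.0),
        node_radius_mm=2.0, fit_model="single",
    )
    return ps.run_depth_sweep(cfg)


class TestMiniSweep:
    def test_noiseless_percent_error_tiny(self, noiseless_sweep):
        _, res = noiseless_sweep
        assert np.all(res.summary["pct_error"] < 0.1)

    def test_noiseless_no_exceedance(self, noiseless_sweep):
        _, res = noiseless_sweep
        depths = ps.clinical_imaging_depth(res)
        assert all(v == BEYOND_RANGE for v in depths.values())

    def test_deterministic_rerun(self, noiseless_sweep):
        cfg, res = noiseless_sweep
        res2 = ps.run_depth_sweep(cfg)
        pd.testing.assert_frame_equal(res.cells, res2.cells)

    def test_snr_profile_shape(self, noiseless_sweep):
        _, res = noiseless_sweep
        prof = ps.snr_profile(res)
        assert set(prof.columns) == {"depth_mm", "pO2", "mean_snr"}
        # noiseless acquisition: silent noise window -> infinite SNR flags
        assert np.all(np.isinf(prof["mean_snr"]))


class TestNoisySweepProperties:
    def test_snr_decreases_with_depth(self, noisy_sweep):
        prof = ps.snr_profile(noisy_sweep)
        vals = prof.sort_values("depth_mm")["mean_snr"].to_numpy()
        assert vals[0] > vals[-1]

    def test_rate_dispersion_grows_with_depth(self, noisy_sweep):
        sd = noisy_sweep.summary.sort_values("depth_mm")["sd_rate"].to_numpy()
        assert sd[-1] > sd[0]


class TestWaterGroundTruth:
    def test_water_truth_close_to_calibration(self):
        cfg = ps.DepthSweepConfig(
            depths_mm=[4.0, 8.0], pO2_levels=[150.0], replicates=2,
            n_photons=3000, noise=ps.NoiseModel(nep=0.0), seed=3,
            voxel_mm=0.8, grid_size_mm=(24.0, 24.0, 16.0),
            node_radius_mm=2.0, fit_model="single", truth_mode="water",
        )
        res = ps.run_depth_sweep(cfg)
        truth = res.cells["kt_truth"].iloc[0]
        cal_rate = ps.stern_volmer_rate(cfg.cal_truth, 150.0)
        assert truth == pytest.approx(cal_rate, rel=0.01)
        assert np.all(res.summary["pct_error"] < 1.0)

    def test_invalid_truth_mode(self):
        with pytest.raises(ValueError, match="truth_mode"):
            ps.DepthSweepConfig(truth_mode="oracle")


class TestNoiseDegradation:
    def test_exceedance_monotone_in_nep(self):
        # exceedance counts of both depth criteria never decrease as the
        # receiver noise floor rises
        counts = []
        for nep in (0.0, 2e-7, 5e-4):
            cfg = ps.DepthSweepConfig(
                depths_mm=[4.0, 8.0], pO2_levels=[150.0], replicates=3,
                n_photons=3000, noise=ps.NoiseModel(nep=nep), seed=13,
                voxel_mm=0.8, grid_size_mm=(24.0, 24.0, 16.0),
                node_radius_mm=2.0, fit_model="single",
            )
            res = ps.run_depth_sweep(cfg)
            clin = (res.summary["error_mmHg"] > 10.0).sum()
            mdl = (
                res.summary["pct_error_mean"].abs()
                - 2 * res.summary["pct_error_sd"]
                > 0
            ).sum()
            counts.append((clin, mdl))
        assert counts[0] <= counts[1] <= counts[2]
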