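"""Data reduction: extraction, background, rundown, normalization, QC."""

import math
from dataclasses import replace

import numpy as np
import pytest

from patchperm import (
    BarrierModelParams,
    NoiseModel,
    barrier_iv_curve,
    simulate_background,
    simulate_dataset,
    simulate_patch,
)
from patchperm.ivcurve import IVCurve, Normalization
from patchperm.preprocess import (
    aggregate_patches,
    correct_rundown,
    extract_instantaneous,
    normalize_iv,
    preprocess_pair,
    qc_patch,
    subtract_background,
    zero_crossing_mV,
)
from patchperm.simulate import PatchPair

from conftest import VOLTAGE_GRID, scaled_params


def make_pair(protocol, ion, params, noise, thermo, offset=0.0, seed=None):
    n = noise if seed is None else replace(noise, rng_seed=seed)
    test = simulate_patch(protocol, ion, params, n, thermo, voltage_offset_mV=offset)
    bg = simulate_background(protocol, n, thermo, ion=ion, voltage_offset_mV=offset)
    return PatchPair(test=test, background=bg)


class TestExtraction:
    def test_window_inside_dead_time_rejected(
        self, protocol, symmetric_cl, quiet_noise, thermo, linear_params
    ):
        rec = simulate_patch(protocol, symmetric_cl, linear_params, quiet_noise, thermo)
        with pytest.raises(ValueError):
            extract_instantaneous(rec, window_start_ms=0.1, window_end_ms=0.4)

    def test_window_beyond_step_rejected(
        self, protocol, symmetric_cl, quiet_noise, thermo, linear_params
    ):
        rec = simulate_patch(protocol, symmetric_cl, linear_params, quiet_noise, thermo)
        with pytest.raises(ValueError):
            extract_instantaneous(rec, window_end_ms=100.0)

    def test_extractor_averages_down_white_noise(
        self, protocol, symmetric_cl, thermo, linear_params
    ):
        """SEM of the window mean ≈ sd/√n_samples over replicates."""
        params = scaled_params(symmetric_cl, linear_params)
        sd = 5.0
        n_samples = int((2.0 - 0.5) * protocol.sample_rate_khz)
        estimates = []
        for seed in range(200):
            noise = NoiseModel(
                gaussian_sd_pA=sd,
                leak_conductance_pA_per_mV=0.0,
                patch_amplitude_cv=0.0,
                rng_seed=seed,
            )
            rec = simulate_patch(protocol, symmetric_cl, params, noise, thermo)
            iv = extract_instantaneous(rec)
            estimates.append(iv.i_test[-1])
        expected_se = sd / math.sqrt(n_samples)
        assert np.std(estimates) == pytest.approx(expected_se, rel=0.25)


class TestBackgroundSubtraction:
    def test_synthetic_leak_removed_exactly(
        self, protocol, symmetric_cl, thermo, linear_params
    ):
        from patchperm import barrier_current

        params = scaled_params(symmetric_cl, linear_params)
        noise = NoiseModel(
            gaussian_sd_pA=0.0,
            leak_conductance_pA_per_mV=0.05,
            leak_offset_pA=3.0,
            patch_amplitude_cv=0.0,
            rundown_tau_sweeps=np.inf,
        )
        pair = make_pair(protocol, symmetric_cl, params, noise, thermo)
        iv = subtract_background(
            extract_instantaneous(pair.test), extract_instantaneous(pair.background)
        )
        for v, i in zip(iv.test_voltage, iv.i_test):
            assert i == pytest.approx(
                barrier_current(v, symmetric_cl, params, thermo), abs=1e-10 * 500
            )

    def test_patch_mismatch_rejected(
        self, protocol, symmetric_cl, quiet_noise, thermo, linear_params
    ):
        rec = simulate_patch(
            protocol, symmetric_cl, linear_params, quiet_noise, thermo, patch_id="a"
        )
        bg = simulate_background(protocol, quiet_noise, thermo, patch_id="b")
        with pytest.raises(ValueError):
            subtract_background(extract_instantaneous(rec), extract_instantaneous(bg))


class TestRundownCorrection:
    def test_correction_restores_first_sweep_scale(
        self, protocol, symmetric_cl, quiet_noise, thermo
    ):
        from patchperm import barrier_current

        params = scaled_params(symmetric_cl, BarrierModelParams())
        noise = replace(quiet_noise, rundown_tau_sweeps=5.0)
        pair = make_pair(protocol, symmetric_cl, params, noise, thermo)
        iv = subtract_background(
            extract_instantaneous(pair.test), extract_instantaneous(pair.background)
        )
        corrected = correct_rundown(iv)
        for v, i in zip(corrected.test_voltage, corrected.i_test):
            assert i == pytest.approx(
                barrier_current(v, symmetric_cl, params, thermo), rel=1e-10
            )

    def test_no_rundown_is_identity(self, protocol, symmetric_cl, quiet_noise, thermo):
        params = scaled_params(symmetric_cl, BarrierModelParams())
        pair = make_pair(protocol, symmetric_cl, params, quiet_noise, thermo)
        iv = subtract_background(
            extract_instantaneous(pair.test), extract_instantaneous(pair.background)
        )
        corrected = correct_rundown(iv)
        np.testing.assert_allclose(corrected.i_test, iv.i_test, rtol=1e-12)

    def test_uncorrected_rundown_fakes_rectification(
        self, protocol, symmetric_cl, quiet_noise, thermo
    ):
        """Skipping the correction biases RI away from 1 for a linear pore.

        Test voltages run −100 → +120 in order, so later (more positive)
        sweeps have lost more current; without correction the linear WT
        pore appears inward-rectifying.
        """
        from patchperm import rectification_index

        params = scaled_params(symmetric_cl, BarrierModelParams())
        noise = replace(quiet_noise, rundown_tau_sweeps=5.0)
        pair = make_pair(protocol, symmetric_cl, params, noise, thermo)
        iv = subtract_background(
            extract_instantaneous(pair.test), extract_instantaneous(pair.background)
        )
        # normalize without correcting (bypass the guard deliberately)
        skipped = replace(iv, rundown_corrected=True)
        ri_skipped = rectification_index(normalize_iv(skipped))
        ri_corrected = rectification_index(normalize_iv(correct_rundown(iv)))
        assert ri_corrected == pytest.approx(1.0, rel=1e-9)
        assert ri_skipped < 0.9

    def test_dead_reference_signalled(self, protocol, symmetric_cl, quiet_noise, thermo):
        params = scaled_params(symmetric_cl, BarrierModelParams())
        noise = replace(quiet_noise, rundown_tau_sweeps=5.0)
        pair = make_pair(protocol, symmetric_cl, params, noise, thermo)
        iv = subtract_background(
            extract_instantaneous(pair.test), extract_instantaneous(pair.background)
        )
        iv.i_prepulse[0] = 0.0
        with pytest.raises(ZeroDivisionError):
            correct_rundown(iv)


class TestNormalization:
    def test_order_of_corrections_enforced(
        self, protocol, symmetric_cl, quiet_noise, thermo, linear_params
    ):
        rec = simulate_patch(protocol, symmetric_cl, linear_params, quiet_noise, thermo)
        iv = extract_instantaneous(rec)
        with pytest.raises(ValueError):
            correct_rundown(iv)  # background not yet subtracted
        with pytest.raises(ValueError):
            normalize_iv(iv)  # rundown not yet corrected

    def test_full_pipeline_identity_on_clean_data(
        self, protocol, symmetric_cl, thermo
    ):
        params = scaled_params(symmetric_cl, BarrierModelParams(3, 0.1, 1.0))
        noise = NoiseModel(
            gaussian_sd_pA=0.0,
            leak_conductance_pA_per_mV=0.05,
            leak_offset_pA=1.0,
            rundown_tau_sweeps=5.0,
            patch_amplitude_cv=0.0,
        )
        pair = make_pair(protocol, symmetric_cl, params, noise, thermo)
        curve, _ = preprocess_pair(pair)
        model = barrier_iv_curve(
            curve.voltages, symmetric_cl, params, thermo, normalize=True
        )
        np.testing.assert_allclose(curve.currents, model.currents, atol=1e-10)


class TestQC:
    @pytest.mark.parametrize(
        "offset,expected_pass", [(0.0, True), (2.5, False), (-1.0, True)]
    )
    def test_injected_offset_measured_and_filtered(
        self, protocol, symmetric_cl, quiet_noise, thermo, offset, expected_pass
    ):
        params = scaled_params(symmetric_cl, BarrierModelParams())
        pair = make_pair(
            protocol, symmetric_cl, params, quiet_noise, thermo, offset=offset
        )
        _, report = preprocess_pair(pair)
        assert report.voltage_offset_mV == pytest.approx(offset, abs=0.05)
        assert report.offset_pass is expected_pass

    def test_flat_curve_offset_indeterminate(self):
        curve = IVCurve(VOLTAGE_GRID, np.ones_like(VOLTAGE_GRID))
        with pytest.raises(ValueError):
            qc_patch(curve)


class TestAggregation:
    def test_single_curve_aggregates_to_itself(self, symmetric_cl, linear_params):
        curve = barrier_iv_curve(
            VOLTAGE_GRID, symmetric_cl, linear_params, normalize=True
        )
        agg = aggregate_patches([curve])
        np.testing.assert_array_equal(agg.currents, curve.currents)
        assert np.all(agg.sem == 0.0)
        assert agg.n_patches == 1

    def test_mean_within_3_sem_of_truth(self, protocol, symmetric_cl, thermo):
        params = scaled_params(symmetric_cl, BarrierModelParams())
        noise = NoiseModel(gaussian_sd_pA=10.0, patch_amplitude_cv=0.2)
        ds = simulate_dataset(
            12,
            {"WT": params},
            protocol=protocol,
            ion=symmetric_cl,
            noise=noise,
            thermo=thermo,
            offset_range_mV=0.0,
            master_seed=21,
        )
        agg = aggregate_patches([preprocess_pair(p)[0] for p in ds["WT"]])
        model = barrier_iv_curve(
            agg.voltages, symmetric_cl, params, thermo, normalize=True
        )
        margin = 3.0 * np.maximum(agg.sem, 1e-4)
        assert np.all(np.abs(agg.currents - model.currents) <= margin)

    def test_sem_shrinks_as_root_n(self, protocol, symmetric_cl, thermo):
        params = scaled_params(symmetric_cl, BarrierModelParams())
        noise = NoiseModel(gaussian_sd_pA=10.0, patch_amplitude_cv=0.0)
        sems = {}
        for n in (4, 16):
            ds = simulate_dataset(
                n,
                {"WT": params},
                protocol=protocol,
                ion=symmetric_cl,
                noise=noise,
                thermo=thermo,
                offset_range_mV=0.0,
                master_seed=5,
            )
            agg = aggregate_patches([preprocess_pair(p)[0] for p in ds["WT"]])
            sems[n] = np.mean(agg.sem[agg.sem > 0])
        assert sems[4] / sems[16] == pytest.approx(2.0, rel=0.35)

    def test_grid_mismatch_rejected(self, symmetric_cl, linear_params):
        a = barrier_iv_curve(VOLTAGE_GRID, symmetric_cl, linear_params, normalize=True)
        b = barrier_iv_curve(
            np.arange(-100.0, 121.0, 20.0), symmetric_cl, linear_params, normalize=True
        )
        with pytest.raises(ValueError):
            aggregate_patches([a, b])


class TestZeroCrossing:
    def test_linear_interpolation_between_brackets(self):
        curve = IVCurve(np.array([-20.0, 20.0]), np.array([-1.0, 3.0]))
        assert zero_crossing_mV(curve) == pytest.approx(-10.0)

    def test_multiple_crossings_ambiguous(self):
        curve = IVCurve(
            np.array([-40.0, -20.0, 0.0, 20.0]), np.array([-1.0, 1.0, -1.0, 1.0])
        )
        with pytest.raises(ValueError):
            zero_crossing_mV(curve)
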