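"""Barrier-model fitting, conductance measures, and parameter recovery."""

import math

import numpy as np
import pytest

from patchperm import (
    BarrierModelParams,
    IonSpec,
    NoiseModel,
    barrier_current,
    barrier_iv_curve,
    energy_profile_from_params,
    fit_barrier_model,
    iv_from_chain,
    rectification_index_from_data,
    simulate_dataset,
    slope_conductance,
    concentration_conductance,
)
from patchperm.hopping import HoppingChain
from patchperm.ivcurve import IVCurve, Normalization
from patchperm.preprocess import aggregate_patches, preprocess_pair

from conftest import VOLTAGE_GRID, scaled_params


def recover(curve, ion, thermo):
    fit = fit_barrier_model(curve, ion, thermo)
    return fit.params_hat.sigma_beta, fit.params_hat.sigma_h, fit


class TestFitBarrierModel:
    @pytest.mark.parametrize("sb,sh", [(1.0, 1.0), (0.1, 1.0), (2.0, 0.3)])
    def test_noise_free_self_consistency(self, symmetric_cl, thermo, sb, sh):
        curve = barrier_iv_curve(
            VOLTAGE_GRID, symmetric_cl, BarrierModelParams(3, sb, sh), thermo,
            normalize=True,
        )
        got_sb, got_sh, fit = recover(curve, symmetric_cl, thermo)
        assert got_sb == pytest.approx(sb, abs=1e-6 * max(sb, 1))
        assert got_sh == pytest.approx(sh, abs=1e-6 * max(sh, 1))
        assert fit.converged
        assert fit.residual_norm < 1e-8

    def test_energy_profile_matches_estimates_exactly(self, symmetric_cl, thermo):
        curve = barrier_iv_curve(
            VOLTAGE_GRID, symmetric_cl, BarrierModelParams(3, 0.2, 2.0), thermo,
            normalize=True,
        )
        fit = fit_barrier_model(curve, symmetric_cl, thermo)
        ref = energy_profile_from_params(fit.params_hat, thermo)
        assert fit.energy_profile == ref

    def test_requires_normalized_curve(self, symmetric_cl, thermo, linear_params):
        raw = barrier_iv_curve(VOLTAGE_GRID, symmetric_cl, linear_params, thermo)
        with pytest.raises(ValueError):
            fit_barrier_model(raw, symmetric_cl, thermo)

    def test_deterministic_given_inputs(self, symmetric_cl, thermo):
        curve = barrier_iv_curve(
            VOLTAGE_GRID, symmetric_cl, BarrierModelParams(3, 0.3, 1.5), thermo,
            normalize=True,
        )
        a = fit_barrier_model(curve, symmetric_cl, thermo)
        b = fit_barrier_model(curve, symmetric_cl, thermo)
        assert a.params_hat == b.params_hat
        assert a.residual_norm == b.residual_norm

    def test_amplitude_recovered_from_raw_scale(self, symmetric_cl, thermo):
        true = scaled_params(symmetric_cl, BarrierModelParams(3, 0.5, 1.0), 800.0)
        curve = barrier_iv_curve(VOLTAGE_GRID, symmetric_cl, true, thermo, normalize=True)
        raw120 = barrier_current(120.0, symmetric_cl, true, thermo)
        fit = fit_barrier_model(
            curve, symmetric_cl, thermo, raw_current_at_120mV_pA=raw120
        )
        assert fit.params_hat.amplitude == pytest.approx(true.amplitude, rel=1e-6)

    def test_recovery_from_noisy_replicated_patches(
        self, protocol, symmetric_cl, thermo
    ):
        """12 patches at 2% noise with rundown and offsets: ln σβ within ±0.2."""
        true_sb = 0.1
        params = scaled_params(symmetric_cl, BarrierModelParams(3, true_sb, 1.0))
        noise = NoiseModel(
            gaussian_sd_pA=10.0, rundown_tau_sweeps=20.0, patch_amplitude_cv=0.3
        )
        ds = simulate_dataset(
            12, {"m": params}, protocol=protocol, ion=symmetric_cl,
            noise=noise, thermo=thermo, master_seed=77,
        )
        curves = [c for c, r in (preprocess_pair(p) for p in ds["m"]) if r.offset_pass]
        fit = fit_barrier_model(aggregate_patches(curves), symmetric_cl, thermo)
        assert abs(math.log(fit.params_hat.sigma_beta) - math.log(true_sb)) <= 0.2
        assert fit.rectification_index > 1.0

    def test_estimator_error_shrinks_with_noise(self, protocol, symmetric_cl, thermo):
        """MSE of ln σ̂β decreases monotonically across noise levels."""
        true_sb = 0.3
        params = scaled_params(symmetric_cl, BarrierModelParams(3, true_sb, 1.0))
        mse = []
        for sd_frac in (0.05, 0.02, 0.005):
            errs = []
            for rep in range(8):
                noise = NoiseModel(
                    gaussian_sd_pA=sd_frac * 500.0,
                    rundown_tau_sweeps=20.0,
                    patch_amplitude_cv=0.3,
                )
                ds = simulate_dataset(
                    12, {"m": params}, protocol=protocol, ion=symmetric_cl,
                    noise=noise, thermo=thermo, master_seed=3000 + rep,
                )
                curves = [
                    c for c, r in (preprocess_pair(p) for p in ds["m"]) if r.offset_pass
                ]
                fit = fit_barrier_model(aggregate_patches(curves), symmetric_cl, thermo)
                errs.append(
                    (math.log(fit.params_hat.sigma_beta) - math.log(true_sb)) ** 2
                )
            mse.append(np.mean(errs))
        assert mse[0] > mse[1] > mse[2]

    def test_well_posed_fit_stays_off_bounds(self, symmetric_cl, thermo):
        curve = barrier_iv_curve(
            VOLTAGE_GRID, symmetric_cl, BarrierModelParams(3, 0.1, 1.0), thermo,
            normalize=True,
        )
        fit = fit_barrier_model(curve, symmetric_cl, thermo)
        for val in (fit.params_hat.sigma_beta, fit.params_hat.sigma_h):
            assert 1e-3 * 1.01 < val < 1e3 * 0.99


class TestRectificationFromData:
    def test_linear_curve_gives_unity(self):
        curve = IVCurve(
            VOLTAGE_GRID, VOLTAGE_GRID / 120.0,
            normalization=Normalization.NORMALIZED_TO_PLUS120MV,
        )
        assert rectification_index_from_data(curve) == pytest.approx(1.0)

    def test_matches_ground_truth_model_ri(self, protocol, symmetric_cl, thermo):
        from patchperm import rectification_index

        true = BarrierModelParams(3, 0.1, 1.0)
        params = scaled_params(symmetric_cl, true)
        noise = NoiseModel(gaussian_sd_pA=10.0, patch_amplitude_cv=0.2)
        ds = simulate_dataset(
            12, {"m": params}, protocol=protocol, ion=symmetric_cl,
            noise=noise, thermo=thermo, offset_range_mV=0.0, master_seed=8,
        )
        agg = aggregate_patches([preprocess_pair(p)[0] for p in ds["m"]])
        assert rectification_index_from_data(agg) == pytest.approx(
            rectification_index(true, symmetric_cl, thermo), rel=0.1
        )

    def test_oracle_generated_inward_rectifier(self, symmetric_cl):
        curve = iv_from_chain(
            HoppingChain((1.0, 1.0, 0.1)), symmetric_cl, VOLTAGE_GRID, normalize=True
        )
        assert rectification_index_from_data(curve) < 1.0


class TestSlopeConductance:
    def test_straight_line_recovered_exactly(self):
        curve = IVCurve(VOLTAGE_GRID, 0.25 * VOLTAGE_GRID + 3.0)
        assert slope_conductance(curve, -100.0) == pytest.approx(0.25)

    def test_matches_analytic_derivative_for_linear_pore(
        self, symmetric_cl, thermo, linear_params
    ):
        fine = np.arange(-120.0, -79.0, 2.0)
        curve = barrier_iv_curve(fine, symmetric_cl, linear_params, thermo)
        got = slope_conductance(curve, -100.0, window_mV=10.0)
        h = 1e-3
        want = (
            barrier_current(-100.0 + h, symmetric_cl, linear_params, thermo)
            - barrier_current(-100.0 - h, symmetric_cl, linear_params, thermo)
        ) / (2 * h)
        assert got == pytest.approx(want, rel=0.01)

    def test_single_point_rejected(self):
        curve = IVCurve(np.array([-100.0, 40.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            slope_conductance(curve, -100.0, window_mV=10.0)


class TestConcentrationConductance:
    def test_model_conductance_linear_in_concentration(self, thermo, linear_params):
        grid = np.arange(-120.0, 121.0, 20.0)
        datasets = {
            c: barrier_iv_curve(grid, IonSpec(-1, c, c), linear_params, thermo)
            for c in (15.0, 37.5, 75.0, 150.0)
        }
        table, summary = concentration_conductance(datasets)
        g = table["conductance_pA_per_mV"].to_numpy()
        c = table["concentration_mM"].to_numpy()
        ratio = g / c
        assert np.ptp(ratio) / ratio.mean() < 1e-6
        assert summary is not None and not summary["saturating"]

    def test_duplicate_concentration_gives_identical_conductance(
        self, thermo, linear_params, symmetric_cl
    ):
        curve = barrier_iv_curve(VOLTAGE_GRID, symmetric_cl, linear_params, thermo)
        table, _ = concentration_conductance({150.0: curve, 150.0 + 0.0: curve})
        assert len(table) == 1  # same key collapses; sanity only

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            concentration_conductance({})
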