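import numpy as np
import pytest

from patchperm import (
    BarrierModelParams,
    IonSpec,
    NoiseModel,
    StepProtocol,
    Thermo,
    amplitude_for_current,
)

VOLTAGE_GRID = np.arange(-120.0, 121.0, 20.0)


@pytest.fixture
def thermo():
    return Thermo()


@pytest.fixture
def symmetric_cl():
    """150 mM Cl⁻ on both sides, the rectification-experiment condition."""
    return IonSpec(valence=-1, conc_in=150.0, conc_out=150.0)


@pytest.fixture
def linear_params():
    """Equal barriers: a linear, non-rectifying pore."""
    return BarrierModelParams(n_barriers=3, sigma_beta=1.0, sigma_h=1.0)


@pytest.fixture
def protocol():
    return StepProtocol()


@pytest.fixture
def quiet_noise():
    """No stochastic noise, no rundown, no leak: generator in oracle mode."""
    return NoiseModel(
        gaussian_sd_pA=0.0,
        leak_conductance_pA_per_mV=0.0,
        leak_offset_pA=0.0,
        rundown_tau_sweeps=np.inf,
        patch_amplitude_cv=0.0,
    )


def scaled_params(ion, base, target_pA=500.0):
    """Ground-truth params rescaled to a physiological +120 mV current."""
    from dataclasses import replace

    return replace(base, amplitude=amplitude_for_current(target_pA, ion, base))
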