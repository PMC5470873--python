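"""Synthetic inside-out patch-clamp recordings with known ground truth.

Emulates the instantaneous-current step protocol used to characterize
Ca²⁺-activated Cl⁻ currents: each sweep holds, jumps to a fixed +80 mV
pre-pulse (the rundown reference), then to one test voltage. Channel
currents follow the closed-form barrier model and respond instantaneously
to voltage (recordings at saturating 1 mM Ca²⁺ minimize gating relaxation;
an optional mono-exponential relaxation hook exists but defaults off).

Imperfections layered on top, each with a known ground truth:

* multiplicative per-sweep rundown, availability a_s = exp(−s/τ), applied
  identically at pre-pulse and test step — the premise that makes
  pre-pulse-based correction exact;
* an ohmic leak g·(v − offset) + b present with and without Ca²⁺;
* a per-patch voltage offset (channel and leak both see v_cmd − offset, so
  the zero crossing measured in symmetric solutions equals the offset);
* per-patch lognormal amplitude variability and Gaussian sample noise;
* a dead time after each voltage step during which samples are flagged
  unusable (stand-in for capacitive transients).

Ca²⁺-free background sweeps contain only leak and noise and are paired to
their test recording by patch id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .barrier import BarrierModelParams, barrier_current
from .thermo import IonSpec, Thermo

__all__ = [
    "StepProtocol",
    "NoiseModel",
    "Sweep",
    "PatchRecording",
    "PatchPair",
    "simulate_patch",
    "simulate_background",
    "simulate_dataset",
    "amplitude_for_current",
]

DEFAULT_TEST_VOLTAGES = tuple(float(v) for v in range(-100, 121, 20))


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol of one sweep: holding → pre-pulse → test step."""

    prepulse_voltage: float = 80.0
    prepulse_duration_ms: float = 15.0
    test_voltages: Tuple[float, ...] = DEFAULT_TEST_VOLTAGES
    test_duration_ms: float = 15.0
    holding_voltage: float = 0.0
    holding_duration_ms: float = 5.0
    sample_rate_khz: float = 20.0
    filter_cutoff_khz: float = 5.0  # metadata only; no digital re-filtering
    dead_time_ms: float = 0.5

    def __post_init__(self) -> None:
        tv = tuple(float(v) for v in self.test_voltages)
        object.__setattr__(self, "test_voltages", tv)
        for required in (120.0, 100.0, -100.0):
            if not any(math.isclose(v, required) for v in tv):
                raise ValueError(
                    f"test voltages must include {required:+.0f} mV "
                    "(normalization and rectification index depend on it)"
                )
        if self.sample_rate_khz <= 2 * self.filter_cutoff_khz:
            raise ValueError("sample rate must exceed twice the filter cutoff")
        if min(self.prepulse_duration_ms, self.test_duration_ms) <= self.dead_time_ms:
            raise ValueError("step segments must outlast the dead time")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sample_rate_khz

    @property
    def sweep_duration_ms(self) -> float:
        return (
            self.holding_duration_ms + self.prepulse_duration_ms + self.test_duration_ms
        )

    @property
    def prepulse_onset_ms(self) -> float:
        return self.holding_duration_ms

    @property
    def test_onset_ms(self) -> float:
        return self.holding_duration_ms + self.prepulse_duration_ms

    def time_base_ms(self) -> np.ndarray:
        n = int(round(self.sweep_duration_ms * self.sample_rate_khz))
        return np.arange(n) * self.dt_ms

    def command_trace(self, test_voltage: float) -> np.ndarray:
        t = self.time_base_ms()
        v = np.full(t.shape, self.holding_voltage)
        v[t >= self.prepulse_onset_ms] = self.prepulse_voltage
        v[t >= self.test_onset_ms] = float(test_voltage)
        return v

    def usable_mask(self) -> np.ndarray:
        """False within ``dead_time_ms`` after each voltage step."""
        t = self.time_base_ms()
        mask = np.ones(t.shape, dtype=bool)
        for onset in (self.prepulse_onset_ms, self.test_onset_ms):
            mask[(t >= onset) & (t < onset + self.dead_time_ms)] = False
        return mask


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic and systematic imperfections of a synthetic patch."""

    gaussian_sd_pA: float = 2.0
    leak_conductance_pA_per_mV: float = 0.05
    leak_offset_pA: float = 0.0
    rundown_tau_sweeps: float = math.inf
    patch_amplitude_cv: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gaussian_sd_pA, self.leak_conductance_pA_per_mV) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.rundown_tau_sweeps <= 0:
            raise ValueError("rundown_tau_sweeps must be positive (inf disables rundown)")
        if self.patch_amplitude_cv < 0:
            raise ValueError("patch_amplitude_cv must be non-negative")

    def availability(self, sweep_index: int) -> float:
        """Fraction of channels still active in sweep ``sweep_index``."""
        if math.isinf(self.rundown_tau_sweeps):
            return 1.0
        return math.exp(-sweep_index / self.rundown_tau_sweeps)


@dataclass
class Sweep:
    sweep_index: int
    test_voltage: float
    command_mV: np.ndarray
    current_pA: np.ndarray


@dataclass
class PatchRecording:
    """Ordered sweeps from one membrane patch plus condition metadata."""

    patch_id: str
    protocol: StepProtocol
    sweeps: List[Sweep]
    ion: IonSpec
    calcium_mM: float
    voltage_offset_mV: float = 0.0
    true_params: Optional[BarrierModelParams] = None
    thermo: Thermo = field(default_factory=Thermo)

    def __post_init__(self) -> None:
        nb = len(self.protocol.time_base_ms())
        for s in self.sweeps:
            if len(s.current_pA) != nb or len(s.command_mV) != nb:
                raise ValueError("all sweeps must share the protocol's time base")


@dataclass
class PatchPair:
    """A test recording and its Ca²⁺-free background from the same patch."""

    test: PatchRecording
    background: PatchRecording


def amplitude_for_current(
    target_pA: float,
    ion: IonSpec,
    params: BarrierModelParams,
    thermo: Thermo = Thermo(),
    at_voltage_mV: float = 120.0,
) -> float:
    """Amplitude A giving |I| = ``target_pA`` at ``at_voltage_mV``.

    The model is linear in A, so this is a single division; convenient for
    setting physiologically sized currents (hundreds of pA to nA).
    """
    unit = barrier_current(at_voltage_mV, ion, replace(params, amplitude=1.0), thermo)
    if unit == 0:
        raise ZeroDivisionError("model current vanishes at the calibration voltage")
    return abs(target_pA / unit)


def _channel_current(
    v_cmd: np.ndarray,
    ion: IonSpec,
    params: BarrierModelParams,
    thermo: Thermo,
    offset_mV: float,
) -> np.ndarray:
    levels = {float(v) for v in np.unique(v_cmd)}
    lut = {
        v: barrier_current(v - offset_mV, ion, params, thermo) for v in levels
    }
    out = np.empty_like(v_cmd, dtype=float)
    for v, i in lut.items():
        out[v_cmd == v] = i
    return out


def simulate_patch(
    protocol: StepProtocol,
    ion: IonSpec,
    params: BarrierModelParams,
    noise: NoiseModel,
    thermo: Thermo = Thermo(),
    patch_id: str = "patch0",
    voltage_offset_mV: float = 0.0,
    calcium_mM: float = 1.0,
    relaxation_tau_ms: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> PatchRecording:
    """One activated-patch recording: one sweep per test voltage, in order.

    Sweep ``s`` carries channel current a_s·I_model(v − offset) at the
    pre-pulse and the test step, the ohmic leak everywhere, and Gaussian
    noise per sample. ``relaxation_tau_ms`` optionally relaxes each step's
    channel current mono-exponentially from the previous level (off by
    default: instantaneous currents only).
    """
    if rng is None:
        rng = np.random.default_rng(noise.rng_seed)
    t = protocol.time_base_ms()
    sweeps: List[Sweep] = []
    for s, v_test in enumerate(protocol.test_voltages):
        v_cmd = protocol.command_trace(v_test)
        i_chan = _channel_current(v_cmd, ion, params, thermo, voltage_offset_mV)
        if relaxation_tau_ms is not None:
            i_chan = _apply_relaxation(i_chan, t, protocol, relaxation_tau_ms)
        a_s = noise.availability(s)
        leak = (
            noise.leak_conductance_pA_per_mV * (v_cmd - voltage_offset_mV)
            + noise.leak_offset_pA
        )
        current = a_s * i_chan + leak
        if noise.gaussian_sd_pA > 0:
            current = current + rng.normal(0.0, noise.gaussian_sd_pA, size=t.shape)
        sweeps.append(Sweep(s, float(v_test), v_cmd, current))
    return PatchRecording(
        patch_id=patch_id,
        protocol=protocol,
        sweeps=sweeps,
        ion=ion,
        calcium_mM=calcium_mM,
        voltage_offset_mV=voltage_offset_mV,
        true_params=params,
        thermo=thermo,
    )


def _apply_relaxation(
    i_target: np.ndarray, t: np.ndarray, protocol: StepProtocol, tau_ms: float
) -> np.ndarray:
    out = i_target.copy()
    onsets = (protocol.prepulse_onset_ms, protocol.test_onset_ms)
    for k, onset in enumerate(onsets):
        seg = t >= onset if k == len(onsets) - 1 else (t >= onset) & (t < onsets[k + 1])
        idx = np.nonzero(seg)[0]
        if idx.size == 0:
            continue
        prev = out[idx[0] - 1] if idx[0] > 0 else i_target[idx[0]]
        out[idx] = i_target[idx] + (prev - i_target[idx]) * np.exp(
            -(t[idx] - onset) / tau_ms
        )
    return out


def simulate_background(
    protocol: StepProtocol,
    noise: NoiseModel,
    thermo: Thermo = Thermo(),
    ion: Optional[IonSpec] = None,
    patch_id: str = "patch0",
    voltage_offset_mV: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> PatchRecording:
    """Ca²⁺-free sweeps from the same patch: leak and noise only."""
    if rng is None:
        rng = np.random.default_rng(noise.rng_seed)
    if ion is None:
        ion = IonSpec(valence=-1, conc_in=150.0, conc_out=150.0)
    t = protocol.time_base_ms()
    sweeps: List[Sweep] = []
    for s, v_test in enumerate(protocol.test_voltages):
        v_cmd = protocol.command_trace(v_test)
        current = (
            noise.leak_conductance_pA_per_mV * (v_cmd - voltage_offset_mV)
            + noise.leak_offset_pA
        )
        current = current.astype(float)
        if noise.gaussian_sd_pA > 0:
            current = current + rng.normal(0.0, noise.gaussian_sd_pA, size=t.shape)
        sweeps.append(Sweep(s, float(v_test), v_cmd, current))
    return PatchRecording(
        patch_id=patch_id,
        protocol=protocol,
        sweeps=sweeps,
        ion=ion,
        calcium_mM=0.0,
        voltage_offset_mV=voltage_offset_mV,
        true_params=None,
        thermo=thermo,
    )


def simulate_dataset(
    n_patches: int,
    construct_params: Dict[str, BarrierModelParams],
    protocol: StepProtocol = StepProtocol(),
    ion: IonSpec = IonSpec(valence=-1, conc_in=150.0, conc_out=150.0),
    noise: NoiseModel = NoiseModel(),
    thermo: Thermo = Thermo(),
    offset_range_mV: float = 3.0,
    master_seed: int = 0,
) -> Dict[str, List[PatchPair]]:
    """Simulate ``n_patches`` independent patches per construct.

    Per-patch amplitude is drawn lognormally with unit mean and coefficient
    of variation ``noise.patch_amplitude_cv``; the per-patch voltage offset
    is uniform on ±``offset_range_mV`` (the default ±3 mV makes the <2 mV
    acceptance filter reject about a third of patches). All randomness
    derives deterministically from ``master_seed`` and the patch index.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be at least 1")
    cv = noise.patch_amplitude_cv
    log_sd = math.sqrt(math.log1p(cv**2))
    dataset: Dict[str, List[PatchPair]] = {}
    for c_idx, (name, params) in enumerate(construct_params.items()):
        pairs: List[PatchPair] = []
        for p_idx in range(n_patches):
            rng = np.random.default_rng(
                np.random.SeedSequence((master_seed, c_idx, p_idx))
            )
            scale = (
                math.exp(rng.normal(-0.5 * log_sd**2, log_sd)) if cv > 0 else 1.0
            )
            offset = rng.uniform(-offset_range_mV, offset_range_mV)
            patch_params = replace(params, amplitude=params.amplitude * scale)
            pid = f"{name}_p{p_idx:02d}"
            test = simulate_patch(
                protocol,
                ion,
                patch_params,
                noise,
                thermo,
                patch_id=pid,
                voltage_offset_mV=offset,
                rng=rng,
            )
            background = simulate_background(
                protocol,
                noise,
                thermo,
                ion=ion,
                patch_id=pid,
                voltage_offset_mV=offset,
                rng=rng,
            )
            pairs.append(PatchPair(test=test, background=background))
        dataset[name] = pairs
    return dataset
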