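"""Raw sweeps → rundown-corrected, background-subtracted, normalized I-V.

The reduction follows the rules used for instantaneous Cl⁻-current
recordings: background sweeps recorded without intracellular Ca²⁺ are
subtracted first; the test current of each sweep is then divided by the
fraction of current remaining during the +80 mV pre-pulse (relative to the
first sweep) to undo rundown — uncorrected rundown masquerades as
rectification because test voltages are visited in order; finally currents
are normalized to the response at +120 mV. Patches are accepted only when
the voltage offset measured in symmetric solutions is below 2 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ivcurve import IVCurve, Normalization
from .simulate import PatchPair, PatchRecording

__all__ = [
    "InstantaneousIV",
    "QCReport",
    "extract_instantaneous",
    "subtract_background",
    "correct_rundown",
    "normalize_iv",
    "qc_patch",
    "aggregate_patches",
    "preprocess_pair",
    "zero_crossing_mV",
]

OFFSET_ACCEPT_MV = 2.0  # patches at or above this offset are rejected


@dataclass
class InstantaneousIV:
    """Per-sweep instantaneous currents at the pre-pulse and the test step."""

    patch_id: str
    sweep_index: np.ndarray
    test_voltage: np.ndarray
    i_prepulse: np.ndarray
    i_test: np.ndarray
    background_subtracted: bool = False
    rundown_corrected: bool = False

    def __post_init__(self) -> None:
        for name in ("sweep_index", "test_voltage", "i_prepulse", "i_test"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.test_voltage.shape
            == self.i_prepulse.shape
            == self.i_test.shape
            == self.sweep_index.shape
        ):
            raise ValueError("per-sweep arrays must share one shape")


@dataclass
class QCReport:
    voltage_offset_mV: float
    offset_pass: bool
    n_sweeps_used: int
    exclusion_reasons: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = abs(self.voltage_offset_mV) < OFFSET_ACCEPT_MV
        if self.offset_pass != expected:
            raise ValueError("offset_pass inconsistent with the <2 mV rule")


def extract_instantaneous(
    recording: PatchRecording,
    window_start_ms: float = 0.5,
    window_end_ms: float = 2.0,
) -> InstantaneousIV:
    """Average the current in a fixed window after each voltage jump.

    The window is measured from each step onset and must lie beyond the
    protocol's dead time (capacitive-transient blanking) and inside the
    step segment.
    """
    proto = recording.protocol
    if window_start_ms < proto.dead_time_ms:
        raise ValueError(
            f"window starts at {window_start_ms} ms, inside the "
            f"{proto.dead_time_ms} ms dead time"
        )
    if window_end_ms <= window_start_ms:
        raise ValueError("window must have positive length")
    if window_end_ms > min(proto.prepulse_duration_ms, proto.test_duration_ms):
        raise ValueError("window extends beyond the step segment")

    t = proto.time_base_ms()
    sel_pre = (t >= proto.prepulse_onset_ms + window_start_ms) & (
        t < proto.prepulse_onset_ms + window_end_ms
    )
    sel_test = (t >= proto.test_onset_ms + window_start_ms) & (
        t < proto.test_onset_ms + window_end_ms
    )
    if not (sel_pre.any() and sel_test.any()):
        raise ValueError("extraction window contains no samples")

    rows = [
        (s.sweep_index, s.test_voltage, s.current_pA[sel_pre].mean(), s.current_pA[sel_test].mean())
        for s in recording.sweeps
    ]
    idx, volts, i_pre, i_test = map(np.array, zip(*rows))
    return InstantaneousIV(recording.patch_id, idx, volts, i_pre, i_test)


def subtract_background(iv: InstantaneousIV, background: InstantaneousIV) -> InstantaneousIV:
    """Pointwise subtraction of the Ca²⁺-free background at matched voltages."""
    if iv.background_subtracted:
        raise ValueError("background already subtracted")
    if iv.patch_id != background.patch_id:
        raise ValueError(
            f"patch mismatch: {iv.patch_id!r} vs {background.patch_id!r}"
        )
    if not np.allclose(iv.test_voltage, background.test_voltage):
        raise ValueError("background sweeps do not match the test voltages")
    return replace(
        iv,
        i_prepulse=iv.i_prepulse - background.i_prepulse,
        i_test=iv.i_test - background.i_test,
        background_subtracted=True,
    )


def correct_rundown(
    iv: InstantaneousIV, reference_floor_fraction: float = 0.01
) -> InstantaneousIV:
    """Divide each test current by the remaining pre-pulse fraction.

    The reference is the first accepted sweep (maximal availability). If its
    pre-pulse current is below ``reference_floor_fraction`` of the largest
    pre-pulse magnitude, rundown is deemed uncorrectable.
    """
    if not iv.background_subtracted:
        raise ValueError("subtract background before correcting rundown")
    if iv.rundown_corrected:
        raise ValueError("rundown already corrected")
    order = np.argsort(iv.sweep_index)
    ref = iv.i_prepulse[order[0]]
    ceiling = np.max(np.abs(iv.i_prepulse))
    if ceiling == 0 or abs(ref) < reference_floor_fraction * ceiling:
        raise ZeroDivisionError(
            "uncorrectable rundown: reference pre-pulse current is below the floor"
        )
    fraction = iv.i_prepulse / ref
    return replace(
        iv,
        i_test=iv.i_test / fraction,
        i_prepulse=np.full_like(iv.i_prepulse, ref),
        rundown_corrected=True,
    )


def normalize_iv(iv: InstantaneousIV, floor: float = 1e-12) -> IVCurve:
    """Normalize the rundown-corrected I-V to its +120 mV response."""
    if not iv.rundown_corrected:
        raise ValueError("correct rundown before normalizing")
    order = np.argsort(iv.test_voltage)
    volts = iv.test_voltage[order]
    currents = iv.i_test[order]
    at120 = np.isclose(volts, 120.0)
    if not at120.any():
        raise ValueError("+120 mV response required for normalization")
    divisor = float(currents[at120][0])
    if abs(divisor) < floor:
        raise ZeroDivisionError("degenerate normalization: response at +120 mV ≈ 0")
    return IVCurve(
        volts,
        currents / divisor,
        normalization=Normalization.NORMALIZED_TO_PLUS120MV,
    )


def zero_crossing_mV(curve: IVCurve) -> float:
    """Zero crossing of an I-V curve by linear interpolation.

    Raises if the curve never changes sign (no crossing in range) or
    changes sign more than once (ambiguous, e.g. a noisy flat curve).
    """
    i = curve.currents
    v = curve.voltages
    crossings = []
    for k in range(len(i) - 1):
        if i[k] == 0 and (k == 0 or i[k - 1] != 0):
            crossings.append(float(v[k]))
        elif i[k] * i[k + 1] < 0:
            crossings.append(float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])))
    if i[-1] == 0:
        crossings.append(float(v[-1]))
    if len(crossings) == 0:
        raise ValueError("no zero crossing within the voltage range")
    if len(crossings) > 1:
        raise ValueError(f"ambiguous reversal: {len(crossings)} zero crossings")
    return crossings[0]


def qc_patch(
    symmetric_control_iv: IVCurve,
    patch_id: str = "",
    n_sweeps_used: Optional[int] = None,
) -> QCReport:
    """Voltage-offset QC from an I-V recorded in symmetric solutions.

    The offset is the curve's zero crossing; patches with |offset| ≥ 2 mV
    are rejected.
    """
    reasons: List[str] = []
    offset = zero_crossing_mV(symmetric_control_iv)
    passed = abs(offset) < OFFSET_ACCEPT_MV
    if not passed:
        reasons.append(f"voltage offset {offset:+.2f} mV ≥ {OFFSET_ACCEPT_MV} mV")
    return QCReport(
        voltage_offset_mV=offset,
        offset_pass=passed,
        n_sweeps_used=n_sweeps_used if n_sweeps_used is not None else len(symmetric_control_iv),
        exclusion_reasons=reasons,
    )


def aggregate_patches(curves: Sequence[IVCurve]) -> IVCurve:
    """Pointwise mean ± s.e.m. across patches on a common voltage grid."""
    if len(curves) == 0:
        raise ValueError("no curves to aggregate")
    grid = curves[0].voltages
    for c in curves:
        if c.normalization != Normalization.NORMALIZED_TO_PLUS120MV:
            raise ValueError("aggregate only normalized curves")
        if c.voltages.shape != grid.shape or not np.allclose(c.voltages, grid):
            raise ValueError("voltage grids do not align across patches")
    stack = np.vstack([c.currents for c in curves])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return IVCurve(
        grid,
        mean,
        sem=sem,
        normalization=Normalization.NORMALIZED_TO_PLUS120MV,
        n_patches=n,
    )


def preprocess_pair(
    pair: PatchPair,
    window_start_ms: float = 0.5,
    window_end_ms: float = 2.0,
    symmetric_control: Optional[IVCurve] = None,
) -> Tuple[IVCurve, QCReport]:
    """Full single-patch reduction: extract → subtract → rundown → normalize → QC.

    When the recording itself is in symmetric solutions (the rectification
    datasets) its own normalized curve doubles as the symmetric control;
    otherwise pass one recorded separately for the same patch.
    """
    iv = extract_instantaneous(pair.test, window_start_ms, window_end_ms)
    bg = extract_instantaneous(pair.background, window_start_ms, window_end_ms)
    iv = subtract_background(iv, bg)
    iv = correct_rundown(iv)
    curve = normalize_iv(iv)
    control = symmetric_control if symmetric_control is not None else curve
    report = qc_patch(control, pair.test.patch_id, n_sweeps_used=len(pair.test.sweeps))
    return curve, report
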