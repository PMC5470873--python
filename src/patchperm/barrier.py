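"""Closed-form multi-barrier Eyring permeation model.

The open-channel current through a chain of ``n`` symmetric Eyring barriers
spanning equal fractions of the transmembrane electric field is, with
u = zFV/(nRT),

    I(V) = zFA · e^{u/2} · (c_in − c_out·e^{−n u})
           / [ e^{−(n−1)u} + (1/σ_h)·(1 − e^{−(n−2)u})/(e^{u} − 1) + 1/σ_β ]

σ_β is the rate of crossing the innermost barrier relative to the
outermost, σ_h the rate over the internal (middle) barriers relative to the
outermost, and A a proportionality factor carrying the concentration-to-
current scale. σ < 1 raises the corresponding barrier; the conversion to an
activation-energy offset is ΔEa = −RT·ln σ.

The quotient (1 − e^{−(n−2)u})/(e^{u} − 1) has a removable singularity at
u = 0 with limit n − 2; it is evaluated by that limit for |u| < 1e−8 to
avoid catastrophic cancellation, which keeps I continuous through V = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .ivcurve import IVCurve, Normalization
from .thermo import IonSpec, Thermo, nernst_potential_mV

__all__ = [
    "BarrierModelParams",
    "EnergyProfile",
    "barrier_current",
    "barrier_iv_curve",
    "energy_profile_from_params",
    "params_from_energy_profile",
    "rectification_index",
    "model_reversal_potential",
]

#: |u| below which the removable singularity at V = 0 is taken by its limit.
_U_SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class BarrierModelParams:
    """Free parameters of the barrier model.

    Parameters
    ----------
    n_barriers
        Number of barriers n ≥ 2 (a fixed structural choice, default 3).
    sigma_beta
        Relative rate over the innermost barrier (vs the outermost), > 0.
    sigma_h
        Relative rate over the internal barrier(s), > 0.
    amplitude
        Proportionality factor A > 0; multiplies zF, so currents come out
        in A's units per mM of driving concentration.
    """

    n_barriers: int = 3
    sigma_beta: float = 1.0
    sigma_h: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_barriers < 2:
            raise ValueError("n_barriers must be at least 2")
        if not (self.sigma_beta > 0 and self.sigma_h > 0):
            raise ValueError("sigma_beta and sigma_h must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class EnergyProfile:
    """Activation-energy offsets of the inner barriers relative to the outermost.

    ``delta_ea_in_minus_out = −RT·ln σ_β`` and
    ``delta_ea_mid_minus_out = −RT·ln σ_h``, both in kJ/mol: a rate smaller
    than the outermost barrier's (σ < 1) means a higher barrier, i.e. a
    positive energy offset.
    """

    delta_ea_in_minus_out: float
    delta_ea_mid_minus_out: float
    n_barriers: int


def _check_params(params: BarrierModelParams) -> None:
    # dataclass __post_init__ already enforces invariants; re-validate in case
    # of object.__setattr__ tampering or duck-typed inputs
    if params.n_barriers < 2 or params.sigma_beta <= 0 or params.sigma_h <= 0:
        raise ValueError(f"invalid barrier parameters: {params}")


def barrier_current(
    v_mV: Union[float, np.ndarray],
    ion: IonSpec,
    params: BarrierModelParams,
    thermo: Thermo = Thermo(),
) -> Union[float, np.ndarray]:
    """Open-channel current at membrane potential ``v_mV`` (mV).

    Accepts a scalar or array of voltages. The current vanishes exactly at
    the Nernst potential of the permeant ion for every parameter set, and
    the V = 0 point is evaluated by analytic limit.
    """
    _check_params(params)
    v = np.asarray(v_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    scalar = v.ndim == 0
    v = np.atleast_1d(v)

    z = ion.valence
    n = params.n_barriers
    u = z * thermo.faraday * (v * 1e-3) / (n * thermo.rt)

    numerator = ion.conc_in - ion.conc_out * np.exp(-n * u)
    with np.errstate(over="ignore", invalid="ignore"):
        quot = np.where(
            np.abs(u) < _U_SINGULARITY_TOL,
            float(n - 2),
            -np.expm1(-u * (n - 2)) / np.expm1(u),
        )
    denom = np.exp(-u * (n - 1)) + quot / params.sigma_h + 1.0 / params.sigma_beta
    current = (
        z * thermo.faraday * params.amplitude * np.exp(u / 2.0) * numerator / denom
    )
    return float(current[0]) if scalar else current


def barrier_iv_curve(
    voltages_mV: Sequence[float],
    ion: IonSpec,
    params: BarrierModelParams,
    thermo: Thermo = Thermo(),
    normalize: bool = False,
) -> IVCurve:
    """Model I-V curve over ``voltages_mV``.

    With ``normalize`` the currents are divided by the model current at
    +120 mV (evaluated there even if +120 mV is absent from the grid),
    mirroring the convention of normalizing patch data to the response at
    +120 mV.
    """
    voltages = np.asarray(voltages_mV, dtype=float)
    if voltages.size == 0:
        raise ValueError("voltage grid must be nonempty")
    currents = np.asarray(barrier_current(voltages, ion, params, thermo))
    currents = np.atleast_1d(currents)
    if not normalize:
        return IVCurve(voltages, currents, normalization=Normalization.RAW)
    divisor = barrier_current(120.0, ion, params, thermo)
    if divisor == 0:
        raise ZeroDivisionError("degenerate normalization: model current at +120 mV is zero")
    return IVCurve(
        voltages,
        currents / divisor,
        normalization=Normalization.NORMALIZED_TO_PLUS120MV,
    )


def energy_profile_from_params(
    params: BarrierModelParams, thermo: Thermo = Thermo()
) -> EnergyProfile:
    """Convert relative rates to activation-energy offsets, ΔEa = −RT·ln σ (kJ/mol)."""
    _check_params(params)
    rt_kj = thermo.rt * 1e-3
    return EnergyProfile(
        delta_ea_in_minus_out=-rt_kj * float(np.log(params.sigma_beta)),
        delta_ea_mid_minus_out=-rt_kj * float(np.log(params.sigma_h)),
        n_barriers=params.n_barriers,
    )


def params_from_energy_profile(
    profile: EnergyProfile, thermo: Thermo = Thermo(), amplitude: float = 1.0
) -> BarrierModelParams:
    """Inverse of :func:`energy_profile_from_params`: σ = exp(−ΔEa/RT)."""
    rt_kj = thermo.rt * 1e-3
    return BarrierModelParams(
        n_barriers=profile.n_barriers,
        sigma_beta=float(np.exp(-profile.delta_ea_in_minus_out / rt_kj)),
        sigma_h=float(np.exp(-profile.delta_ea_mid_minus_out / rt_kj)),
        amplitude=amplitude,
    )


def rectification_index(
    curve_or_params,
    ion: IonSpec | None = None,
    thermo: Thermo = Thermo(),
) -> float:
    """Rectification index RI = |I(+100 mV)| / |I(−100 mV)|.

    RI > 1 is outward rectification, RI < 1 inward. Accepts either an
    :class:`IVCurve` (interpolating to ±100 mV if necessary) or a
    :class:`BarrierModelParams` together with an :class:`IonSpec`, in which
    case the model is evaluated directly.
    """
    if isinstance(curve_or_params, IVCurve):
        i_pos = curve_or_params.current_at(100.0)
        i_neg = curve_or_params.current_at(-100.0)
    elif isinstance(curve_or_params, BarrierModelParams):
        if ion is None:
            raise ValueError("model-level rectification index requires an IonSpec")
        i_pos = barrier_current(100.0, ion, curve_or_params, thermo)
        i_neg = barrier_current(-100.0, ion, curve_or_params, thermo)
    else:
        raise TypeError(f"unsupported input {type(curve_or_params)!r}")
    if i_neg == 0:
        raise ZeroDivisionError("rectification index undefined: I(−100 mV) = 0")
    return abs(i_pos) / abs(i_neg)


def model_reversal_potential(ion: IonSpec, thermo: Thermo = Thermo()) -> float:
    """Zero-current voltage of the barrier model, in mV.

    Equals the Nernst potential (RT/zF)·ln(c_out/c_in) for every
    (σ_β, σ_h, n, A): the barrier model describes a perfectly selective
    pore, so only the driving-force term in the numerator can vanish.
    """
    return nernst_potential_mV(ion, thermo)
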