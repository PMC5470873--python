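"""Weighted least-squares fitting of the barrier model to normalized I-V data.

The fit works on curves normalized to the +120 mV response, under which the
amplitude A cancels, leaving two free parameters (σ_β, σ_h) with the
barrier count n fixed (default 3). Parameters are searched in log-space —
σ spans decades and the model is smooth in ln σ — from a 3×3 multistart
grid, keeping the best converged solution; the procedure is deterministic
for a given curve. Confidence intervals come from the local quadratic
approximation at the optimum and are descriptive only: barrier models are
a phenomenological account of rectification, not a quantitative energy map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .barrier import (
    BarrierModelParams,
    EnergyProfile,
    barrier_current,
    energy_profile_from_params,
    rectification_index,
)
from .ivcurve import IVCurve, Normalization
from .thermo import IonSpec, Thermo

__all__ = [
    "FitResult",
    "fit_barrier_model",
    "rectification_index_from_data",
    "slope_conductance",
    "concentration_conductance",
]

DEFAULT_SIGMA_BOUNDS = (1e-3, 1e3)
_MULTISTART_SIGMAS = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class FitResult:
    params_hat: BarrierModelParams
    energy_profile: EnergyProfile
    rectification_index: float
    residual_norm: float
    ci_sigma_beta: Tuple[float, float]
    ci_sigma_h: Tuple[float, float]
    converged: bool
    n_barriers_fixed: int
    n_starts_converged: int = 0


def _normalized_model(
    log_sigma: np.ndarray,
    voltages: np.ndarray,
    ion: IonSpec,
    thermo: Thermo,
    n_barriers: int,
) -> np.ndarray:
    params = BarrierModelParams(
        n_barriers=n_barriers,
        sigma_beta=float(np.exp(log_sigma[0])),
        sigma_h=float(np.exp(log_sigma[1])),
    )
    i = np.asarray(barrier_current(voltages, ion, params, thermo))
    i120 = barrier_current(120.0, ion, params, thermo)
    return i / i120


def _weights(curve: IVCurve) -> np.ndarray:
    if curve.sem is None or not np.any(curve.sem > 0):
        return np.ones_like(curve.currents)
    sem = curve.sem.copy()
    # the +120 mV point has sem 0 by construction of the normalization;
    # give zero-sem points the weight of the best-determined real one
    floor = sem[sem > 0].min()
    sem[sem <= 0] = floor
    return 1.0 / sem


def fit_barrier_model(
    curve: IVCurve,
    ion: IonSpec,
    thermo: Thermo = Thermo(),
    n_barriers: int = 3,
    sigma_bounds: Tuple[float, float] = DEFAULT_SIGMA_BOUNDS,
    raw_current_at_120mV_pA: Optional[float] = None,
) -> FitResult:
    """Fit (σ_β, σ_h) to a normalized I-V curve with n barriers fixed.

    Weighted least squares with weights 1/sem² where the curve carries
    uncertainties; the model is self-normalized to its own +120 mV value so
    the amplitude drops out. When ``raw_current_at_120mV_pA`` is supplied
    the amplitude is recovered post hoc from that scale, otherwise it is
    reported as 1.
    """
    if curve.normalization != Normalization.NORMALIZED_TO_PLUS120MV:
        raise ValueError("fit requires a curve normalized to +120 mV")
    if len(curve) < 5 or curve.voltages[0] >= 0 or curve.voltages[-1] <= 0:
        raise ValueError("need ≥ 5 voltage points spanning both polarities")

    w = _weights(curve)
    y = curve.currents

    def residuals(log_sigma: np.ndarray) -> np.ndarray:
        return w * (
            _normalized_model(log_sigma, curve.voltages, ion, thermo, n_barriers) - y
        )

    lo, hi = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    best = None
    n_ok = 0
    for sb0 in _MULTISTART_SIGMAS:
        for sh0 in _MULTISTART_SIGMAS:
            sol = optimize.least_squares(
                residuals,
                x0=np.log([sb0, sh0]),
                bounds=([lo, lo], [hi, hi]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if not sol.success:
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(
            "barrier-model fit failed to converge from every start; "
            "check that the curve is a plausible normalized I-V"
        )

    sigma_beta, sigma_h = np.exp(best.x)
    amplitude = 1.0
    if raw_current_at_120mV_pA is not None:
        unit = barrier_current(
            120.0,
            ion,
            BarrierModelParams(n_barriers, sigma_beta, sigma_h, 1.0),
            thermo,
        )
        amplitude = abs(raw_current_at_120mV_pA / unit)
    params_hat = BarrierModelParams(n_barriers, float(sigma_beta), float(sigma_h), amplitude)

    ci_b, ci_h = _curvature_ci(best, len(y))
    return FitResult(
        params_hat=params_hat,
        energy_profile=energy_profile_from_params(params_hat, thermo),
        rectification_index=rectification_index(params_hat, ion, thermo),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        ci_sigma_beta=ci_b,
        ci_sigma_h=ci_h,
        converged=True,
        n_barriers_fixed=n_barriers,
        n_starts_converged=n_ok,
    )


def _curvature_ci(
    sol: optimize.OptimizeResult, n_points: int, z: float = 1.96
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Descriptive 95% intervals on σ from the Jacobian at the optimum."""
    dof = max(n_points - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(sol.x.size, np.inf)
    intervals = []
    with np.errstate(over="ignore"):
        for x, s in zip(sol.x, se):
            intervals.append((float(np.exp(x - z * s)), float(np.exp(x + z * s))))
    return intervals[0], intervals[1]


def rectification_index_from_data(curve: IVCurve) -> float:
    """RI = |I(+100)| / |I(−100)| read off an aggregated I-V curve."""
    return rectification_index(curve)


def slope_conductance(
    curve: IVCurve, at_voltage_mV: float = -100.0, window_mV: float = 20.0
) -> float:
    """Local slope dI/dV (pA/mV) from a linear fit around ``at_voltage_mV``."""
    sel = np.abs(curve.voltages - at_voltage_mV) <= window_mV
    if sel.sum() < 2:
        raise ValueError(
            f"need at least 2 points within ±{window_mV} mV of {at_voltage_mV} mV"
        )
    slope, _ = np.polyfit(curve.voltages[sel], curve.currents[sel], 1)
    return float(slope)


def concentration_conductance(
    datasets: Mapping[float, IVCurve],
    at_voltage_mV: float = -100.0,
    window_mV: float = 20.0,
) -> Tuple[pd.DataFrame, Optional[Dict[str, float]]]:
    """Slope conductance at −100 mV as a function of intracellular [Cl⁻].

    Returns a table (concentration_mM, conductance_pA_per_mV) and, when at
    least two concentrations are present, a saturating-hyperbola summary
    G = G_max·c/(c + K_half). The barrier model itself is linear in
    concentration, so on model-generated data the relationship stays
    near-linear and the fitted K_half runs to its upper bound — the
    summary is a convenience for real, saturating data.
    """
    if len(datasets) == 0:
        raise ValueError("no concentration datasets supplied")
    rows = [
        {
            "concentration_mM": float(c),
            "conductance_pA_per_mV": slope_conductance(curve, at_voltage_mV, window_mV),
        }
        for c, curve in sorted(datasets.items())
    ]
    table = pd.DataFrame(rows)

    summary: Optional[Dict[str, float]] = None
    if len(table) >= 2:
        c = table["concentration_mM"].to_numpy()
        g = table["conductance_pA_per_mV"].to_numpy()

        def resid(theta: np.ndarray) -> np.ndarray:
            gmax, k = np.exp(theta)
            return gmax * c / (c + k) - g

        k0 = float(np.median(c))
        g0 = float(np.max(np.abs(g))) * 2.0 or 1.0
        sol = optimize.least_squares(
            resid,
            x0=np.log([max(g0, 1e-12), k0]),
            bounds=(np.log([1e-12, 1e-6]), np.log([1e12, 1e6])),
        )
        gmax, khalf = np.exp(sol.x)
        summary = {
            "g_max_pA_per_mV": float(gmax),
            "k_half_mM": float(khalf),
            "saturating": bool(khalf < 10.0 * c.max()),
        }
    return table, summary
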