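"""Steady-state hopping-chain transport model.

Brute-force counterpart of the closed-form barrier model: ions hop over a
chain of ``n`` Eyring barriers with per-barrier rate multipliers γⱼ
(relative to the outermost barrier, whose γ is 1 by convention). Barrier
peaks sit at fractional electrical distance (2j−1)/(2n) from the
intracellular side and wells at j/n, so each half-hop senses 1/(2n) of the
field — the same symmetric-Eyring geometry that gives the closed form its
e^{zFV/2nRT} prefactor. Well depths are equal (no preferred binding site)
and the reservoirs are fixed (no depletion, no multi-ion occupancy).

The n−1 internal well occupancies are obtained by solving the steady-state
linear system directly, which makes this module an independent check on the
closed form and, unlike (σ_β, σ_h), lets the *outermost* barrier be
perturbed on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ivcurve import IVCurve, Normalization
from .thermo import IonSpec, Thermo

__all__ = ["HoppingChain", "chain_from_sigmas", "steady_state_flux", "iv_from_chain"]


@dataclass(frozen=True)
class HoppingChain:
    """A chain of Eyring barriers with per-barrier rate multipliers.

    ``barrier_rate_factors[0]`` is the innermost barrier, the last entry the
    outermost; all must be positive. ``base_rate`` sets an arbitrary
    frequency scale that cancels in normalized curves.
    """

    barrier_rate_factors: tuple
    base_rate: float = 1.0

    def __post_init__(self) -> None:
        factors = tuple(float(g) for g in self.barrier_rate_factors)
        object.__setattr__(self, "barrier_rate_factors", factors)
        if len(factors) < 2:
            raise ValueError("a chain needs at least two barriers")
        if any(g <= 0 for g in factors):
            raise ValueError("all barrier rate factors must be positive")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")

    @property
    def n_barriers(self) -> int:
        return len(self.barrier_rate_factors)

    @property
    def peak_positions(self) -> np.ndarray:
        """Fractional electrical distance of barrier peaks from the inside."""
        n = self.n_barriers
        return (2 * np.arange(1, n + 1) - 1) / (2 * n)

    @property
    def well_positions(self) -> np.ndarray:
        n = self.n_barriers
        return np.arange(1, n) / n


def chain_from_sigmas(
    sigma_beta: float, sigma_h: float, n_barriers: int = 3, base_rate: float = 1.0
) -> HoppingChain:
    """Chain reproducing the closed-form parameterization.

    γ_innermost = σ_β, all internal γ = σ_h, γ_outermost = 1.
    """
    if n_barriers < 2:
        raise ValueError("n_barriers must be at least 2")
    factors = (sigma_beta,) + (sigma_h,) * (n_barriers - 2) + (1.0,)
    return HoppingChain(factors, base_rate)


def steady_state_flux(
    chain: HoppingChain,
    ion: IonSpec,
    v_mV: float,
    thermo: Thermo = Thermo(),
    return_all_fluxes: bool = False,
):
    """Net steady-state flux through the chain, positive outward.

    Hop rates over barrier j are kⱼ± = base_rate·γⱼ·e^{±u/2} with
    u = zFV/(nRT) (+ = outward); the linear balance equations for the
    internal well occupancies are solved exactly. At steady state the flux
    across every barrier is identical; with ``return_all_fluxes`` the full
    per-barrier vector is returned so conservation can be checked.
    """
    n = chain.n_barriers
    u = ion.valence * thermo.faraday * (v_mV * 1e-3) / (n * thermo.rt)
    gam = np.asarray(chain.barrier_rate_factors)
    kp = chain.base_rate * gam * np.exp(u / 2.0)
    km = chain.base_rate * gam * np.exp(-u / 2.0)

    ci, co = ion.conc_in, ion.conc_out
    m = n - 1  # internal wells
    a = np.zeros((m, m))
    b = np.zeros(m)
    for j in range(1, n):  # well j between barriers j and j+1 (1-indexed)
        row = j - 1
        a[row, row] = -km[j - 1] - kp[j]
        if j >= 2:
            a[row, j - 2] += kp[j - 1]
        else:
            b[row] -= kp[0] * ci
        if j <= m - 1:
            a[row, j] += km[j]
        else:
            b[row] -= km[n - 1] * co
    occupancy = np.linalg.solve(a, b)
    p = np.concatenate([[ci], occupancy, [co]])
    fluxes = kp * p[:-1] - km * p[1:]
    if return_all_fluxes:
        return fluxes
    return float(fluxes[0])


def iv_from_chain(
    chain: HoppingChain,
    ion: IonSpec,
    voltages_mV: Sequence[float],
    thermo: Thermo = Thermo(),
    normalize: bool = False,
) -> IVCurve:
    """I-V curve of the chain: current = zF·flux at each voltage."""
    voltages = np.asarray(voltages_mV, dtype=float)
    if voltages.size == 0:
        raise ValueError("voltage grid must be nonempty")
    currents = np.array(
        [
            ion.valence * thermo.faraday * steady_state_flux(chain, ion, v, thermo)
            for v in voltages
        ]
    )
    if not normalize:
        return IVCurve(voltages, currents, normalization=Normalization.RAW)
    divisor = ion.valence * thermo.faraday * steady_state_flux(chain, ion, 120.0, thermo)
    if divisor == 0:
        raise ZeroDivisionError("degenerate normalization: chain current at +120 mV is zero")
    return IVCurve(
        voltages,
        currents / divisor,
        normalization=Normalization.NORMALIZED_TO_PLUS120MV,
    )
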