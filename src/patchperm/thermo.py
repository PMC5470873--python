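"""Thermodynamic constants and ionic conditions.

Voltages are millivolts at every public interface and converted to volts
internally; energies are reported in kJ/mol. The membrane-potential
convention is physiological: v = V_in − V_out, and positive current is
outward movement of positive charge, so Cl⁻ influx registers as a positive
(outward) current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Molar gas constant, J mol^-1 K^-1 (CODATA).
GAS_CONSTANT = 8.314462618

#: Faraday constant, C mol^-1 (CODATA).
FARADAY = 96485.33212


@dataclass(frozen=True)
class Thermo:
    """Temperature and the physical constants entering the permeation model.

    The default 295 K is nominal room temperature; the thermal voltage
    RT/F is then ≈ 25.42 mV.
    """

    temperature: float = 295.0
    gas_constant: float = field(default=GAS_CONSTANT)
    faraday: float = field(default=FARADAY)

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def rt(self) -> float:
        """RT in J/mol."""
        return self.gas_constant * self.temperature

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in millivolts."""
        return self.rt / self.faraday * 1e3


@dataclass(frozen=True)
class IonSpec:
    """A single permeant ion species and its reservoir concentrations.

    Parameters
    ----------
    valence
        Signed charge number z (e.g. −1 for Cl⁻). Must be nonzero.
    conc_in, conc_out
        Intracellular and extracellular concentrations in mM. Both must be
        non-negative and not both zero.
    """

    valence: int
    conc_in: float
    conc_out: float

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be non-negative")
        if self.conc_in == 0 and self.conc_out == 0:
            raise ValueError("at least one reservoir concentration must be positive")


def nernst_potential_mV(ion: IonSpec, thermo: Thermo = Thermo()) -> float:
    """Equilibrium (Nernst) potential (RT/zF)·ln(c_out/c_in), in mV.

    For a perfectly selective pore this is the reversal potential of the
    current, independent of the energy profile.
    """
    if ion.conc_in <= 0 or ion.conc_out <= 0:
        raise ValueError("Nernst potential undefined for zero concentration")
    return thermo.thermal_voltage_mV / ion.valence * np.log(ion.conc_out / ion.conc_in)
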