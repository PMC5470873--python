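"""Recording-solution bookkeeping and Nernst-based anion-selectivity analysis.

Solutions are component maps (salt → mM) mirroring the recording buffers:
the NaCl buffer (150 mM NaCl, 5.99 mM Ca(OH)₂, 5 mM EGTA, 10 mM HEPES,
pH 7.4), the KCl buffer, and the Cl⁻-free (NMDG)₂SO₄ solution used to
dilute intracellular Cl⁻ by mixing at the required ratio. Free Ca²⁺ is
nominal — total calcium minus EGTA — which reproduces the working "1 mM
Ca²⁺" of the buffers above without a multi-equilibrium speciation model.

Selectivity is assessed against the Nernst line: a perfectly Cl⁻-selective
pore reverses at E_Cl = (RT/zF)·ln([Cl]ₒ/[Cl]ᵢ); deviations of the
offset-corrected reversal potential from that line measure apparent
cation permeation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .ivcurve import IVCurve
from .preprocess import QCReport, zero_crossing_mV
from .thermo import IonSpec, Thermo, nernst_potential_mV

__all__ = [
    "SolutionSpec",
    "NACL_BUFFER",
    "KCL_BUFFER",
    "NMDG_SULFATE_SOLUTION",
    "mix_solutions",
    "ReversalEstimate",
    "estimate_reversal",
    "SelectivityResult",
    "selectivity_table",
    "selectivity_from_patches",
    "nernst_slope_mV_per_efold",
]

#: Ions of interest contributed per formula unit of each supported salt.
_SALT_IONS: Dict[str, Dict[str, int]] = {
    "NaCl": {"Cl": 1, "Na": 1},
    "KCl": {"Cl": 1, "K": 1},
    "CaCl2": {"Cl": 2, "Ca": 1},
    "Ca(OH)2": {"Ca": 1},
    "EGTA": {"EGTA": 1},
    "HEPES": {},
    "(NMDG)2SO4": {"NMDG": 2, "SO4": 1},
    "NMDG-Cl": {"Cl": 1, "NMDG": 1},
}


@dataclass(frozen=True)
class SolutionSpec:
    """Ionic composition of a bath or pipette solution (component mM)."""

    components: Mapping[str, float]
    ph: float = 7.4
    name: str = ""

    def __post_init__(self) -> None:
        comp = dict(self.components)
        for salt, mM in comp.items():
            if salt not in _SALT_IONS:
                raise KeyError(f"unknown salt {salt!r}; add it to the salt registry")
            if mM < 0:
                raise ValueError(f"negative concentration for {salt!r}")
        object.__setattr__(self, "components", comp)

    def _ion_total(self, ion: str) -> float:
        return sum(
            _SALT_IONS[salt].get(ion, 0) * mM for salt, mM in self.components.items()
        )

    @property
    def cl_mM(self) -> float:
        return self._ion_total("Cl")

    @property
    def na_mM(self) -> float:
        return self._ion_total("Na")

    @property
    def free_ca_mM(self) -> float:
        """Nominal free Ca²⁺: total calcium minus EGTA, floored at zero."""
        return max(0.0, self._ion_total("Ca") - self.components.get("EGTA", 0.0))


NACL_BUFFER = SolutionSpec(
    {"NaCl": 150.0, "Ca(OH)2": 5.99, "EGTA": 5.0, "HEPES": 10.0}, name="NaCl buffer"
)
KCL_BUFFER = SolutionSpec(
    {"KCl": 150.0, "Ca(OH)2": 5.99, "EGTA": 5.0, "HEPES": 10.0}, name="KCl buffer"
)
NMDG_SULFATE_SOLUTION = SolutionSpec(
    {"(NMDG)2SO4": 100.0, "Ca(OH)2": 5.99, "EGTA": 5.0, "HEPES": 10.0},
    name="(NMDG)2SO4 solution",
)


def mix_solutions(a: SolutionSpec, b: SolutionSpec, ratio_of_a: float) -> SolutionSpec:
    """Componentwise linear mixture ``ratio·a + (1−ratio)·b``."""
    if not 0.0 <= ratio_of_a <= 1.0:
        raise ValueError("mixing ratio must lie in [0, 1]")
    if abs(a.ph - b.ph) > 0.2:
        raise ValueError("solutions buffered at incompatible pH")
    salts = set(a.components) | set(b.components)
    comp = {
        s: ratio_of_a * a.components.get(s, 0.0)
        + (1.0 - ratio_of_a) * b.components.get(s, 0.0)
        for s in salts
    }
    return SolutionSpec(comp, ph=a.ph, name=f"{ratio_of_a:g}×{a.name or 'A'} mix")


@dataclass
class ReversalEstimate:
    """A reversal potential and whether the patch offset was subtracted."""

    erev_mV: float
    offset_corrected: bool = False
    offset_mV: float = 0.0


def estimate_reversal(
    curve: IVCurve, qc: Optional[QCReport] = None
) -> ReversalEstimate:
    """Reversal potential by linear interpolation of the zero crossing.

    When a :class:`QCReport` from the same patch's symmetric recording is
    given, its voltage offset is subtracted (the standard per-patch
    correction); correcting an already-corrected estimate is an error, so
    correction state is tracked on the result.
    """
    erev = zero_crossing_mV(curve)
    if qc is None:
        return ReversalEstimate(erev)
    return apply_offset_correction(ReversalEstimate(erev), qc)


def apply_offset_correction(est: ReversalEstimate, qc: QCReport) -> ReversalEstimate:
    if est.offset_corrected:
        raise ValueError("voltage offset already subtracted from this estimate")
    return ReversalEstimate(
        erev_mV=est.erev_mV - qc.voltage_offset_mV,
        offset_corrected=True,
        offset_mV=qc.voltage_offset_mV,
    )


@dataclass
class SelectivityResult:
    """Measured vs Nernst reversal potentials across intracellular [Cl⁻]."""

    construct: str
    table: pd.DataFrame  # cl_in_mM, erev_mV, corrected_erev_mV, nernst_mV, deviation_mV
    max_abs_deviation_mV: float


def selectivity_table(
    datasets: Mapping[float, Tuple[IVCurve, Optional[QCReport]]],
    cl_out_mM: float,
    construct: str = "WT",
    thermo: Thermo = Thermo(),
    n_patches: Optional[Mapping[float, int]] = None,
) -> SelectivityResult:
    """Assemble the reversal-vs-Nernst comparison for one construct.

    ``datasets`` maps intracellular [Cl⁻] (mM) to an aggregated I-V curve
    and, optionally, the QC report carrying the patch (or averaged) voltage
    offset. Small deviations across all conditions support strong anion
    over cation selectivity.
    """
    if len(datasets) < 2:
        raise ValueError("selectivity analysis needs at least 2 Cl⁻ concentrations")
    rows: List[dict] = []
    for cl_in, (curve, qc) in sorted(datasets.items()):
        est = estimate_reversal(curve, qc)
        nernst = nernst_potential_mV(
            IonSpec(valence=-1, conc_in=cl_in, conc_out=cl_out_mM), thermo
        )
        rows.append(
            {
                "construct": construct,
                "cl_in_mM": float(cl_in),
                "erev_mV": est.erev_mV if not est.offset_corrected else est.erev_mV + est.offset_mV,
                "corrected_erev_mV": est.erev_mV,
                "nernst_mV": nernst,
                "deviation_mV": est.erev_mV - nernst,
                "n_patches": (n_patches or {}).get(cl_in, curve.n_patches),
            }
        )
    table = pd.DataFrame(rows)
    return SelectivityResult(
        construct=construct,
        table=table,
        max_abs_deviation_mV=float(table["deviation_mV"].abs().max()),
    )


def selectivity_from_patches(
    per_condition_erev: Mapping[float, Tuple[List[float], List[float]]],
    cl_out_mM: float,
    construct: str = "WT",
    thermo: Thermo = Thermo(),
) -> SelectivityResult:
    """Selectivity table from per-patch reversal potentials.

    The preferred correction route: each patch's voltage offset (measured in
    its own symmetric recording) is subtracted from that patch's reversal
    potential before averaging, so true offsets cancel patch by patch.
    ``per_condition_erev`` maps [Cl⁻]ᵢ (mM) to (uncorrected per-patch E_rev
    list, per-patch offset list). The averaged-offset route
    (:func:`selectivity_table`) remains for constructs without per-patch
    symmetric data.
    """
    if len(per_condition_erev) < 2:
        raise ValueError("selectivity analysis needs at least 2 Cl⁻ concentrations")
    rows: List[dict] = []
    for cl_in, (erevs, offsets) in sorted(per_condition_erev.items()):
        if len(erevs) != len(offsets) or len(erevs) == 0:
            raise ValueError("need matching, nonempty E_rev and offset lists")
        corrected = [e - o for e, o in zip(erevs, offsets)]
        nernst = nernst_potential_mV(
            IonSpec(valence=-1, conc_in=cl_in, conc_out=cl_out_mM), thermo
        )
        rows.append(
            {
                "construct": construct,
                "cl_in_mM": float(cl_in),
                "erev_mV": float(np.mean(erevs)),
                "corrected_erev_mV": float(np.mean(corrected)),
                "nernst_mV": nernst,
                "deviation_mV": float(np.mean(corrected)) - nernst,
                "n_patches": len(erevs),
            }
        )
    table = pd.DataFrame(rows)
    return SelectivityResult(
        construct=construct,
        table=table,
        max_abs_deviation_mV=float(table["deviation_mV"].abs().max()),
    )


def nernst_slope_mV_per_efold(
    result: SelectivityResult, cl_out_mM: float
) -> float:
    """Slope of corrected E_rev against ln([Cl]ₒ/[Cl]ᵢ), mV per e-fold.

    For a Cl⁻-selective pore this recovers RT/zF (≈ −25.42 mV at 295 K
    with z = −1).
    """
    t = result.table
    if len(t) < 2:
        raise ValueError("need at least 2 conditions for a slope")
    x = np.log(cl_out_mM / t["cl_in_mM"].to_numpy())
    y = t["corrected_erev_mV"].to_numpy()
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
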