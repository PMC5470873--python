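"""The current-voltage curve container exchanged between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np


class Normalization(str, Enum):
    RAW = "raw"
    NORMALIZED_TO_PLUS120MV = "normalized_to_plus120mV"


@dataclass
class IVCurve:
    """A set of (voltage, current) points with optional uncertainty.

    Voltages are mV, strictly increasing. Currents are pA when raw, or
    dimensionless when normalized to the response at +120 mV, in which case
    the +120 mV point equals 1 within numerical tolerance.
    """

    voltages: np.ndarray
    currents: np.ndarray
    sem: Optional[np.ndarray] = None
    normalization: Normalization = Normalization.RAW
    n_patches: Optional[int] = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.ndim != 1 or self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must be 1-D arrays of equal length")
        if self.voltages.size == 0:
            raise ValueError("IVCurve must contain at least one point")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing with no duplicates")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.currents.shape:
                raise ValueError("sem must match currents in shape")
        if self.normalization == Normalization.NORMALIZED_TO_PLUS120MV:
            i120 = self.current_at(120.0)
            if not np.isclose(i120, 1.0, atol=1e-6):
                raise ValueError(
                    f"normalized curve must equal 1 at +120 mV, got {i120!r}"
                )

    def current_at(self, v_mV: float) -> float:
        """Current at ``v_mV``, by exact match or linear interpolation.

        Raises ``ValueError`` if ``v_mV`` lies outside the measured range.
        """
        idx = np.nonzero(np.isclose(self.voltages, v_mV, atol=1e-9))[0]
        if idx.size:
            return float(self.currents[idx[0]])
        if v_mV < self.voltages[0] or v_mV > self.voltages[-1]:
            raise ValueError(f"{v_mV} mV outside measured range")
        return float(np.interp(v_mV, self.voltages, self.currents))

    def __len__(self) -> int:
        return int(self.voltages.size)
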