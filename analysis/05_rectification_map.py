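#!/usr/bin/env python
"""Map barrier position to rectification, and conductance to concentration.

Uses the hopping-chain model (which, unlike the closed form's (σβ, σh)
parameterization, can perturb any single barrier) to tabulate the
rectification index as each of the three barriers is raised over three
decades, and computes the slope conductance at −100 mV as a function of
symmetric Cl⁻ concentration — linear by construction, since the barrier
model carries no saturating binding site.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from patchperm import (
    BarrierModelParams,
    HoppingChain,
    IonSpec,
    barrier_iv_curve,
    iv_from_chain,
    rectification_index,
)
from patchperm.fitting import concentration_conductance

OUT = Path("results")
OUT.mkdir(exist_ok=True)
grid = np.arange(-120.0, 121.0, 20.0)
sym = IonSpec(-1, 150.0, 150.0)

rows = []
for barrier, position in (("innermost", 0), ("central", 1), ("outermost", 2)):
    for raise_factor in 10.0 ** np.linspace(0.0, 3.0, 7):
        gammas = [1.0, 1.0, 1.0]
        gammas[position] = 1.0 / raise_factor  # slower rate = higher barrier
        curve = iv_from_chain(HoppingChain(tuple(gammas)), sym, grid)
        rows.append(
            {
                "barrier_raised": barrier,
                "raise_factor": raise_factor,
                "rectification_index": rectification_index(curve),
            }
        )
map_table = pd.DataFrame(rows)
map_table.to_csv(OUT / "rectification_map.csv", index=False, float_format="%.6g")
print(map_table.pivot(index="raise_factor", columns="barrier_raised",
                      values="rectification_index").to_string(float_format="%.3f"))

datasets = {
    c: barrier_iv_curve(grid, IonSpec(-1, c, c), BarrierModelParams(amplitude=1e-5))
    for c in (15.0, 37.5, 75.0, 150.0, 300.0)
}
cc_table, summary = concentration_conductance(datasets)
cc_table.to_csv(OUT / "concentration_conductance.csv", index=False, float_format="%.6g")
print("\nslope conductance at −100 mV vs [Cl⁻] (arbitrary amplitude):")
print(cc_table.to_string(index=False))
print(f"hyperbola summary: {summary} (non-saturating: conductance ∝ concentration)")
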