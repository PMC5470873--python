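# patchperm

Quantitative analysis of ion-channel current–voltage (I-V) relations from
inside-out patch-clamp recordings, built around an n-barrier Eyring
permeation model. The package was written for the kind of experiment used
to characterize pore mutants of the Ca²⁺-activated Cl⁻ channel TMEM16A:
instantaneous currents measured in a voltage-step protocol at saturating
intracellular Ca²⁺, corrected for channel rundown, background-subtracted,
normalized, fitted to a barrier model to localize which energy barrier a
mutation raises, and checked for anion selectivity against the Nernst line.
It is aimed at channel biophysicists who want a tested, reproducible
version of this analysis, with a synthetic-data generator that provides
ground truth for every stage.

## The model

Permeation is described as thermally activated hopping over `n` energy
barriers in series, each spanning an equal fraction of the transmembrane
electric field, with barrier peaks midway between wells (symmetric Eyring
barriers). With `u = zFV/(nRT)`, the open-channel current is

    I(V) = zFA · e^{u/2} · (cᵢ − c₀·e^{−nu})
           ─────────────────────────────────────────────────────
           e^{−(n−1)u} + (1/σ_h)·(1 − e^{−(n−2)u})/(e^{u} − 1) + 1/σ_β

where `cᵢ, c₀` are the intracellular and extracellular concentrations of
the permeant ion (valence `z`), `A` a proportionality factor, and `σ_β`,
`σ_h` the rates over the innermost and middle barrier(s) relative to the
outermost. `σ < 1` means a higher barrier; the descriptive energy profile
is `ΔEa = −RT·ln σ` (kJ/mol). Three structural facts follow and are
enforced by tests:

* equal barriers (`σ_β = σ_h = 1`) and symmetric concentrations collapse
  the model to `I = 2zFAc·sinh(zFV/2nRT)` — a near-linear I-V over
  physiological voltages;
* the current reverses exactly at the Nernst potential
  `(RT/zF)·ln(c₀/cᵢ)` for every parameter set (the model is perfectly
  selective);
* raising the *intracellular* barrier (σ_β < 1) produces outward
  rectification, raising the *extracellular* barrier inward
  rectification, and raising the *central* barrier an S-shaped deviation
  from linearity in both directions at rectification index ≈ 1.

An independent steady-state hopping-chain solver (`patchperm.hopping`)
solves the master equation for the well occupancies numerically; it agrees
with the closed form to ~1e−12 and also allows perturbing the outermost
barrier, which the (σ_β, σ_h) parameterization cannot express.

## Worked example

`analysis/` contains the study as numbered drivers over the library; each
writes its tables under `results/pipeline/`. Steps 01–02 simulate and
reduce 12 synthetic patches per construct (symmetric 150 mM Cl⁻, 2% noise,
rundown τ = 20 sweeps, ±3 mV offsets against the <2 mV QC filter). Step 03
fits the three-barrier model per construct and prints:

```
construct                     σβ      σh  ΔEa(in-out)  ΔEa(mid-out)     RI
WT                         0.988   1.030      0.03 kJ      -0.07 kJ   1.01
inner-barrier-mutant       0.151   0.952      4.64 kJ       0.12 kJ   3.96
outer-barrier-mutant       4.748   5.518     -3.82 kJ      -4.19 kJ   0.31
central-barrier-mutant     1.043   0.196     -0.10 kJ       4.00 kJ   0.98
```

The ground truths were σβ = 0.15 (inner mutant), σβ = σh = 5 (outer) and
σh = 0.2 (central): the fit recovers each within the precision the noise
allows, and the rectification indices reproduce the barrier-position map —
outward (RI ≈ 4.0) for a raised intracellular barrier, inward (RI ≈ 0.31)
for a raised extracellular one, RI ≈ 1 for a central one. Step 04 runs the
selectivity series (intracellular Cl⁻ diluted 150 → 15 mM):

```
Nernst slope -25.62 mV/e-fold (ideal -25.42); max |E_rev − E_Cl| = 0.42 mV
```

i.e. the offset-corrected reversal potentials track the Cl⁻ Nernst line
within half a millivolt, the signature of a strictly anion-selective pore.
Step 05 tabulates the rectification map over three decades of barrier
height and the (linear) concentration–conductance relation.

The same pipeline is scriptable via the `patchperm` CLI
(`simulate | preprocess | fit | selectivity | all`, with `--config`,
`--outdir`, `--seed`).

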