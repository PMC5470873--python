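# Methods

## Permeation model

The core model treats the open pore as a sequence of `n` Eyring barriers.
Assumptions: a single permeant species; one ion in the pore at a time (no
saturation — current is strictly linear in concentration); equal well
depths (no dominant binding site, consistent with the low effective
affinity of Cl⁻ conduction in the channels this analysis targets); each
hop spans an electrical distance `1/n` with the barrier peak midway, so a
hop's forward/backward rates carry the symmetric factors `e^{±zFV/2nRT}`.
Under these assumptions the steady-state current has the closed form given
in the README, with three shape parameters: the barrier count `n` and the
relative rates `σ_β` (innermost vs outermost barrier) and `σ_h` (middle
barrier(s) vs outermost). Energy offsets are reported as
`ΔEa = −RT·ln σ`, i.e. relative to the outermost barrier; absolute barrier
heights are not identifiable from I-V shape and are not reported.

The typeset form of such equations is easy to mis-group, so the
implementation was accepted only after two independent checks, both kept
as permanent tests: (i) with `σ_β = σ_h = 1` and symmetric concentrations
it reduces algebraically to `2zFAc·sinh(zFV/2nRT)` (the denominator
telescopes into a geometric sum); (ii) it agrees pointwise, up to one
voltage-independent constant, with a brute-force steady-state solution of
the hopping master equation (`patchperm.hopping`), which solves the
`n−1` well occupancies by linear algebra with per-barrier rate multipliers
`γⱼ`. The mapping `γ = (σ_β, σ_h, …, σ_h, 1)` reproduces the closed form;
arbitrary `γ` vectors extend it, in particular to perturbations of the
outermost barrier.

A consequence worth stating because it is often paraphrased loosely: a
raised *central* barrier does not flatten the I-V. Once the flanking wells
equilibrate with the reservoirs, the middle barrier effectively senses the
whole field and the current grows as `sinh(zFV/2RT)` — steeper than the
equal-barrier curve. The phenotype is therefore a symmetric, S-shaped
deviation from linearity (rectification index ≈ 1); in +120 mV-normalized
coordinates the midrange values fall below the straight line through the
origin, which is how such curves look "suppressed" in normalized plots.
The tests assert this superlinear form.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 295 | K | room-temperature recording; RT/F ≈ 25.42 mV; configurable |
| n (barriers) | 3 | — | fixed structural choice, not fitted; a sensitivity refit at n ∈ {3,4,5} is available |
| σ_β, σ_h bounds | 10⁻³…10³ | — | three decades either side; fits are done in ln σ because σ spans decades and the model is smooth there |
| z | −1 | — | Cl⁻; the voltage convention is v = V_in − V_out with positive current outward, so Cl⁻ influx at depolarized potentials is a positive current |
| voltage grid | −100…+120, 20 mV steps | mV | includes +120 (normalization) and ±100 (rectification index) |

Voltages are mV at every interface (converted to volts internally);
energies kJ/mol; currents pA in the synthetic data.

## Fitting

Curves are normalized to the +120 mV response, under which the amplitude
`A` cancels; the fit searches (ln σ_β, ln σ_h) with `n` fixed, by weighted
least squares (weights 1/sem² where the aggregated curve carries
uncertainties; the +120 mV point, whose sem is 0 by construction, gets the
weight of the best-determined other point). A 3×3 multistart grid over
σ ∈ {0.1, 1, 10}² guards against local minima; the best converged start
wins, deterministically. Confidence intervals come from the local
quadratic approximation at the optimum and are descriptive only — barrier
models of this kind are a phenomenological account of I-V shape, not a
quantitative energy landscape, and the package treats them that way.
`A` is recovered after the fact from the raw +120 mV current when the
caller supplies it.

## Synthetic recordings

The generator emulates inside-out patches under a step protocol (holding
5 ms → +80 mV pre-pulse 15 ms → test step 15 ms; −100…+120 mV in 20 mV
increments, one sweep per voltage in ascending order; 20 kHz sampling,
5 kHz filter as metadata). Channel currents are instantaneous — recordings
at saturating Ca²⁺ are modeled as free of gating relaxation, which is the
regime the instantaneous-current protocol isolates; a mono-exponential
relaxation hook exists for robustness tests but defaults off. On top of
the model current it layers, each with known ground truth:

* **rundown** — availability `a_s = e^{−s/τ}` per sweep (default τ = 20
  sweeps), applied identically at pre-pulse and test step; this identity
  is what makes pre-pulse-based correction exact, and it is the premise
  of the correction rather than an approximation to it;
* **ohmic leak** `g·(v − offset) + b` (default 0.05 pA/mV), present in
  Ca²⁺-free background sweeps too;
* **voltage offset** per patch, uniform ±3 mV by default — channel and
  leak both see `v_cmd − offset`, so the zero crossing measured in
  symmetric solutions equals the injected offset, and the default range
  gives the <2 mV acceptance filter a 2/3 expected pass rate;
* **amplitude variability** — lognormal with unit mean, CV 0.3 (typical
  patch-to-patch spread of expression and patch area);
* **Gaussian sample noise** (default 2 pA; the replication studies use
  2% of the +120 mV current, i.e. 10 pA at the 500 pA default scale);
* **dead time** 0.5 ms after each step, flagged unusable, standing in for
  capacitive transients without simulating RC physics.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: single-channel gating noise, series
resistance and imperfect space clamp, liquid-junction potentials,
Ca²⁺-dependent gating kinetics, cation permeation (the synthetic channel
is perfectly anion-selective), and saturation of conduction at high Cl⁻
(the model is linear in concentration by construction, so the
concentration–conductance table is linear and the optional
saturating-hyperbola summary reports a diverging half-saturation value on
synthetic data).

## Preprocessing rules

Instantaneous currents are the mean over a 0.5–2.0 ms window after each
jump (configurable; must start after the dead time). Corrections apply in
a fixed order, tracked by state flags: background subtraction (paired
Ca²⁺-free recording) → rundown correction (divide each test current by
that sweep's pre-pulse fraction relative to the first sweep; the first
sweep is the reference because availability is maximal there) →
normalization to +120 mV. Skipping the rundown correction makes a linear
pore look inward-rectifying, because later sweeps in the ascending
protocol have lost more current — the regression suite pins this
artifact. The voltage offset is the linearly interpolated zero crossing of
a symmetric-condition I-V; patches at |offset| ≥ 2 mV are rejected.
Reported patch counts are counts of *accepted* patches, so replication
studies simulate until the target number passes QC.

Reversal potentials under asymmetric conditions are zero crossings by
linear interpolation between the bracketing grid points (a monotone
fit-free rule, matching how offsets are read); curves with no crossing or
more than one are flagged rather than guessed. Offset correction is
per-patch wherever per-patch symmetric data exist — each patch's offset
subtracted from its own reversal, so true offsets cancel exactly — with
the averaged-offset fallback retained for constructs where low current or
fast rundown precludes per-patch controls. Solution bookkeeping is
nominal: free Ca²⁺ = total Ca − EGTA (reproducing the ~1 mM working
concentration of the standard buffers) rather than a full speciation
calculation, and Nernst potentials use concentrations, not activities.

## Numerical choices

* The closed form's removable singularity at V = 0: the quotient
  `(1 − e^{−(n−2)u})/(e^u − 1)` is replaced by its limit `n − 2` for
  |u| < 10⁻⁸, and both exponential differences use `expm1` to avoid
  cancellation. Continuity is tested by the symmetric midpoint
  `(I(+ε)+I(−ε))/2` against the limit branch, because with asymmetric
  concentrations the physical slope dI/dV contributes a genuine O(ε)
  one-sided difference that is not numerical error.
* The hopping chain solves a dense (n−1)×(n−1) linear system per voltage;
  flux conservation across barriers (relative spread ≤ 1e−10) is the
  internal consistency check.
* Rundown correction refuses a reference pre-pulse below 1% of the
  largest pre-pulse magnitude; normalization refuses a +120 mV response
  below 1e−12 of scale.
* All stochastic stages derive their generators from a master seed and
  the patch index, so datasets are reproducible and growing a patch pool
  never changes earlier patches.

## Problem sizes

Replication studies use 12 accepted patches per construct, 20 seeded
replicates per ground truth, and 1000 patches for the QC pass-rate Monte
Carlo; the selectivity series uses 12 patches at each of four
intracellular Cl⁻ concentrations (150, 75, 37.5, 15 mM against 150 mM
outside). These sizes match the replication level of the experimental
design the generator emulates, and every headline number in
`scripts/acceptance.py` is recomputed at these sizes at run time.

## Known limitations

Only energy *offsets* relative to the outermost barrier are identifiable;
σ_h is weakly determined when σ_β is far from 1 (the large inner barrier
dominates the shape), which the descriptive confidence intervals make
visible. The model cannot express multi-ion effects, anomalous mole
fraction behavior, or conduction saturation. The fitted parameters are a
phenomenological summary of I-V shape: agreement with the model does not
establish the physical reality of discrete barriers.
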