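# Methods

## Model

Every cell carries the same gene regulatory network, written as ordinary
differential equations over compartmental species (nucleus, cytoplasm,
membrane; concentrations in arbitrary units `au`, first-order rates in
`min⁻¹`). The negative-feedback core is Hes7: nuclear mRNA is
transcribed at rate `k · rep(pN; H_R, h_R) · act(pN_NICD; H_A, h_A)`,
exported to the cytoplasm (`emN`), translated (`K`), and the protein is
imported into the nucleus (`epC`) where it represses its own promoter
and decays saturably at `G·pN/(F+pN)`. The transport chain provides the
feedback delay; no delay arguments are used. Dll1 has the same
mRNA/protein transport structure with its protein delivered to the
membrane; its promoter is repressed by HES7, which makes the ligand
oscillate. Notch1 is constitutive (single mRNA pool). The promoter
logic for Hes7 is multiplicative (AND): nuclear NICD is an obligatory
activator, reflecting that Hes7 stops oscillating without Notch input.

Cell coupling is the trans-activation reaction

```
flux_i = rDN · pM_Notch1(i) · mean_{j∈nb(i)} pM_Dll1(j) · M(i),
M = r0 + raLfng · act(pC_Lfng; 1.0, 2)
```

added to cytoplasmic NICD of the receiver `i`, and subtracted both from
the receiver's membrane NOTCH1 and from the sender-side membrane DLL1
(computed symmetrically as `rDN · pM_Dll1(i) · mean_j pM_Notch1(j) · M`).
Averaging over the neighbor list keeps parameters independent of lattice
dimensionality. Without the Lfng gene the LFNG pool is identically
zero, so the trans-reaction runs at the unaided weight `M = r0 = 0.256`;
with Lfng enabled, saturation raises it to `r0 + 1`, an unaided:promoted
ratio of roughly 1:4.

Cis-inhibition is mass action between DLL1 and NOTCH1 of the *same*
cell, applied independently in the cytoplasm and the membrane with a
single rate constant `rDNcis` (default 0.01 au⁻¹min⁻¹); both molecules
are removed (immediate decay of the complex). This is the mechanism
under study: the titration leaves each cell with an excess of either
ligand or receptor, breaking the sender/receiver symmetry.

## Design decisions on under-determined pieces

The original equation set for this network is not reproducible from the
available description alone; four choices were genuinely open and are
fixed here as follows.

* **NICD transport orientation.** The printed constants assign
  `epC = 0.12` and `epN = 0.6` to the two nucleus↔cytoplasm transport
  directions ambiguously, while the accompanying text requires nuclear
  import to exceed export. With import = 0.12 the nucleus starves of
  NICD and the whole network sits at a fixed point; with import = 0.6
  (`nicd_transport="swapped"`, the default) the network oscillates at
  2.3 h. The literal orientation remains available as a config switch.
* **Trans-reaction weight without Lfng.** Applying `M = 1` in the base
  network saturates the NICD activation Hill (nuclear NICD 7–19 au
  against `H_A = 4.5`), and no lattice synchronizes at any cis rate.
  Applying `M = r0 = 0.256` always (the Lfng term simply vanishing
  without the gene) puts nuclear NICD astride the threshold and
  reproduces the two-cell anti→in-phase transition at
  `rDNcis = 0.010` and the reported cube behavior.
* **NICD cooperativity `h_A`.** The promoter is bound by a dimer of
  NICD complexes plus co-factors, i.e. cooperativity of at least 2 and
  plausibly higher. Measured on this implementation: with `h_A = 2`
  the in-phase state of any multicellular lattice is linearly unstable
  at every cis rate (pairs synchronize, lattices never do), whereas
  `h_A = 4` — the smallest integer we found to work — yields fast,
  complete lattice synchronization. Default `h_A = 4`. The trade-off
  is quantitative: with `h_A = 2` the two-cell oscillation-death
  boundary falls at `rDNcis ≈ 0.014–0.015` (the originally reported
  location) but the lattice result is lost; with `h_A = 4` the lattice
  results hold and the two-cell death boundary moves to 0.030. We
  ship the lattice-functional value and report the measured boundary.
* **Neighborhood.** `build_tissue` defaults to the von Neumann
  neighborhood (interior counts 2/4/6 in 1/2/3 dimensions); simulation
  configs default to the extended neighborhood (diagonals signal too),
  which is required for the cube synchronization onset at
  `rDNcis = 0.0115` and is the mode used for the growing-PSM runs.

## Synthetic initial conditions and noise

The canonical initial state is a point on the synchronized limit cycle:
a noise-free two-cell system is integrated for 3000 min and snapshot at
a cytoplasmic Hes7 mRNA peak; the constants are frozen in
`grn_model.CANONICAL_INITIAL_STATE` and re-derivable with
`compute_canonical_initial_state` (a test compares them). Initial noise
of `p` percent multiplies every concentration of every cell by
`1 + (p/100)·u`, `u ~ U(0,1)` i.i.d. — 200% noise maps `c` into
`[c, 3c]`. Two properties of this generator matter for interpreting
results: it only scales concentrations *upward*, and from an on-cycle
state it scatters amplitudes much more than phases (the phase order
parameter starts near 0.9 even at 100% noise and the disorder develops
over the first oscillations through amplitude–phase shear). It does not
emulate ongoing molecular noise, cell movements, or mitosis elsewhere
than in the PSM growth zone, so passing tests demonstrate deterministic
re-entrainment from scattered states, not robustness to continuous
stochasticity.

## Growing PSM

The PSM is a conveyor slab with a fixed 7×3 cross-section and posterior
growth: every `cell_cycle_min` (default 30 min, the reported early-embryo
cell-cycle scale) the posterior-most row divides as a group, daughters
inherit the mother's concentrations exactly, and the slab elongates by
one row (capped at `max_length`). Each dividing cell optionally shuts
its transcription gate (Hes7, Dll1, Notch1, Lfng — not the gradient
fields) for `mitosis_shutdown_min` (default 20 min when enabled), with a
uniform per-cell jitter (default ≤ 5 min) so divisions are synchronous
but not simultaneous; alternatively division noise re-scatters daughter
concentrations. The FGF8 gradient is a parametric exponential,
`factor(d) = 1 + A·exp(−d/λ)` with `A = 0.5`, `λ = 5` cell widths and
`d` the distance from the posterior end, multiplying the cytoplasmic
HES7 decay rate: posterior cells cycle faster, anterior ones slow down,
which is what makes expression waves travel and was verified as the
anterior-period ≥ posterior-period property. The gradient-generating
genes themselves (Fgf8/Wnt3a/Tbx6 dynamics) are replaced by this static
advected profile; boundary genes downstream of the clock are out of
scope.

## Numerics

Time integration is synchronous explicit Euler with `dt = 0.1 min`;
neighbor fields are computed from the pre-step state, so results do not
depend on cell ordering. Updates are clamped at zero; the clamp rate is
recorded on every trace and a rate above 0.1% triggers a warning to
reduce `dt` (all shipped fixtures stay below 10⁻⁶). Against an adaptive
LSODA reference at rtol 10⁻⁹ the two-cell full-state trajectory differs
by 0.8% relative L2 over 500 min, and halving `dt` halves the change
(first-order convergence), so the fixed-step scheme is adequate at the
default step. The stiffest term is the saturated nuclear decay near
`pN → 0` (effective rate `G/F ≈ 4.8 min⁻¹`), which bounds usable `dt`.

Randomness flows from one root seed through independent child streams
for initial noise and growth scheduling, so enabling growth does not
change the noise draws; traces embed seed and config and are bit-exactly
reproducible.

## Metrics and classification

`C(t)` is the unnormalized covariance form
`mean_i (c_i − c̄)(⟨c_j⟩_{nb(i)} − c̄)` over cytoplasmic Hes7 mRNA
(zero at uniformity without 0/0 issues; a variance-normalized variant is
available for cross-size comparison). `R` is a reconstruction of a
Kuramoto order parameter: per-cell phases grow linearly by 2π between
successive peaks of that cell's series (extrapolated beyond the first
and last peak with the cell's mean period), and `R(t)` is the modulus of
the mean unit phasor; cells without two peaks are excluded and flagged.
Periods are mean peak-to-peak intervals after burn-in; a series is
damped when its successive cycle amplitudes decay persistently
(last 4 ratios < 0.98) or the oscillation has died (late cycle amplitude
below 2% of the cycle maximum, or fewer than two peaks).

Outcome labels: a trace is **damped** when the cell-averaged temporal
standard deviation in the last 20% of the run falls below 10% of its
early value (the cells oscillated, then died — including decay into a
static salt-and-pepper pattern); otherwise **anti_synchronized** when
the late-window mean of C is below −ε; otherwise **synchronized** when
the late-window R stays above ρ = 0.9 and |C| < ε; otherwise **waves**
(persistent oscillation in domains of different phase). ε is 1% of the
temporal variance of the late mean field, floored at 10⁻¹². Time to
synchronization is the first time R exceeds 0.9 and stays above it to
the end of the run.

## Problem sizes

Unit and property tests use two-cell systems and lattices up to 3×3×3;
the lattice experiments use the 7×7×7 cube at 50 000 × 0.1 min steps
(the reported horizon), and the robustness partition uses a 5×5×5 cube
at 20 000 steps — legitimate because synchronization behavior was shown
to be volume-independent across cube edges 5–14. The acceptance script
runs the two-cell sweep (grid step 0.001, 5000 min per point), the cube
time-to-sync grid over three seeds, 40 perturbed parameter sets, and the
period measurement; together a few minutes on one CPU.

## Known limitations

* The ODE forms are a reconstruction from a textual description; the
  per-term structure is tested against its own contract and an SBML
  round-trip, but not against the original code. The main measurable
  divergence is that no single parameter reading reproduces *both* the
  two-cell oscillation-death boundary at 0.014 and lattice
  synchronization; see the design-decision section.
* On the cube, time-to-sync decreases monotonically across the tested
  sync window (0.0115–0.02) — this reconstruction shows no cube-level
  damping immediately above the synchronization onset, so the "optimal"
  cis rate sits at the top of any tested grid rather than at 0.0115.
* With the ±10% parameter perturbations the default oscillator is far
  from its Hopf boundary: damped outcomes are rare (≈1/40), unlike the
  reported 16/40, again a consequence of the `h_A = 4` regime.
* Initial noise scatters amplitudes, not phases (see above); stochastic
  kinetics, cell movement and the somite boundary gene cascade are out
  of scope.
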