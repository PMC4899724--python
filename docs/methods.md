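# Methods

## Three-state gating model

The macroscopic current model is a linear three-state chain

```
        alpha           kappa
   C  --------->  O  --------->  I
   C  <---------  O  <---------  I
         beta           lambda
```

with activation rates α, β in ms⁻¹ and inactivation rates κ, λ in s⁻¹.
The master equation `dP/dt = A·P` is solved exactly: the 3×3 generator for
the step voltage is exponentiated once per sample interval
(`scipy.linalg.expm`) and the propagator applied recursively, which is
exact for uniform sampling and any rate magnitudes.  The initial
distribution is the stationary (null-space) distribution of the
holding-voltage generator, so a sweep begins from the true resting
occupancies.  Probabilities are renormalized per step to absorb round-off;
conservation holds to 1 × 10⁻⁹ or better over a 10-s sweep.

No two-state approximation is used in the simulator.  The closed forms
`τ = 1/(κ+λ)` and `SS/I_max = λ/(κ+λ)` hold in the α ≫ β limit and serve
as the independent oracle in the tests.  With the default activation
parameters (below), α/β ≈ 200 at +80 mV; the resulting open probability of
≈ 0.995 biases recovered rates by under 1% — within every tolerance used.
The round-trip property test uses a steeper fast gate (α/β ≈ 4 × 10⁴ at
+80 mV) because the decomposition's own assumption is the strict α ≫ β
limit.

### Voltage dependence of the fast gate

Only the α ≫ β condition at the analysis voltage matters to the slow-rate
analysis, so the fast gate is parameterized generically as
`α(V) = α₀·exp(V/s_a)`, `β(V) = β₀·exp(−V/s_b)` with defaults
α₀ = β₀ = 0.3 ms⁻¹ and s_a = s_b = 30 mV.  These defaults open the channel
within ~10 ms at +80 mV and keep it essentially closed at the −80 mV
holding potential.  They are interface defaults, not fitted quantities.

### Decay fitting

`fit_inactivation` fits `I(t) = (I_max − SS)·exp(−t/τ) + SS` by bounded
least squares (`scipy.optimize.curve_fit`, SS ≥ 0, τ > 0), with time
re-zeroed at the fit start.  The fit start defaults to the time of the
current maximum, following the convention that I_max is the current at the
start of the fit, close to the peak.  Degenerate windows are flagged
rather than silently reported: a fitted τ beyond 100× the window length
(constant `LOW_CONFIDENCE_TAU_FACTOR`), a vanishing decay amplitude
(|I_max − SS| < 10⁻⁶·I_max), or an optimizer failure all set
`low_confidence`.

Amplitude-corrected comparisons fit each trace against its own fitted
peak, so steady-state fractions are per-trace normalized and kinetic
comparisons are independent of interventions that scale the current; the
peak ratio is reported alongside.  This per-trace normalization is this
package's documented choice for handling amplitude changes between
control and treated sweeps.

The κ/λ quotient ratio is computed purely from steady-state fractions,
`[(1−SS_a)/SS_a]/[(1−SS_b)/SS_b]`, which equals the ratio of κ/λ
quotients with τ cancelled — so it is insensitive to any τ mis-estimation
shared between the two fits.  Uncertainty propagation for the quotient,
when SEMs are available, is by the delta method.

## Concerted-action classification

The multiplicative (energy-additive) prediction `τ_AB = τ_A·τ_B/τ_wt` and
the independent prediction `min(τ_A, τ_B)` are compared with the observed
double-mutant τ in log₁₀ space.  The verdict is the nearer prediction when
the margin between the two log-distances exceeds a band (default 0.15
log₁₀ units ≈ 1.4-fold); otherwise indeterminate.  Observations *faster*
than the multiplicative prediction always classify as concerted:
super-multiplicative acceleration is stronger, not weaker, evidence of a
shared cooperative transition.  The band is a reproducibility device — the
underlying distinction is qualitative — and is configurable.

## Gating-charge analysis

- **Boltzmann parameterization**: `A/(1 + exp((V_½ − V)/s))` with s > 0
  for curves rising with depolarization.  The sign convention is this
  package's; midpoint-based quantities are independent of it.
- **Leak subtraction** (performed offline): `linear_baseline` fits a line
  in time to pre-pulse samples and subtracts its extrapolation (offsets,
  slow drift); `subthreshold_scaling` scales a companion subthreshold
  sweep by the pointwise command-voltage ratio, removing an ohmic leak
  exactly.  The integral of the correction over the ON pulse is reported.
- **Charge integration**: trapezoidal rule from an exclusion window
  (default 1.5 ms, configurable) after pulse onset to pulse end, with the
  window edges interpolated onto the sample grid.  µA × ms integrates
  directly to nC.  Against closed-form exponential test currents the
  integral is accurate to well under 0.5% at 0.05-ms sampling.
- **Q(V)**: integrated ON charges per voltage, divided by the maximum and
  scaled to 100%.  Normalization is idempotent and scale-invariant.
- **Shared-slope fits**: the two Q(V) curves from different holding
  voltages are fit in a single joint least-squares problem (lmfit) with
  one common slope — not sequentially.
- **Constrained two-component refit**:
  `A·[f₂·B(V; V_fix, s) + (1−f₂)·B(V; V_1, s)]` with f₂ ∈ [0, 1] and one
  shared slope; f₂ pinned at a bound raises a boundary warning because the
  complementary midpoint is then unidentifiable.
- **Q(V) shift**: `V_½(holding 0) − V_½(holding −80)`; the corrected shift
  replaces the raw reference midpoint with the refit first-component
  midpoint when part of the charge has already moved at the reference
  holding voltage.
- **Decay constants**: the gating-current magnitude is fit to
  `A·exp(−t/τ) + C` starting where |I| has fallen halfway from its peak
  toward the tail level — past the slowly rising phase, where the decay is
  genuinely exponential.

## Filter geometry

Internal unit is nm; multi-model PDB I/O (biotite) converts from/to Å.
Opposing-chain pairing is fixed as (A,C)/(B,D) by convention and
configurable for other chain naming.  Residue numbers are Shaker
numbering throughout (F416, W434, V443–G446, K456, E418).

- **Pull coordinate**: center-of-mass distance between residue 416 of
  opposing subunits, mass-weighted.  The harmonic restraint
  `F = k·(ref(t) − d)` with `ref(t) = ref₀ + rate·t` uses
  k = 2000 kJ/mol/nm² and rate = 0.002 nm/ns as reference values (0.1 nm
  displacement → 200 kJ/mol/nm); because the coordinate is a pair
  distance, each residue drifts outward at half the reference rate.
- **Superposition**: unweighted least-squares rigid-body alignment
  (Kabsch SVD with reflection correction) over the N, CA, C, O backbone
  atoms of residues 441–446 in all four chains.  The test suite checks it
  against an independent quaternion-eigenvector implementation.
- **Filter diameter**: mean of the two opposing carbonyl-O center-to-center
  distances per position.  Center-to-center is the documented reading of
  "distance between carbonyls"; van der Waals radii are not added.  The
  Cα series uses the same convention on CA atoms.
- **Collapse detection**: baseline = median of the first `window` frames;
  the event frame is the first whose |diameter − baseline| exceeds the
  threshold (default 0.05 nm) for at least `window` (default 10)
  consecutive frames.  A programmed step at frame k is therefore reported
  as exactly k.  The defaults are documented choices; the original
  identification of such events is by inspection.
- **Ion occupancy**: ions are counted inside a cylinder built per frame
  from the filter carbonyl rings (axis through their mean xy; default
  radius 0.4 nm; z-range spanning the 443–446 rings ± 0.1 nm).  Departure
  is the first frame where the count drops below its initial value for a
  persistence window (default 5 frames).
- **Control statistic**: mean absolute displacement of opposing-carbonyl
  distances from the reference frame across frames × positions 443–445,
  with its standard error.

## Synthetic data

The generators emulate the structure of the study's recordings, not their
biological variability:

- **Current families**: exact three-state sweeps (10-s steps, −40…+80 mV
  from −80 mV holding by default) plus additive Gaussian noise scaled to
  the peak.  They do not emulate series-resistance error, endogenous
  currents, or rundown.
- **Gating currents**: shape `(1 − e^{−t/τ_rise})·e^{−t/τ_decay}` with
  τ_rise = 0.3 ms default (a rising phase is present in recordings but has
  no published parameter), normalized so the noise-free ON integral equals
  the prescribed Boltzmann charge; the OFF phase returns the same charge
  with its own τ.  Optional sub-1.5-ms capacitive spikes and ohmic leak.
- **Q(V) datasets**: one or two Boltzmann components with a shared slope,
  normalized to percent.
- **Filter trajectories**: an idealized fourfold-symmetric filter —
  carbonyl rings of radius 0.25 nm for positions 441–446 stacked 0.3 nm
  apart, backbone N/CA/C atoms on slightly larger rings, two axial K⁺
  ions, a bulk Na⁺, and residue-416 sites at 1.2 nm radius — with
  programmable widening schedules, an abrupt collapse step, ion exit,
  outward 416 drift and Gaussian jitter.  These are cartoon geometries
  chosen for plausibility: passing tests demonstrate that the *metrics and
  detectors* recover programmed events, not that real filters have these
  dimensions.

Every generator takes an explicit seed (no global RNG state), is
bit-reproducible, and records its ground truth in a sidecar for
self-contained recovery tests.

## Problem sizes

The test suite and the acceptance script run at desk scale: 10-s current
sweeps at 10-ms sampling (1001 samples), gating sweeps at 0.05-ms
sampling, 26-point Q(V) curves, and trajectories of 40–260 frames with
~100 atoms.  These sizes resolve every fitted quantity to well inside the
tolerances asserted; the full-atom, 300-ns steered MD the trajectory
metrics were designed around is explicitly not reproduced here.

## Known limitations

- N-type (fast) inactivation, single-channel stochastics, and
  recovery-from-inactivation two-pulse protocols are out of scope.
- λ is inferred from the steady state of the O ⇌ I equilibrium, not from
  recovery kinetics; it is only meaningful where the open probability is
  high.
- The Q(V) analysis has no capacitance model beyond the exclusion window,
  and no junction-potential correction; voltages are absolute membrane
  potentials.
- Geometry analyses assume one atom per (chain, residue, atom-name) for
  the selections used; altloc handling is not implemented.
- The ion-occupancy cylinder is axis-aligned in z after alignment; heavily
  tilted pores would need a principal-axis generalization.
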