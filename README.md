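# kvgating

Quantitative analysis of slow (C-type) inactivation in voltage-gated K⁺
channels, built for electrophysiologists and simulators working on the
Shaker channel and its relatives.  C-type inactivation is the
seconds-timescale shutdown of conduction caused by a rearrangement of the
selectivity filter during prolonged depolarization; this package implements
the full analysis chain used to study how the voltage-sensor domain (VSD)
and the pore communicate during that process:

- **Gating kinetics** — the three-state scheme C ⇌ O ⇌ I with fast
  activation rates α, β (ms⁻¹) and slow inactivation rates κ (O→I) and
  λ (I→O) (s⁻¹).  When α ≫ β the open-current decay is
  `I(t) = (I_max − SS)·exp(−t/τ) + SS` with `τ = 1/(κ+λ)` and
  `SS/I_max = λ/(κ+λ)`, so κ and λ follow from a single exponential fit.
  Effects of mutations, drugs and metal-ion bridges are expressed as
  τ fold-changes, percent changes, and κ/λ quotient ratios.
- **Concerted action** — double-mutant analysis: if two residues act in
  concert their fold effects multiply (`τ_AB = τ_A·τ_B/τ_wt`); if they act
  independently the faster single mutant dominates (`τ_AB = min(τ_A, τ_B)`).
  Observed double mutants are classified by log-distance to each prediction.
- **Conductance and gating charge** — chord conductance
  `G_K(V) = I_K/(V − V_rev)`, offline leak subtraction, gating-current
  integration (capacitive exclusion window), normalized Q(V) curves,
  single and shared-slope Boltzmann fits `A/(1+exp((V_½−V)/s))`, the
  constrained two-component refit, and the holding-voltage-dependent Q(V)
  shift with its correction.
- **Filter geometry** — steered-pull coordinate (opposing-subunit
  center-of-mass distance with a harmonic moving-reference restraint) and
  trajectory metrics on multi-model PDBs: carbonyl-ring filter diameters,
  Cα distances, rigid-body superposition (Kabsch) on the filter backbone,
  collapse detection, ion occupancy, and control displacement statistics.
- **Synthetic data** — seeded generators for every input (current
  families, gating currents, Q(V) datasets, filter trajectories) with
  ground-truth sidecars, so the whole pipeline is testable without any
  recordings.

## Worked example

```python
from kvgating import (KineticRates, simulate_three_state, fit_inactivation,
                      rates_from_fit, fold_change, voltage_dependent_activation,
                      MutantTau, classify)

alpha, beta = voltage_dependent_activation()
wt  = KineticRates(alpha, beta, kappa=0.145833, lambda_=0.0625)
mut = KineticRates(alpha, beta, kappa=0.766667, lambda_=0.066667)

for label, rates in [("wt", wt), ("F416D", mut)]:
    trace = simulate_three_state(rates, step_voltage=80.0, duration=10.0, dt=0.01)
    fit = fit_inactivation(trace)
    r = rates_from_fit(fit)
    print(f"{label:6s} tau = {fit.tau:.2f} s  SS = {100*fit.ss_frac:.0f}%  "
          f"kappa = {r.kappa:.3f} /s  lambda = {r.lambda_:.4f} /s")

print(f"fold acceleration: {fold_change(4.80, 1.20).value:.1f}")

verdict = classify(MutantTau("wt", 4.8), MutantTau("T449A", 4.8/13),
                   MutantTau("K456M", 4.8/20), MutantTau("T449A/K456M", 4.8/1600))
print(f"concerted prediction: {verdict.tau_concert_pred*1e3:.1f} ms, "
      f"independent: {verdict.tau_independent_pred*1e3:.0f} ms, "
      f"observed: {verdict.observed_tau*1e3:.0f} ms -> {verdict.classification}")
```

prints

```
wt     tau = 4.82 s  SS = 30%  kappa = 0.144 /s  lambda = 0.0633 /s
F416D  tau = 1.21 s  SS = 9%  kappa = 0.759 /s  lambda = 0.0709 /s
fold acceleration: 4.0
concerted prediction: 18.5 ms, independent: 240 ms, observed: 3 ms -> concerted
```

The wild-type channel inactivates with τ ≈ 4.8 s to a 30% residual
current; the F416D pore mutant inactivates four times faster to an ~8%
residual, and the decomposition attributes that mostly to a larger κ
(faster entry into the inactivated state).  The T449A/K456M double mutant
inactivates far faster than even the multiplicative prediction of its two
single mutants — the signature of the two residues acting on one concerted
transition rather than independently.

## Command line

The same pipeline is scriptable via config-driven subcommands
(`simulate`, `fit-inactivation`, `rates`, `concert`, `gv`, `gating`,
`qv-shift`, `filter`, `report`), each writing a manifest with the config
hash and seeds for reproducibility:

```sh
kvgating simulate -c sim.yaml -o run/
kvgating fit-inactivation -o run/ -s trace_dir=run
kvgating rates -o run/
kvgating report -o run/
```

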