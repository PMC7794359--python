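# slipfret

Simulation and inference for single-molecule FRET (smFRET) studies of
slipped-strand DNA three-way junctions (3WJs) — the branched structures
formed when a tract of CAG or CTG trinucleotide repeats extrudes from a
duplex as an intrastrand hairpin ("slip-out"). Such structures are central
intermediates in trinucleotide repeat-expansion diseases, and their dynamics
are observed one molecule at a time either as camera-binned donor/acceptor
intensity traces of immobilized molecules (TIRF) or as photon bursts of
freely diffusing molecules under pulsed excitation (multiparameter
fluorescence detection, MFD).

The package is aimed at single-molecule biophysicists who want to (a) model
3WJ dynamics as an explicit kinetic scheme, (b) generate realistic synthetic
data for both assays, and (c) run the complete inference chain used on real
data — hidden Markov idealization, transition density plots, dwell-time rate
fitting, burst selection, and FRET-histogram mixture fitting — with known
ground truth to validate every step.

## Model

A construct is described by the number of slip-out repeats *n* and the
number of complementary repeat triplets *m* in the flanking duplex. The
slip-out can sit at *m* + 1 registers, the **positional isomers**
P1…P(*m*+1); each isomer additionally exchanges between two branchpoint
**conformers**. Dynamics are a continuous-time Markov chain over
(isomer, conformer) states with generator **Q**:

* conformational exchange within each isomer at rates
  (k_lh, k_hl) — e.g. (12.25, 3.38) s⁻¹ for a static CTG₁₀ construct;
* branch migration between adjacent isomers (optional longer-range jumps
  and conformational gating of migration);
* a per-state mean FRET efficiency E ∈ [0, 1]. For the canonical mobile
  construct (*m* = 3, two conformers) the eight states carry six unique E
  values: the last isomer's pair is unresolved and overlaps one P3 state.

Observables follow the field's standard relations: the proximity ratio
E = S_R/(S_G + S_R); the quenched donor lifetime τ_D(A) = τ_D(0)(1 − E),
so static populations fall on the FRET line E = 1 − τ_D(A)/τ_D(0); dwell
times in a state with exit rate k are Exponential(k); a chain sampled at
frame interval Δt has per-frame transition matrix P = exp(QΔt).

## Worked example

Recover the conformational exchange rates of a static CTG construct from
synthetic TIRF data (60 traces × 60 s at 50 ms exposure, 10% Gaussian
channel noise), and count FRET states from an MFD burst measurement of the
mobile construct:

```python
from slipfret.pipelines import recover_static_rates, mobile_scheme, run_mfd_pipeline

r = recover_static_rates(12.25, 3.38, n_traces=60, duration=60.0, seed=0)
print(f"low->high: {r['k_low_to_high']:.2f} +/- {r['se_low_to_high']:.2f} s^-1 "
      f"(truth {r['true_k_low_to_high']})")
print(f"high->low: {r['k_high_to_low']:.2f} +/- {r['se_high_to_low']:.2f} s^-1 "
      f"(truth {r['true_k_high_to_low']})")

ana = run_mfd_pipeline(mobile_scheme(), n_molecules=2000, donor_only_fraction=0.2, seed=0)
print(f"{len(ana.accepted)} bursts -> {ana.best_n_fret} FRET components, "
      f"means {ana.best_fit.fret_means.round(2).tolist()}")
```

```
low->high: 12.33 +/- 0.15 s^-1 (truth 12.25)
high->low: 3.43 +/- 0.04 s^-1 (truth 3.38)
1479 bursts -> 6 FRET components, means [0.15, 0.3, 0.46, 0.6, 0.75, 0.9]
```

The recovered rate pair matches the generative truth to ~1%, and mixture
model selection on the burst FRET histogram resolves exactly the six unique
efficiencies of the eight-state scheme, with the donor-only population
appearing as the constrained zero-FRET component.

## Layout

* `src/slipfret/` — the library: `junction`/`scheme`/`ctmc` (constructs,
  kinetic schemes, exact Gillespie simulation), `tirf_sim`/`mfd_sim`
  (synthetic traces and photon records), `hmm` (Baum–Welch/Viterbi
  idealization, including a motional-blur-aware variant), `kinetics`
  (transitions, TDPs, dwell/rate fitting), `bursts`/`mixture` (burst
  search, per-burst observables, constrained Gaussian mixtures),
  `pipelines`, `config`, `plots`, `cli`.
* `analysis/01…05_*.py` — numbered drivers that run the two pipelines end
  to end and write tables/figures under `results/`.
* `slipfret` console script — `simulate-tirf`, `analyze-tirf`,
  `simulate-mfd`, `analyze-mfd` subcommands over YAML scheme configs, each
  writing a JSON run manifest with all seeds.
* `docs/methods.md` — model, estimator, and design notes.

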