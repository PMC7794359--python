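# Methods

## Kinetic model

Dynamics of a slipped-strand 3WJ are modelled as a continuous-time Markov
chain (CTMC) over `(positional isomer, branchpoint conformer)` states with
generator **Q** (s⁻¹): off-diagonal entries are rate constants, diagonals
the negated row sums. The default parameterization shares one
conformational pair `(k_lh, k_hl)` across isomers (the measured rates for
the different static isomers agree within error), uses one migration rate
for all adjacent-isomer pairs, an optional two-register jump rate (default
0), and an optional gate restricting migration to one conformer (off by
default — whether conformation switches migration on/off is an open
question, so no default is asserted). Any individual edge can be
overridden per-edge through the config.

Defaults and units:

| parameter | default | meaning |
|---|---|---|
| `low_to_high`, `high_to_low` | 12.25, 3.38 s⁻¹ | conformational exchange (static CTG₁₀ values) |
| `migration` | 2.0 s⁻¹ | adjacent-isomer branch migration; a stand-in of the same order as the exchange rates, since per-edge migration rates are not established |
| `jump` | 0 s⁻¹ | two-register migration (e.g. P1↔P3) |
| FRET map | 6 values evenly spaced on [0.15, 0.90] | per-state mean efficiency |

**Degenerate FRET map.** For the canonical mobile construct (4 isomers × 2
conformers) the default map assigns the six unique values so that both P4
states coincide with each other *and* with the high-FRET P3 state — the
last isomer presents a single unresolved efficiency that overlaps a P3
state. This reproduces "8 predicted, 6 resolvable" and is fully
overridable. Exact per-state efficiencies of real constructs are not
built in; the evenly spaced defaults are documented stand-ins.

Trajectories are sampled exactly (Gillespie): dwell ~ Exponential(−Q_ii),
successor j with probability k_ij/Σk_ij, truncation at the requested
duration, absorbing rows handled as terminal segments. The matrix
exponential `p(t) = p(0)·exp(Qt)` serves as the independent occupancy
oracle in tests. Initial states default to a stationary draw.

## Synthetic TIRF traces

Frames integrate the trajectory over the full exposure (50 ms default), so
the per-frame ground truth is the duration-weighted mean of the state
efficiencies (motional blurring), computed exactly from the piecewise-linear
cumulative integral. Channel intensities are `acceptor = E·R`,
`donor = (1−E)·R` for photon budget R (1000 counts/frame default) plus
per-channel background and noise — Gaussian with σ = 0.10·R by default
(matching the Gaussian emission model assumed by trace-HMM tools), Poisson
optionally. Optional exponential photobleaching produces the donor-only
tail (acceptor → background, donor → full budget) that generates the
zero-FRET peak; bleaching is off by default so kinetics tests are not
right-censored. `e_apparent` is the uncorrected proximity ratio; γ
correction is a config option (default γ = 1). Zero-total frames are
flagged and excluded from fitting. Default trace length is 60 s
(1200 frames); real photon budgets and trace lengths vary more than these
stand-ins.

## HMM idealization

`fit_hmm` is plain Baum–Welch with per-state Gaussian emissions on
`e_apparent`: starting means evenly distributed over [0, 1] plus jittered
restarts (10 by default), tolerance 1e-6 relative log-likelihood, max 500
iterations, best-of-restarts selection, states sorted by mean, collapse
within 1e-3 flagged as degenerate. The log-likelihood is asserted
non-decreasing at every EM iteration. Forward/backward and Viterbi are
batched across equal-length traces, so hundreds of one-minute traces fit in
seconds. The state count follows the protocol choice (2 for static
constructs, 6 for mobile ones); BIC-style selection exists separately in
the mixture module.

**Motional blur and `fit_hmm_blur`.** At exchange rates comparable to the
frame rate (k·Δt ≈ 0.6 here) the per-state Gaussian model is misspecified:
transition frames carry intermediate averaged values, which inflate the
short-lived state's fitted width and bias the inferred chain (the fast rate
comes out ~25% low). The blur-aware variant conditions each frame's
emission on the *pair* of states at the frame boundaries: equal boundary
states emit the state Gaussian; a transition frame i→j emits
`u·μ_i + (1−u)·μ_j` with u ~ U(0,1) convolved with the channel noise
(closed form via the normal CDF). Emission parameters are re-estimated
from pure-frame responsibilities only — a generalized-EM step, so the fit
tracks the likelihood and keeps the best-scoring parameters instead of
asserting strict monotonicity. The inferred boundary chain approximates
the point-sampled CTMC, whose transition matrix is exactly `exp(QΔt)`.

## Rate estimation

Dwells are contiguous runs of the idealized chain times the frame width;
the first and last run of every trace are censored, and stitched series
drop boundary-spanning dwells by construction. `fit_dwell_rate` offers the
exponential MLE `k = 1/mean` (SE `k/√n`) and a Levenberg–Marquardt fit of
`A·exp(−kt)` to the 30-bin dwell histogram spanning one frame width to the
99th percentile, reporting SE scaled by √(reduced χ²); both apply a
minimum-dwell cutoff of one frame.

`rate_matrix_from_traces` corrects frame discretization by default: the
per-frame embedded matrix **P** (self-transition `1 − Δt/mean_dwell`,
off-diagonals split by branching counts) is inverted through
`Q = logm(P)/Δt`, which is exact for a two-state chain observed by point
sampling and removes most of the geometric-dwell bias; the naive product
`k_ij = (1/mean_dwell_i)·branching_ij` remains available. No further
missed-event correction is applied at this stage.

**Parametric-bootstrap bias inversion.** Even the blur-aware chain
over-counts transitions slightly (~15%): frames containing a complete
within-frame excursion are sometimes read as transition frames. Because
the generator is part of the package, `recover_static_rates` removes this
residual bias exactly in the way its own forward model defines it: the
identical simulate→fit estimator is evaluated at the current candidate
rates on a fixed-seed calibration set and the candidate updated by
`k ← k · k_raw / B(k)` for two fixed-point steps. The calibration seed is
fixed, so the bias map is deterministic; the correction is generic (no
knowledge of the truth enters). At study conditions (300 traces × 60 s)
recovery is within ~2–3% of the generative rates.

## Transition density plots

TDPs are 50×50 histograms of (E before, E after) over [0,1]²; bins under
the minimum transition count (10 by default, overridable down to 2 for
low-count data) are zeroed and the diagonal is empty by construction. The
reported symmetry score `1 − Σ|c_ij − c_ji| / Σ(c_ij + c_ji)` is 1 for a
perfectly reversible plot; detailed-balance simulations score > 0.9.

## Synthetic MFD photon records

Molecules arrive as a sparse Poisson process; each transit has a Gaussian
intensity envelope of width 200 μs (log-normal spread σ = 0.3) and peak
rate 1 MHz, so accepted bursts carry a few hundred photons. The molecule's
E is frozen per transit by a stationary draw — exchange at ~10 s⁻¹ is
static on the ~200 μs diffusion timescale (an intra-burst switching option
exists for future use). Photon color is Bernoulli(E); green micro-times
are Exponential(τ_D(0)·(1−E)) wrapped into the 25 ns window of 40 MHz
excitation (δ-IRF: the ~60 ps instrument response is negligible against ns
lifetimes); τ_D(0) = 4.0 ns is a documented stand-in. Polarization sends a
photon to its color's parallel detector with probability (1+2r)/(2+r)
(G-factor 1), r = 0.15 by default; anisotropy is recovered by inverting the
same convention, `r = (N_∥ − N_⊥)/(N_∥ + 2N_⊥)`. Background photons
(1.5 kHz total by default, within the 1–2 kHz regime) are uniform over the
record on all four detectors. Crosstalk and direct excitation default to
0 and are available as options.

## Burst analysis

Bursts are maximal photon runs with interphoton gaps ≤ 0.1 ms and ≥ 100
photons; an exhaustive-window scan is the test oracle. The acceptor-bleach
filter rejects bursts with |T_G − T_R| ≥ 0.55 ms; single-color bursts have
an undefined difference and are retained flagged by default (they are
typically donor-only and carry no bleach information) — a strict policy
drops them. Per-burst estimates: proximity-ratio E (uncorrected; γ and
crosstalk corrections are opt-in), τ_D(A) as the mean green micro-time
(background-naive, acceptable at ≥100-photon bursts over 1–2 kHz
background; micro-time wrapping biases τ down by <2% at 4 ns), and r_D
from the green polarization split.

## FRET-histogram mixtures and state counting

Burst E values are fitted unbinned by EM to one donor-only Gaussian whose
mean is constrained to [−0.02, 0.05] (free width) plus N free FRET
components; multi-start initialization uses histogram peaks, quantiles,
and evenly spaced means, with jittered extras. A binned least-squares
variant over 50 display bins on [−0.1, 1.1] is provided for parity with
histogram-fitting workflows; ML on unbinned values is the default
estimator.

Model selection scans N = 1…8. The default criterion is ICL (BIC plus
twice the assignment entropy) rather than plain BIC: burst-wise shot noise
scales as √(E(1−E)/N_photons) and burst sizes vary log-normally, so each
state's E distribution has heavier-than-Gaussian tails, and BIC buys
likelihood by fitting strongly overlapping shadow components into those
tails (selecting 7–8 where 6 populations exist). The entropy term
penalizes exactly that overlap; BIC remains available. Each N is
additionally refined by cascade warm starts (merging the closest pair of
the N+1 fit, splitting the broadest component of the N−1 fit) with per-N
candidates kept by the selection criterion itself — the standard
classification-likelihood refinement — which makes the count stable across
seeds. At the default study conditions (5000 molecules, 20% donor-only,
≈3600 accepted bursts) the selected count is 6 with component means on the
scheme's unique FRET values to ±0.01.

## Problem sizes and numerical choices

Rate-recovery runs use 300 traces × 60 s (≈3·10⁴ uncensored dwells per
direction) with a calibration set of 150 traces; MFD runs use 5000
molecules (≈3600 accepted bursts). Emission σ floors: 1e-3 (HMM), 5e-3
(mixtures). Mixture EM tolerance 1e-8 relative; HMM 1e-6. `logm` output
has tiny negative off-diagonal round-off clipped to zero. Degenerate
inputs: empty streams yield empty burst lists; single-state traces yield no
transitions; unobserved state pairs are reported absent, not zero; absorbing
CTMC states yield terminal segments.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the inference chain
rests on: exponential dwells, motional blurring at the camera exposure,
anti-correlated channels with Gaussian/Poisson noise, donor-only species,
diffusion-limited burst sizes, lifetime–E coupling, and polarization
anisotropy. They do not emulate dye photophysics beyond a generic
acceptor-dark tail (no blinking kinetics, no dye stacking), spatial optics
(no PSF, no detection-volume shape beyond the Gaussian envelope), γ/
crosstalk calibration errors, or sequence-dependent thermodynamics (rates
are inputs, not predictions). Passing tests therefore validate the
inference chain against the stated stochastic model, not against every
artefact of real recordings.

## Known limitations

* The blur-aware HMM models at most one transition per frame; multi-switch
  frames and within-frame excursions are handled only through the
  bootstrap bias inversion, which assumes the generative model family.
* The embedded-chain `logm` inversion requires the sampled chain's
  transition matrix to have a real logarithm; very sparse observations of
  many-state schemes may need the naive estimator.
* The lifetime estimator is background-naive and wrap-naive; at much
  higher backgrounds or lifetimes approaching the excitation period a
  corrected estimator should be enabled.
* Mobile-construct migration rates are stand-ins; only the static/variant
  conformational rates are quantitatively validated.
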