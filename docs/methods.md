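# Methods

`photonhmm` analyzes diffusion-based single-molecule FRET measurements at the
single-photon level.  A double-labeled molecule diffusing through a confocal
spot emits a ~1 ms burst of photons; if the molecule interconverts between
conformations on the tens-of-microseconds scale, individual bursts carry the
kinetic signature in the ordering of their donor/acceptor photon colors even
though per-burst averages wash it out.  The package covers the whole chain:
synthetic data generation with known ground truth, burst processing,
photon-by-photon hidden-Markov inference, model validation, and derived
equilibrium/energetic observables.

## The model

Each selected burst is treated as an independent realization of a hidden
Markov chain λ = (Π, A, B).  The hidden state is the conformational state of
the molecule; the observation alphabet is the photon color (donor = 0,
acceptor = 1).  Row i of the observation matrix B is
(1 − E_i, E_i), so each state's acceptor-emission probability *is* its
apparent FRET efficiency.  Π is the state distribution at a burst's first
photon; bursts are independent chains restarted from Π (molecules are
uncorrelated between transits).

Two propagation conventions are supported:

* **Photon-indexed** (default): one application of A between consecutive
  photons.  This is the classical discrete-chain reading of the observation
  sequence and is the default for free n-state fits.  Per-photon transition
  probabilities are converted to rates by a_ij / ⟨Δt⟩, with ⟨Δt⟩ the mean
  within-burst inter-photon interval — a reporting convention, documented as
  such.  For exponential gaps at rate λ_ph the *identifiable* per-photon
  transition matrix is E[e^{QΔt}] = λ_ph (λ_ph I − Q)^{-1}, which for the
  two-state benchmark (k = 2×10⁴ s⁻¹, λ_ph = 2×10⁵ s⁻¹) is ≈17 % below
  k·⟨Δt⟩; recovered probabilities track the former.
* **Elementary-time-step** (`TopologyConstraint.time_step`): the chain is
  propagated on a fixed time grid (silent, non-emitting steps inserted
  between photons), so state changes can occur *between* photons.  This is a
  coarse quantization of the tick-resolved formulation.  It is essential for
  the sequential-grid fit below: in photon-indexed mode every well-to-well
  crossing of the grid is forced to emit ≥2 photons from intermediate grid
  states, which at ~10 photons per dwell floods the middle of the profile
  and (verified at full convergence) erases the two wells.  With silent
  steps the crossings carry no photon occupancy and the wells reappear at
  the true state positions.  Likelihood evaluation and Viterbi decoding also
  accept a fully tick-resolved flag (per-gap propagator A^Δk); EM
  re-estimation is implemented for the photon-indexed and silent-step modes.

## Fitting

Baum–Welch (EM) with per-step rescaling of the forward/backward variables;
log-likelihood is exactly monotone by construction and asserted in the test
suite.  Multiple random restarts guard against local optima: Π uniform,
A diagonally dominant with off-diagonal mass log-uniform in [10⁻³, 0.3], and
B rows drawn uniform in [0.05, 0.95] and sorted.  Convergence is declared
when the total log-likelihood gain drops below `tol_per_photon` × (number of
photons); the default 10⁻⁶/photon is adequate for exploratory fits, while
parameter-recovery experiments in the tests use 10⁻⁸/photon because on 10⁶
photon datasets the looser setting stops while transition probabilities are
still drifting by several percent.  States are always reported sorted by
ascending FRET efficiency, which resolves the label-swap degeneracy; a state
whose posterior photon occupancy vanishes triggers a degenerate-fit warning
and is pruned.

Fit variants:

* **Free n-state** — all parameters open.
* **Sequential grid** — emissions frozen on 9–10 equally spaced FRET values
  in [0.05, 0.98]; transitions restricted to nearest grid neighbours
  (tridiagonal; zero entries are fixed points of EM and stay exactly zero).
  The occupancy profile p(E) is Boltzmann-inverted into a 1D free-energy
  profile V(E) = −ln p(E) in k_BT.
* **Global two-dataset** — Π and A free and independent per condition, B
  updated from the pooled emission statistics, so both conditions share one
  set of state FRET efficiencies (the M-step pooled update equals the
  occupancy-weighted average of the per-dataset updates; asserted
  numerically).

## Burst processing

Bursts are maximal runs of photons whose consecutive inter-photon gaps are
all below 5 µs, keeping runs of ≥30 photons (comparisons are exact in
integer clock ticks).  Raw E uses donor-excitation photons only; raw
stoichiometry S is the donor-excitation fraction of all photons.  Leakage l
is calibrated from donor-only bursts (S_raw > 0.9) as ⟨E⟩/(1 − ⟨E⟩), direct
excitation d from acceptor-only bursts (S_raw < 0.2) as ⟨S⟩/(1 − ⟨S⟩) —
the standard alternating-laser estimators.  Corrected acceptor counts
F = n_A|Dex − l·n_D|Dex − d·n_A|Aex; γ defaults to 1.  Double-label
selection keeps bursts with corrected S in [0.3, 0.8] (configurable; the
window is a declared convention).  Burst variance analysis splits each
burst into 5-photon windows and compares the spread of window acceptor
fractions with the binomial shot-noise expectation.

## Validation procedures

* **Recoloring**: photon times fixed, colors redrawn from the fitted model;
  per-burst E histograms compared by a two-sample Kolmogorov–Smirnov test
  (the match criterion; a fitted model passing at the 1 % level is
  indistinguishable from the data-generating coloring).
* **Segmentation histograms**: Viterbi segments of ≥5 photons are
  histogrammed by assigned state (40 bins on [0, 1]); the crossing of the
  two normalized histograms between their modes (linear interpolation, with
  empty-gap midpoint fallback) defines the split point for the HMM-free
  population-ratio cross-check K12_split = N(E < split)/N(E ≥ split).
* **Dwell times**: a dwell runs from a segment's first photon to the next
  segment's first photon; each burst's first and last segments are censored
  and excluded.  Rates are exponential MLEs (1/mean) with bootstrap CIs;
  the integrated (survival) distribution is computed for display.
  *Caveat measured on synthetic data*: with ~10 photons per dwell and
  moderate emission contrast (0.45 vs 0.75) the most-probable path absorbs
  most short dwells and dwell rates underestimate the model's transition
  rates several-fold; Viterbi dwell analysis is quantitative only when
  dwells span many photons or the states are well separated.

## Derived observables

Free energies V = −ln p (k_BT, minimum at 0); barrier heights from the
Arrhenius relation ΔG‡ = ln(A₀/k) with A₀ = 10⁵ s⁻¹.  Equilibrium
coefficient K12 = p(low-E state)/p(high-E state) — state 1 is *defined* as
the lower-FRET state — with populations taken as posterior-expected photon
occupancy fractions (full posterior, not Viterbi counts).  The
substrate-response factor is R = K12(with)/K12(without); all uncertainties
are percentile bootstrap over bursts (200 resamples, seeded).  Distances
come from r = R₀(1/E − 1)^{1/6} with R₀ = 54 Å; distances are apparent (no
κ² or linker corrections).  Per-burst donor–acceptor cross-correlation uses
a pair-count estimator on geometric lag bins with (1 − τ/T) edge
correction, combined across bursts as the ratio of summed pair counts to
summed independence expectations and normalized to 1 at long lags; a rising
g_DA(τ) with relaxation time 1/(k12+k21) is the signature of anticorrelated
two-state dynamics.  Anisotropy decays follow
r(t) = (I_∥ − G·I_⊥)/(I_∥ + 2G·I_⊥) with G = 1 by default.

## Synthetic data

The generator emulates freely diffusing, double-labeled molecules: hidden
dynamics are a continuous-time Markov chain (exponential holding times,
stationary initial state); photon detection is a homogeneous Poisson
process during a burst, colored by the current state's E; leakage moves
donor-colored photons to the acceptor channel with probability l; direct
excitation superimposes extra acceptor-colored donor-period photons at
d × photon rate; acceptor-laser (PIE) photons arrive at the rate implied by
the configured period fraction (default 0.5, the symmetric-alternation
case in which the burst-level d-correction is exact); background photons at
per-channel rates cover the whole record.  Donor-only and acceptor-only
molecule fractions provide the single-label populations the correction
estimators need.  Burst durations are exponential with mean 1 ms, floored
at 0.2 ms (grazing transits are not bursts), with a fixed-duration mode for
controlled experiments; bursts are separated by dark gaps well above ten
burst-search cutoffs; everything derives deterministically from one seed.

Not emulated: diffusion-profile intensity variation across a burst
(inference operates on colors, not intensities), detector physics (IRF,
afterpulsing, dead time), triplet blinking, and acceptor photophysics.
Passing tests therefore demonstrate correctness of the inference given the
model's assumptions, not robustness to these instrumental effects.

Default in-burst detected photon rate is 2×10⁶ s⁻¹ (donor excitation).
This is deliberately at the bright end: with a 5 µs gap criterion, any
burst that survives detection intact necessarily has inter-photon gaps well
below 5 µs; at lower rates the generator's bursts would fragment under the
package's own burst search.  The parameter-recovery benchmark instead uses
its own stated conditions — 2×10⁵ s⁻¹, fixed 1 ms bursts, clean streams —
and takes burst boundaries from the ground truth so that burst-search
choices do not contaminate the recovery comparison.

## Problem sizes used in tests

Parameter recovery: 20 replicates × 5,000 bursts (10⁶ photons each), free
two-state fits with 2 restarts at 10⁻⁸/photon tolerance.  Free-energy
profile: 500 bursts, 10-state grid, 2 µs elementary step, single start run
to 10⁻⁷/photon.  Recoloring: 50 replicates × 200 bursts.  Cross-
correlation: 2,000–3,000 bursts.  Corrections: 1,500–2,000 mixed-species
bursts.  These sizes keep every statistical check comfortably powered
while the full suite completes in well under half an hour on one core.

## Known limitations

* EM rate estimates in photon-indexed mode are bounded by the identifiable
  per-photon matrix E[e^{QΔt}]; rates approaching or exceeding the photon
  rate are not recoverable.
* The split-point population ratio is meaningful only while the burst-E
  histogram retains two-state structure; once dynamics are much faster than
  the burst duration the histogram collapses to its mean and the area ratio
  becomes hypersensitive to the split position.
* Viterbi dwell-time analysis is biased toward long dwells at low photon-
  per-dwell counts (see above).
* The tick-resolved flag covers likelihood and decoding, not EM.
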