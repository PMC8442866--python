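# photonhmm

Photon-by-photon hidden-Markov analysis of single-molecule FRET bursts.

Freely diffusing, double-labeled molecules crossing a confocal spot produce
millisecond photon bursts.  When the molecule switches conformations on the
tens-of-microseconds scale — as the substrate-gripping pore loops of AAA+
disaggregation machines like ClpB do — per-burst FRET averages blur the
dynamics, but the *ordering* of individual donor/acceptor photons still
carries them.  `photonhmm` recovers those dynamics by fitting a hidden
Markov model directly to the photon colors of each burst:

* hidden states = conformational states, each with an apparent FRET
  efficiency E_i (its acceptor-color probability, row i of the observation
  matrix B);
* the transition matrix A acts between consecutive photons (or on an
  elementary time grid with silent steps, so states can switch between
  photons);
* every burst is an independent chain started from the prior Π.

Around that core the package provides the full pipeline used in such
studies: a synthetic photon-trace generator with exact kinetic ground
truth; burst search (5 µs inter-photon cutoff, ≥30 photons), PIE-based
leakage/direct-excitation corrections and stoichiometry selection; free,
sequential-grid (1D free-energy surface) and global shared-emission fits
with Viterbi decoding; validation by Monte-Carlo recoloring, segmentation
histograms and dwell-time analysis; and derived observables — free-energy
profiles V(E) = −k_BT ln p(E), equilibrium coefficients
K12 = p(low-E)/p(high-E), substrate-response factors R = K12^with/K12^without,
FRET→distance amplitudes via r = R₀(1/E − 1)^{1/6} (R₀ = 54 Å), per-burst
donor–acceptor cross-correlation, and anisotropy decays.

## Worked example

```python
import numpy as np
import photonhmm as ph

# two-state molecule: E = 0.45/0.75, symmetric exchange at 2e4 s^-1,
# 2e5 detected photons/s, 500 bursts of 1 ms
cfg = ph.benchmark_config(n_bursts=500, seed=7)
stream, truth = ph.generate_dataset(cfg)
colors, ticks = ph.truth_burst_sequences(stream, truth)

fit = ph.em_fit(colors, n_states=2, restarts=2, tol_per_photon=1e-8,
                max_iter=600, seed=3, ticks=ticks, tick=stream.tick)
print(fit.summary())
```

```
Photon-by-photon HMM fit
============================================================
bursts: 500    photons: 100178
states: 2    constraint: free
log-likelihood: -66628.912   iterations: 156   converged: True
restarts: 2   best restart: 0
------------------------------------------------------------
state   E (FRET)  occupancy      prior
    1     0.4539     0.5099     0.4437
    2     0.7543     0.4901     0.5563
------------------------------------------------------------
transition matrix (per photon step):
   0.91907   0.08093
   0.08480   0.91520
mean inter-photon time: 4.966 us
transition rates (s^-1, a_ij / <dt>):
       ---   16296.0
   17075.0       ---
```

The two fitted efficiencies land within 0.005 of the ground truth (0.45 /
0.75) and the occupancies near the true 50/50 split.  The per-photon
switching probabilities (~0.081–0.085) sit close to the identifiable value
E[e^{QΔt}] ≈ 0.083; divided by the ~5 µs mean photon spacing they give
rates of ~1.6–1.7×10⁴ s⁻¹ against the true 2×10⁴ s⁻¹ (the gap-averaging of
the photon-indexed convention; see `docs/methods.md`).  The interstate
motion amplitude from the fitted efficiencies,
`ph.motion_amplitude(*fit.state_fret)`, is 10.9 Å at R₀ = 54 Å.

A command-line pipeline wraps the same stages:

```bash
photonhmm simulate --out run.h5 --seed 1 --n-bursts 200
photonhmm bursts --in run.h5 --out bursts.tsv --leakage 0.0526 --direct-excitation 0.04
photonhmm fit --photons run.h5 --bursts bursts.tsv --out model.yaml --n-states 2 --seed 1
photonhmm validate --photons run.h5 --bursts bursts.tsv --model model.yaml --seed 1
```

## Layout

| Module | Contents |
| --- | --- |
| `photonhmm.simulate` | `SimConfig`, CTMC + Poisson photon generator, ground truth |
| `photonhmm.photons` | `PhotonStream`, Photon-HDF5-style I/O |
| `photonhmm.bursts` | burst search, raw/corrected E & S, BVA |
| `photonhmm.model` | `PhotonHMM` / `PhotonHMMResults`, fits, Viterbi |
| `photonhmm.validation` | recoloring, segmentation histograms, dwell times |
| `photonhmm.observables` | free energies, K12/R, distances, FCCS, anisotropy |
| `photonhmm.cli` | `photonhmm` console entry point |
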