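"""Synthetic photon-trace generator with known kinetic ground truth.

Emulates confocal smFRET measurements on freely diffusing, double-labeled
molecules: each transit through the beam yields a ~1 ms photon burst during
which the molecule interconverts between conformational states on the
tens-of-microseconds scale.  The hidden dynamics are a continuous-time Markov
chain; photon detection is a Poisson process whose color statistics are set
by the current state's FRET efficiency, contaminated by spectral leakage,
direct acceptor excitation, background counts, and the alternating-laser
(PIE) acceptor-excitation photons used for stoichiometry.

Ground-truth state labels and switch times are retained per photon and per
burst so that downstream inference can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .photons import ACCEPTOR, AEX, DEX, DONOR, DEFAULT_TICK, PhotonStream

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_trajectory",
    "emit_photons",
    "generate_dataset",
    "stationary_distribution",
    "benchmark_config",
    "truth_burst_sequences",
]

# molecular species codes
DUAL, DONOR_ONLY, ACCEPTOR_ONLY = 0, 1, 2


@dataclass
class SimConfig:
    """Generative settings for a synthetic diffusion-smFRET dataset.

    The defaults describe a two-state system switching at 2x10^4 s^-1 in each
    direction between apparent FRET efficiencies 0.45 and 0.75 — a molecule
    jumping between two conformations separated by roughly 11 Å at a Förster
    distance of 54 Å.  ``photon_rate`` is the detected donor-excitation count
    rate during a burst; the default 2x10^6 s^-1 keeps typical inter-photon
    gaps far below the 5 µs burst-search cutoff, as any burst surviving that
    criterion must have.
    """

    n_states: int = 2
    state_fret: np.ndarray = field(default_factory=lambda: np.array([0.45, 0.75]))
    #: off-diagonal transition rates in s^-1; diagonal ignored
    rate_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 2e4], [2e4, 0.0]])
    )
    photon_rate: float = 2e6
    burst_duration_mean: float = 1e-3
    #: draw durations exponentially (True) or use the mean as a fixed length
    burst_duration_exponential: bool = True
    #: lower truncation of exponential durations, so bursts clear the
    #: 30-photon detection threshold (grazing beam transits are not bursts)
    burst_duration_min: float = 2e-4
    n_bursts: int = 100
    #: donor / acceptor background count rates, s^-1
    background_rates: tuple = (1e3, 1e3)
    leakage: float = 0.05
    direct_excitation: float = 0.04
    #: fraction of photons falling in acceptor-laser (PIE) periods
    acceptor_excitation_fraction: float = 0.5
    #: fractions of bursts from incompletely labeled molecules
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    tick: float = DEFAULT_TICK
    #: mean of the exponential inter-burst dark gap, plus a hard floor
    gap_mean: float = 4e-4
    gap_min: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_fret = np.atleast_1d(np.asarray(self.state_fret, dtype=float))
        self.rate_matrix = np.atleast_2d(np.asarray(self.rate_matrix, dtype=float))
        n = self.n_states
        if n < 1:
            raise ValueError("n_states must be >= 1")
        if self.state_fret.shape != (n,):
            raise ValueError("state_fret must have length n_states")
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be n_states x n_states")
        off = self.rate_matrix[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)) or np.any(off < 0):
            raise ValueError("transition rates must be finite and nonnegative")
        if np.any(self.state_fret <= 0) or np.any(self.state_fret >= 1):
            raise ValueError("state_fret values must lie strictly inside (0, 1)")
        if self.photon_rate <= 0 or self.tick <= 0:
            raise ValueError("photon_rate and tick must be positive")
        if self.n_bursts < 0:
            raise ValueError("n_bursts must be >= 0")
        if not 0 <= self.leakage < 1 or not 0 <= self.direct_excitation < 1:
            raise ValueError("leakage and direct_excitation must be in [0, 1)")
        f = self.acceptor_excitation_fraction
        if not 0 <= f < 1:
            raise ValueError("acceptor_excitation_fraction must be in [0, 1)")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1:
            raise ValueError("species fractions must sum to <= 1")

    def with_(self, **kw) -> "SimConfig":
        """Copy with fields replaced."""
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Oracle labels accompanying a generated :class:`PhotonStream`.

    ``photon_state`` is the true hidden state of each photon (-1 for
    background photons); ``photon_burst`` the burst index (-1 outside
    bursts).  Per burst, the piecewise-constant state path is kept as
    ``(start_time_s, duration_s, switch_times_s, states, species)``.
    """

    photon_state: np.ndarray
    photon_burst: np.ndarray
    burst_start: np.ndarray
    burst_duration: np.ndarray
    burst_species: np.ndarray
    switch_times: list
    states: list

    @property
    def n_bursts(self) -> int:
        return len(self.burst_start)

    def to_tsv(self, path) -> None:
        """Sidecar ground-truth table: burst_id, species, switch times, states."""
        with open(path, "w") as fh:
            fh.write("burst_id\tstart_s\tduration_s\tspecies\tswitch_times_s\tstates\n")
            for b in range(self.n_bursts):
                st = ",".join(f"{t:.9g}" for t in self.switch_times[b])
                ss = ",".join(str(s) for s in self.states[b])
                fh.write(
                    f"{b}\t{self.burst_start[b]:.9g}\t{self.burst_duration[b]:.9g}"
                    f"\t{self.burst_species[b]}\t{st}\t{ss}\n"
                )


def benchmark_config(n_bursts: int = 5000, seed: int = 0,
                     rate_matrix=None, state_fret=(0.45, 0.75)) -> SimConfig:
    """Two-state recovery benchmark: clean photon streams at known kinetics.

    E = 0.45/0.75, symmetric exchange at 2x10^4 s^-1, 2x10^5 detected
    photons/s, fixed 1 ms bursts, and no leakage, direct excitation,
    background or acceptor-period photons — the photon record is already the
    corrected donor-excitation stream the HMM consumes, so recovered
    parameters compare directly against the generator's.
    """
    if rate_matrix is None:
        rate_matrix = np.array([[0.0, 2e4], [2e4, 0.0]])
    return SimConfig(
        n_states=len(state_fret),
        state_fret=np.asarray(state_fret, dtype=float),
        rate_matrix=np.asarray(rate_matrix, dtype=float),
        photon_rate=2e5,
        burst_duration_mean=1e-3,
        burst_duration_exponential=False,
        n_bursts=n_bursts,
        background_rates=(0.0, 0.0),
        leakage=0.0,
        direct_excitation=0.0,
        acceptor_excitation_fraction=0.0,
        seed=seed,
    )


def truth_burst_sequences(stream: PhotonStream, truth: GroundTruth):
    """Per-burst donor-excitation colors and ticks using ground-truth limits.

    Splits the stream by the generator's own burst boundaries instead of
    re-detecting them — the appropriate input for parameter-recovery tests,
    where burst-search choices should not contaminate the comparison.

    Returns ``(colors, ticks)`` lists indexed by burst.
    """
    dex = stream.excitation == DEX
    bid = truth.photon_burst[dex]
    ch = (stream.channel[dex] == ACCEPTOR).astype(np.int8)
    tk = stream.ticks[dex]
    order = np.argsort(bid, kind="stable")
    colors, ticks = [], []
    b_sorted = bid[order]
    lo = np.searchsorted(b_sorted, np.arange(truth.n_bursts), side="left")
    hi = np.searchsorted(b_sorted, np.arange(truth.n_bursts), side="right")
    for b in range(truth.n_bursts):
        sel = order[lo[b]:hi[b]]
        sel = np.sort(sel)
        colors.append(ch[sel])
        ticks.append(tk[sel])
    return colors, ticks


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of the CTMC generator built from off-diagonal rates.

    Solves pi Q = 0 with sum(pi) = 1, Q having row sums zero.  With all rates
    zero every distribution is stationary; the uniform one is returned.
    """
    K = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    n = K.shape[0]
    if not np.all(np.isfinite(K[~np.eye(n, dtype=bool)])):
        raise ValueError("rates must be finite")
    Q = K.copy()
    np.fill_diagonal(Q, 0.0)
    if np.any(Q < 0):
        raise ValueError("rates must be nonnegative")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if np.allclose(Q, 0):
        return np.full(n, 1.0 / n)
    # augmented least squares: pi Q = 0 and sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def simulate_trajectory(config: SimConfig, duration: float, rng=None):
    """Sample a piecewise-constant CTMC state path of the given duration.

    The initial state is drawn from the stationary distribution of the rate
    matrix; holding times are exponential with each state's total exit rate.

    Returns
    -------
    switch_times : ndarray
        Segment start times in seconds, beginning with 0.0, strictly
        increasing, all < ``duration``.
    states : ndarray of int
        State index of each segment.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    K = config.rate_matrix.copy()
    np.fill_diagonal(K, 0.0)
    exit_rate = K.sum(axis=1)
    pi = stationary_distribution(config.rate_matrix)
    s = rng.choice(config.n_states, p=pi)
    t = 0.0
    switch_times = [0.0]
    states = [s]
    while True:
        if exit_rate[s] == 0.0:
            break
        t += rng.exponential(1.0 / exit_rate[s])
        if t >= duration:
            break
        s = rng.choice(config.n_states, p=K[s] / exit_rate[s])
        switch_times.append(t)
        states.append(s)
    return np.asarray(switch_times), np.asarray(states, dtype=np.int64)


def _poisson_times(rate: float, duration: float, rng) -> np.ndarray:
    n = rng.poisson(rate * duration) if rate > 0 else 0
    return np.sort(rng.uniform(0.0, duration, size=n))


def emit_photons(switch_times, states, duration, config: SimConfig, rng=None,
                 species: int = DUAL):
    """Color a state path with photons.

    Donor-excitation photons arrive as a Poisson process at ``photon_rate``;
    each is acceptor-colored with the current state's FRET efficiency, after
    which leakage reassigns donor-colored photons to the acceptor channel
    with probability ``leakage``.  Direct acceptor excitation adds extra
    acceptor-colored donor-period photons at ``direct_excitation *
    photon_rate``; acceptor-laser (PIE) photons arrive at the rate implied by
    ``acceptor_excitation_fraction``.  Donor-only molecules emit no FRET, no
    direct-excitation and no acceptor-period photons; acceptor-only molecules
    emit only the latter two.

    Returns ``(times_s, channel, excitation, state)`` arrays sorted in time;
    ``state`` is the hidden state at each photon's arrival.
    """
    rng = np.random.default_rng(rng)
    switch_times = np.asarray(switch_times, dtype=float)
    states = np.asarray(states, dtype=np.int64)
    if switch_times.size == 0:
        z = np.zeros(0)
        return z, z.astype(np.uint8), z.astype(np.uint8), z.astype(np.int64)

    f = config.acceptor_excitation_fraction
    aex_rate = config.photon_rate * f / (1.0 - f)

    t_parts, ch_parts, ex_parts, st_parts = [], [], [], []

    def _state_at(t):
        return states[np.searchsorted(switch_times, t, side="right") - 1]

    if species in (DUAL, DONOR_ONLY):
        t_dex = _poisson_times(config.photon_rate, duration, rng)
        s_dex = _state_at(t_dex)
        if species == DUAL:
            e_phot = config.state_fret[s_dex]
        else:
            e_phot = np.zeros(len(t_dex))  # no acceptor, no transfer
        is_acc = rng.random(len(t_dex)) < e_phot
        leaked = (~is_acc) & (rng.random(len(t_dex)) < config.leakage)
        ch = np.where(is_acc | leaked, ACCEPTOR, DONOR).astype(np.uint8)
        t_parts.append(t_dex)
        ch_parts.append(ch)
        ex_parts.append(np.full(len(t_dex), DEX, dtype=np.uint8))
        st_parts.append(s_dex)

    if species in (DUAL, ACCEPTOR_ONLY):
        # direct excitation of the acceptor by the donor laser
        t_dir = _poisson_times(config.direct_excitation * config.photon_rate,
                               duration, rng)
        t_parts.append(t_dir)
        ch_parts.append(np.full(len(t_dir), ACCEPTOR, dtype=np.uint8))
        ex_parts.append(np.full(len(t_dir), DEX, dtype=np.uint8))
        st_parts.append(_state_at(t_dir))
        # acceptor-laser periods probe the acceptor directly
        t_aex = _poisson_times(aex_rate, duration, rng)
        t_parts.append(t_aex)
        ch_parts.append(np.full(len(t_aex), ACCEPTOR, dtype=np.uint8))
        ex_parts.append(np.full(len(t_aex), AEX, dtype=np.uint8))
        st_parts.append(_state_at(t_aex))

    t = np.concatenate(t_parts)
    order = np.argsort(t, kind="stable")
    return (
        t[order],
        np.concatenate(ch_parts)[order],
        np.concatenate(ex_parts)[order],
        np.concatenate(st_parts)[order],
    )


def generate_dataset(config: SimConfig):
    """Assemble a multi-burst photon stream with ground truth.

    Bursts are laid out sequentially with exponential dark gaps (floored at
    ``gap_min``, well above ten times the 5 µs burst-search cutoff) so that
    the burst detector cannot merge neighbours.  Background photons at the
    configured channel rates are superimposed over the whole record.  All
    randomness derives from ``config.seed``; per-burst generators are spawned
    deterministically, so a fixed seed reproduces the stream bit for bit.

    Returns
    -------
    stream : PhotonStream
    truth : GroundTruth
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_bursts + 2)
    rng_layout = np.random.default_rng(children[0])
    rng_bg = np.random.default_rng(children[1])

    starts = np.zeros(config.n_bursts)
    durations = np.zeros(config.n_bursts)
    species = np.zeros(config.n_bursts, dtype=np.int64)
    p_do, p_ao = config.donor_only_fraction, config.acceptor_only_fraction
    t_cursor = 0.0
    all_t, all_ch, all_ex, all_st, all_bid = [], [], [], [], []
    switch_lists, state_lists = [], []

    for b in range(config.n_bursts):
        rng = np.random.default_rng(children[b + 2])
        gap = config.gap_min + rng_layout.exponential(config.gap_mean)
        t_cursor += gap
        if config.burst_duration_exponential:
            dur = config.burst_duration_min + rng.exponential(
                max(config.burst_duration_mean - config.burst_duration_min, 0.0)
            )
        else:
            dur = config.burst_duration_mean
        u = rng_layout.random()
        sp = DONOR_ONLY if u < p_do else (ACCEPTOR_ONLY if u < p_do + p_ao else DUAL)
        sw, st = simulate_trajectory(config, dur, rng)
        t, ch, ex, ps = emit_photons(sw, st, dur, config, rng, species=sp)
        if sp != DUAL:
            ps = np.full(len(t), -1, dtype=np.int64)
        all_t.append(t + t_cursor)
        all_ch.append(ch)
        all_ex.append(ex)
        all_st.append(ps)
        all_bid.append(np.full(len(t), b, dtype=np.int64))
        starts[b] = t_cursor
        durations[b] = dur
        species[b] = sp
        switch_lists.append(sw)
        state_lists.append(st)
        t_cursor += dur

    total_T = t_cursor + config.gap_min + config.gap_mean
    bg_d, bg_a = config.background_rates
    f = config.acceptor_excitation_fraction
    for rate, chan in ((bg_d, DONOR), (bg_a, ACCEPTOR)):
        tb = _poisson_times(rate, total_T, rng_bg)
        all_t.append(tb)
        all_ch.append(np.full(len(tb), chan, dtype=np.uint8))
        all_ex.append((rng_bg.random(len(tb)) < f).astype(np.uint8))
        all_st.append(np.full(len(tb), -1, dtype=np.int64))
        # background inside a burst window belongs to that burst
        idx = np.searchsorted(starts, tb, side="right") - 1
        inside = (idx >= 0) & (tb <= starts[np.clip(idx, 0, None)] +
                               durations[np.clip(idx, 0, None)])
        bid = np.where(inside, np.clip(idx, 0, None), -1)
        all_bid.append(bid.astype(np.int64))

    t = np.concatenate(all_t) if all_t else np.zeros(0)
    order = np.argsort(t, kind="stable")
    ticks = np.round(t[order] / config.tick).astype(np.int64)
    # quantization must not break time ordering
    ticks = np.maximum.accumulate(ticks) if ticks.size else ticks
    stream = PhotonStream(
        ticks,
        np.concatenate(all_ch)[order] if all_ch else np.zeros(0, np.uint8),
        np.concatenate(all_ex)[order] if all_ex else np.zeros(0, np.uint8),
        tick=config.tick,
        meta={"seed": config.seed, "n_bursts": config.n_bursts},
    )
    truth = GroundTruth(
        photon_state=np.concatenate(all_st)[order] if all_st else np.zeros(0, np.int64),
        photon_burst=np.concatenate(all_bid)[order] if all_bid else np.zeros(0, np.int64),
        burst_start=starts,
        burst_duration=durations,
        burst_species=species,
        switch_times=switch_lists,
        states=state_lists,
    )
    return stream, truth
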