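"""Photon-by-photon hidden Markov modeling of smFRET bursts.

The model treats every selected burst as an independent realization of a
hidden Markov chain observed through single photons: the hidden state is the
conformational state of the molecule, the observation alphabet is the photon
color (donor / acceptor), and each state's acceptor-emission probability is
its apparent FRET efficiency.  One application of the transition matrix
separates consecutive photons (photon-indexed chain); an optional
tick-resolved mode propagates the chain through the elementary clock ticks
between photons for likelihood evaluation and Viterbi decoding.

The public surface follows the statsmodels convention: build a
:class:`PhotonHMM` from burst color sequences, call :meth:`PhotonHMM.fit`
(Baum-Welch with multiple random restarts), and read estimates,
uncertainties and diagnostics off the returned :class:`PhotonHMMResults`.
Fit variants: unconstrained n-state, the sequential-grid restriction used to
map a 1D free-energy surface (emissions frozen on an equally spaced FRET
grid, transitions tridiagonal), and a global two-dataset fit sharing the
observation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._kernels import estep, forward_loglik, pack_sequences, viterbi_paths
from .photons import DEFAULT_TICK

__all__ = [
    "FretModel",
    "TopologyConstraint",
    "PhotonHMM",
    "PhotonHMMResults",
    "GlobalFitResults",
    "ViterbiSegmentation",
    "DegenerateFitWarning",
    "sequence_loglik",
    "em_fit",
    "em_fit_restricted_1d",
    "em_fit_global",
    "viterbi_decode",
]

_STOCH_TOL = 1e-9


class DegenerateFitWarning(UserWarning):
    """A fitted state carries (numerically) zero occupancy."""


@dataclass
class FretModel:
    """Hidden-Markov parameter set lambda = (prior, transition, observation).

    ``prior`` (length n) is the state distribution at the first photon of a
    burst; ``transition`` (n x n, row-stochastic) acts once between
    consecutive photons; ``observation`` (n x 2, row-stochastic) gives each
    state's donor/acceptor color probabilities, so column 1 is the state's
    apparent FRET efficiency.
    """

    prior: np.ndarray
    transition: np.ndarray
    observation: np.ndarray

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.observation = np.atleast_2d(np.asarray(self.observation, dtype=float))
        self.validate()

    def validate(self) -> None:
        n = self.n_states
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if self.observation.shape[0] != n:
            raise ValueError("observation matrix shape mismatch")
        for name, m in (("prior", self.prior[None, :]),
                        ("transition", self.transition),
                        ("observation", self.observation)):
            if np.any(m < -_STOCH_TOL):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
                raise ValueError(f"{name} rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.prior)

    @property
    def state_fret(self) -> np.ndarray:
        """Apparent FRET efficiency of each state (acceptor color probability)."""
        return self.observation[:, 1]

    def sorted_by_fret(self):
        """Relabel states in ascending FRET efficiency; returns (model, perm)."""
        perm = np.argsort(self.state_fret, kind="stable")
        return (
            FretModel(
                self.prior[perm],
                self.transition[np.ix_(perm, perm)],
                self.observation[perm],
            ),
            perm,
        )

    @classmethod
    def two_state(cls, e1, e2, a12, a21, prior=None):
        """Convenience constructor for a two-state model."""
        prior = np.array([0.5, 0.5]) if prior is None else np.asarray(prior)
        A = np.array([[1 - a12, a12], [a21, 1 - a21]])
        B = np.array([[1 - e1, e1], [1 - e2, e2]])
        return cls(prior, A, B)

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "prior": self.prior.tolist(),
            "transition": self.transition.tolist(),
            "observation": self.observation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FretModel":
        return cls(np.array(d["prior"]), np.array(d["transition"]),
                   np.array(d["observation"]))


@dataclass
class TopologyConstraint:
    """Structural restriction on the hidden chain.

    ``free`` leaves all parameters open.  ``sequential_grid`` freezes the
    observation matrix on ``n_grid`` equally spaced FRET efficiencies between
    ``e_min`` and ``e_max`` and restricts transitions to nearest grid
    neighbours (tridiagonal), turning state occupancies into a discretized
    1D free-energy profile along the FRET coordinate.

    ``time_step`` switches the chain from photon-indexed (one transition-
    matrix application between consecutive photons) to elementary-time-step
    propagation: silent no-photon steps of this length (seconds) are
    inserted between photons, so state changes — in particular multi-step
    crossings of a sequential grid — can occur between photons without
    emitting.  Strongly recommended for ``sequential_grid``: a well-to-well
    crossing then carries no photon occupancy through the intermediate grid
    states, as in the tick-resolved formulation.
    """

    kind: str = "free"
    n_grid: int = 9
    e_min: float = 0.05
    e_max: float = 0.98
    time_step: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("free", "sequential_grid"):
            raise ValueError("kind must be 'free' or 'sequential_grid'")
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.kind == "sequential_grid":
            if self.n_grid < 2:
                raise ValueError("grid must have at least 2 states")
            if not 0 <= self.e_min < self.e_max <= 1:
                raise ValueError("grid endpoints must be increasing in [0, 1]")

    def grid(self) -> np.ndarray:
        return np.linspace(self.e_min, self.e_max, self.n_grid)

    def transition_mask(self) -> np.ndarray:
        n = self.n_grid
        mask = np.zeros((n, n), dtype=bool)
        idx = np.arange(n)
        mask[idx, idx] = True
        mask[idx[:-1], idx[:-1] + 1] = True
        mask[idx[1:], idx[1:] - 1] = True
        return mask


@dataclass
class ViterbiSegmentation:
    """Most-probable state path per burst with its constant-state segments.

    ``segments`` has one row per maximal constant-state run: burst_id,
    state, photon index range within the burst, start time, duration
    (first photon of the segment to first photon of the next; for the final
    segment, to the last photon) and censoring flags — a burst's first and
    last segments have unknown true entry/exit times.
    """

    paths: list
    ticks: list
    tick: float
    logprobs: np.ndarray
    n_states: int
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.segments) == 0 and self.paths:
            self.segments = _build_segments(self.paths, self.ticks, self.tick)


def _build_segments(paths, ticks, tick) -> pd.DataFrame:
    rows = []
    for b, (path, tk) in enumerate(zip(paths, ticks)):
        if len(path) == 0:
            continue
        change = np.flatnonzero(np.diff(path)) + 1
        bounds = np.concatenate(([0], change, [len(path)]))
        n_seg = len(bounds) - 1
        for k in range(n_seg):
            i0, i1 = int(bounds[k]), int(bounds[k + 1])
            if k < n_seg - 1:
                dur = (tk[int(bounds[k + 1])] - tk[i0]) * tick
            else:
                dur = (tk[i1 - 1] - tk[i0]) * tick
            rows.append(
                {
                    "burst_id": b,
                    "state": int(path[i0]),
                    "first": i0,
                    "last": i1 - 1,
                    "t_start_s": tk[i0] * tick,
                    "duration_s": dur,
                    "n_photons": i1 - i0,
                    "censored_start": k == 0,
                    "censored_end": k == n_seg - 1,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- model
class PhotonHMM:
    """Photon-color HMM over a set of burst observation sequences.

    Parameters
    ----------
    colors : sequence of int arrays
        Per-burst photon colors, 0 = donor, 1 = acceptor (donor-excitation
        photons only).
    ticks : sequence of int arrays, optional
        Matching arrival times in clock ticks; required for dwell times,
        rate conversion and tick-resolved evaluation.
    tick : float
        Clock period in seconds.
    constraint : TopologyConstraint, optional
        Defaults to a free model.
    """

    def __init__(self, colors, ticks=None, tick: float = DEFAULT_TICK,
                 constraint: TopologyConstraint | None = None):
        self.colors = [np.asarray(c, dtype=np.int8) for c in colors]
        if any((c < 0).any() or (c > 1).any() for c in self.colors):
            raise ValueError("photon colors must be 0 (donor) or 1 (acceptor)")
        self.ticks = None if ticks is None else [np.asarray(t, np.int64) for t in ticks]
        if self.ticks is not None and [len(t) for t in self.ticks] != [
            len(c) for c in self.colors
        ]:
            raise ValueError("ticks must match colors burst by burst")
        self.tick = float(tick)
        self.constraint = constraint or TopologyConstraint()
        self._obs, self._starts = pack_sequences(self.colors)

    @classmethod
    def from_bursts(cls, stream, burst_table, selected_only: bool = True,
                    constraint: TopologyConstraint | None = None) -> "PhotonHMM":
        """Build from a photon stream and a burst table (selected bursts)."""
        from .bursts import burst_color_sequences

        colors, ticks = burst_color_sequences(stream, burst_table, selected_only)
        return cls(colors, ticks, tick=stream.tick, constraint=constraint)

    # ----------------------------------------------------------- descriptive
    @property
    def n_bursts(self) -> int:
        return len(self.colors)

    @property
    def n_photons(self) -> int:
        return int(self._starts[-1])

    @property
    def mean_interphoton_time(self) -> float | None:
        """Mean within-burst inter-photon interval in seconds."""
        if self.ticks is None:
            return None
        gaps = [np.diff(t) for t in self.ticks if len(t) > 1]
        if not gaps:
            return None
        return float(np.concatenate(gaps).mean()) * self.tick

    # ------------------------------------------------------------ likelihood
    def loglike(self, model: FretModel, tick_resolved: bool = False) -> float:
        """Total log-likelihood of all bursts under ``model``.

        Each burst is an independent chain started from the prior.  In
        tick-resolved mode the transition matrix is raised to the number of
        elementary clock ticks separating consecutive photons.
        """
        model.validate()
        if not tick_resolved:
            if self.n_photons == 0:
                return 0.0
            return float(forward_loglik(self._obs, self._starts, model.prior,
                                        model.transition, model.observation))
        if self.ticks is None:
            raise ValueError("tick-resolved mode requires photon tick times")
        total = 0.0
        for c, t in zip(self.colors, self.ticks):
            total += _tick_resolved_forward(c, t, model)
        return total

    # ------------------------------------------------------------------- fit
    def fit(self, n_states: int = 2, restarts: int = 50,
            tol_per_photon: float = 1e-6, max_iter: int = 3000,
            seed=None) -> "PhotonHMMResults":
        """Baum-Welch fit, best of ``restarts`` random initializations.

        Initial guesses use a uniform prior, diagonally dominant transition
        matrices with off-diagonal mass log-uniform in [1e-3, 0.3], and
        sorted uniform emission draws (or the frozen grid under a
        ``sequential_grid`` constraint).  Convergence: absolute
        log-likelihood gain below ``tol_per_photon`` per photon.
        """
        if self.n_bursts == 0:
            raise ValueError("cannot fit an empty burst set")
        grid_mode = self.constraint.kind == "sequential_grid"
        if grid_mode:
            n_states = self.constraint.n_grid
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        step = self.constraint.time_step
        if step is None:
            obs, starts = self._obs, self._starts
        else:
            if self.ticks is None:
                raise ValueError("time-step mode requires photon tick times")
            obs, starts = pack_sequences(
                _expand_with_silent(self.colors, self.ticks, self.tick, step)
            )
        rng = np.random.default_rng(seed)
        tol_total = tol_per_photon * max(self.n_photons, 1)
        best = None
        restart_ll = np.full(restarts, -np.inf)
        for r in range(restarts):
            pi0, A0, B0 = self._initial_guess(n_states, rng)
            if step is not None:
                B0 = np.column_stack([B0, np.ones(n_states)])
            out = _run_em(obs, starts, pi0, A0, B0,
                          tol_total, max_iter, update_b=not grid_mode)
            restart_ll[r] = out[3][-1]
            if best is None or restart_ll[r] > best[3][-1]:
                best = out
        (pi, A, B), occ, converged, history = best
        params = FretModel(pi, A, B[:, :2])
        res = PhotonHMMResults(
            self, params, loglik=history[-1], n_iter=len(history),
            converged=converged, restart_logliks=restart_ll,
            best_restart=int(np.argmax(restart_ll)), burst_occupancy=occ,
            ll_history=np.asarray(history), time_step=step,
        )
        res._check_degenerate()
        return res

    def _initial_guess(self, n, rng):
        pi0 = np.full(n, 1.0 / n)
        if self.constraint.kind == "sequential_grid":
            grid = self.constraint.grid()
            B0 = np.column_stack([1 - grid, grid])
            mask = self.constraint.transition_mask()
            A0 = np.zeros((n, n))
            for i in range(n):
                off = np.flatnonzero(mask[i] & (np.arange(n) != i))
                w = np.exp(rng.uniform(np.log(1e-3), np.log(0.3)))
                A0[i, off] = w / len(off)
                A0[i, i] = 1.0 - w
        else:
            e = np.sort(rng.uniform(0.05, 0.95, size=n))
            B0 = np.column_stack([1 - e, e])
            A0 = np.zeros((n, n))
            for i in range(n):
                w = np.exp(rng.uniform(np.log(1e-3), np.log(0.3)))
                if n > 1:
                    A0[i] = w / (n - 1)
                A0[i, i] = 1.0 - (w if n > 1 else 0.0)
        return pi0, A0, B0


def _run_em(obs, starts, pi, A, B, tol_total, max_iter, update_b=True):
    """EM iterations; returns ((pi, A, B), burst_occ, converged, ll_history).

    Parameters returned are the ones that achieved the last log-likelihood
    (the pending M-step update is discarded on convergence), so the history
    is the exact likelihood trace of the returned model's ancestors and is
    nondecreasing by the EM guarantee.
    """
    history = []
    occ = None
    converged = False
    prev = -np.inf
    snap = (pi, A, B)
    for _ in range(max_iter):
        ll, pi_num, xi_num, gam_num, burst_occ = estep(obs, starts, pi, A, B)
        history.append(ll)
        occ = burst_occ
        snap = (pi, A, B)
        if ll - prev < tol_total and len(history) > 1:
            converged = True
            break
        prev = ll
        # M-step; rows without support keep their previous values
        pi = pi_num / pi_num.sum()
        arow = xi_num.sum(axis=1)
        newA = A.copy()
        nz = arow > 0
        newA[nz] = xi_num[nz] / arow[nz, None]
        A = newA
        if update_b:
            # only the photon colors (first two symbols) are re-estimated;
            # a silent third column, if present, stays at weight 1
            brow = gam_num[:, :2].sum(axis=1)
            newB = B.copy()
            nz = brow > 0
            newB[nz, :2] = gam_num[nz, :2] / brow[nz, None]
            B = newB
    return snap, occ, converged, history


def _expand_with_silent(colors, ticks, tick, time_step):
    """Insert silent steps (symbol 2) between photons on a fixed time grid.

    Each inter-photon gap becomes ``max(round(gap / time_step), 1)``
    elementary steps; the intermediate ones emit nothing (observation weight
    1 for every state), so the transition matrix acts per ``time_step``.
    """
    out = []
    for c, t in zip(colors, ticks):
        if len(c) == 0:
            out.append(np.zeros(0, dtype=np.int8))
            continue
        steps = np.maximum(
            np.round(np.diff(t) * tick / time_step).astype(np.int64), 1
        )
        total = 1 + int(steps.sum())
        seq = np.full(total, 2, dtype=np.int8)
        pos = np.concatenate(([0], np.cumsum(steps)))
        seq[pos] = c
        out.append(seq)
    return out


def _gap_steps(ticks, tick, time_step):
    return np.maximum(np.round(np.diff(ticks) * tick / time_step).astype(np.int64), 1)


def _tick_resolved_forward(colors, ticks, model: FretModel) -> float:
    """Scaled forward pass with transition propagators A^dk between photons."""
    if len(colors) == 0:
        return 0.0
    A, B, pi = model.transition, model.observation, model.prior
    alpha = pi * B[:, colors[0]]
    ll = np.log(alpha.sum())
    alpha /= alpha.sum()
    for t in range(1, len(colors)):
        dk = max(int(ticks[t] - ticks[t - 1]), 1)
        P = np.linalg.matrix_power(A, dk)
        alpha = (alpha @ P) * B[:, colors[t]]
        s = alpha.sum()
        ll += np.log(s)
        alpha /= s
    return float(ll)


# ------------------------------------------------------------------- results
class PhotonHMMResults:
    """Estimates and diagnostics from a :class:`PhotonHMM` fit.

    States are relabeled in ascending FRET efficiency.  ``burst_occupancy``
    holds the posterior expected number of photons emitted from each state
    in each burst — the sufficient statistic for population ratios and their
    burst-bootstrap uncertainties.
    """

    def __init__(self, data: PhotonHMM, params: FretModel, loglik, n_iter,
                 converged, restart_logliks, best_restart, burst_occupancy,
                 ll_history, time_step=None):
        params, perm = params.sorted_by_fret()
        self.data = data
        self.params = params
        self.time_step = time_step
        self.loglik = float(loglik)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.restart_logliks = np.asarray(restart_logliks)
        self.best_restart = best_restart
        self.burst_occupancy = np.asarray(burst_occupancy)[:, perm]
        self.ll_history = np.asarray(ll_history)

    # ------------------------------------------------------------ quantities
    @property
    def n_states(self) -> int:
        return self.params.n_states

    @property
    def state_fret(self) -> np.ndarray:
        return self.params.state_fret

    @property
    def transition_matrix(self) -> np.ndarray:
        return self.params.transition

    @property
    def occupancies(self) -> np.ndarray:
        """Expected fraction of photons in each state (posterior-weighted)."""
        tot = self.burst_occupancy.sum()
        return self.burst_occupancy.sum(axis=0) / tot

    def transition_rates(self, mean_dt: float | None = None) -> np.ndarray:
        """Per-step transition probabilities converted to rates (s^-1).

        Photon-indexed fits use rate_ij = a_ij / <dt> with <dt> the
        dataset's mean inter-photon interval (a reporting convention);
        time-step fits use the elementary step length.  The diagonal is
        reported as NaN.
        """
        if self.time_step is not None:
            k = self.params.transition / self.time_step
        else:
            mean_dt = (mean_dt if mean_dt is not None
                       else self.data.mean_interphoton_time)
            if mean_dt is None:
                raise ValueError("mean inter-photon time unavailable; pass mean_dt")
            k = self.params.transition / mean_dt
        np.fill_diagonal(k, np.nan)
        return k

    def viterbi(self) -> ViterbiSegmentation:
        """Most-probable state path per burst under the fitted model."""
        return viterbi_decode(self.params, self.data.colors,
                              ticks=self.data.ticks, tick=self.data.tick,
                              time_step=self.time_step)

    def recolor(self, seed=None):
        """Monte-Carlo recoloring of the data under the fitted model."""
        from .validation import recolor_sequences

        return recolor_sequences(self.data.colors, self.params, seed=seed)

    def bootstrap_occupancy(self, n_boot: int = 200, seed=None) -> np.ndarray:
        """Burst-bootstrap replicates of the state occupancies, (n_boot, n)."""
        rng = np.random.default_rng(seed)
        nb = self.burst_occupancy.shape[0]
        idx = rng.integers(0, nb, size=(n_boot, nb))
        occ = self.burst_occupancy[idx].sum(axis=1)
        return occ / occ.sum(axis=1, keepdims=True)

    def _check_degenerate(self) -> None:
        frac = self.occupancies
        dead = np.flatnonzero(frac < 1e-9)
        if dead.size:
            warnings.warn(
                f"states {dead.tolist()} have zero occupancy; pruning",
                DegenerateFitWarning,
            )
            keep = np.flatnonzero(frac >= 1e-9)
            pi = self.params.prior[keep]
            A = self.params.transition[np.ix_(keep, keep)]
            A = A / A.sum(axis=1, keepdims=True)
            self.params = FretModel(pi / pi.sum(), A, self.params.observation[keep])
            self.burst_occupancy = self.burst_occupancy[:, keep]

    # -------------------------------------------------------------- reporting
    def summary(self) -> str:
        lines = [
            "Photon-by-photon HMM fit",
            "=" * 60,
            f"bursts: {self.data.n_bursts}    photons: {self.data.n_photons}",
            f"states: {self.n_states}    constraint: {self.data.constraint.kind}",
            f"log-likelihood: {self.loglik:.3f}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"restarts: {len(self.restart_logliks)}"
            f"   best restart: {self.best_restart}",
            "-" * 60,
            f"{'state':>5} {'E (FRET)':>10} {'occupancy':>10} {'prior':>10}",
        ]
        for i in range(self.n_states):
            lines.append(
                f"{i + 1:>5} {self.state_fret[i]:>10.4f} "
                f"{self.occupancies[i]:>10.4f} {self.params.prior[i]:>10.4f}"
            )
        lines.append("-" * 60)
        lines.append("transition matrix (per photon step):")
        for row in self.params.transition:
            lines.append("  " + "  ".join(f"{v:8.5f}" for v in row))
        mean_dt = self.data.mean_interphoton_time
        if mean_dt is not None and self.n_states > 1:
            k = self.transition_rates(mean_dt)
            lines.append(f"mean inter-photon time: {mean_dt * 1e6:.3f} us")
            lines.append("transition rates (s^-1, a_ij / <dt>):")
            for row in k:
                lines.append(
                    "  " + "  ".join("     ---" if np.isnan(v) else f"{v:8.1f}"
                                     for v in row)
                )
        return "\n".join(lines)

    def to_yaml(self, path) -> None:
        rec = self.params.to_dict()
        rec.update(
            occupancies=[float(v) for v in self.occupancies],
            loglik=float(self.loglik),
            n_iter=self.n_iter,
            converged=self.converged,
            constraint=self.data.constraint.kind,
            restart_logliks=[float(v) for v in self.restart_logliks],
        )
        with open(path, "w") as fh:
            yaml.safe_dump(rec, fh, sort_keys=False)

    # ------------------------------------------------------------- plotting
    def plot_fret_histogram(self, ax=None, bins=40):
        """Per-burst mean-E histogram with fitted state efficiencies marked."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        e = [c.mean() for c in self.data.colors if len(c)]
        ax.hist(e, bins=np.linspace(0, 1, bins + 1), color="0.6",
                density=True, label="bursts")
        for i, ei in enumerate(self.state_fret):
            ax.axvline(ei, ls="--", label=f"state {i + 1}: E={ei:.2f}")
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel("density")
        ax.legend()
        return ax


@dataclass
class GlobalFitResults:
    """Two-dataset global fit sharing the observation matrix.

    ``results`` holds one :class:`PhotonHMMResults` per dataset (independent
    prior and transition matrix, common state FRET efficiencies); ``loglik``
    is the summed log-likelihood.
    """

    results: tuple
    loglik: float
    converged: bool
    n_iter: int
    restart_logliks: np.ndarray

    @property
    def shared_fret(self) -> np.ndarray:
        return self.results[0].state_fret

    def summary(self) -> str:
        parts = [f"Global fit (shared observation matrix), total "
                 f"log-likelihood {self.loglik:.3f}"]
        for tag, r in zip(("dataset A", "dataset B"), self.results):
            parts.append(f"\n--- {tag} ---\n" + r.summary())
        return "\n".join(parts)


# -------------------------------------------------------- module-level API
def sequence_loglik(model: FretModel, colors, ticks=None,
                    tick: float = DEFAULT_TICK,
                    tick_resolved: bool = False) -> float:
    """Total forward log-likelihood of burst color sequences under ``model``."""
    if len(colors) == 0:
        return 0.0
    return PhotonHMM(colors, ticks=ticks, tick=tick).loglike(
        model, tick_resolved=tick_resolved
    )


def em_fit(colors, n_states: int, restarts: int = 50,
           tol_per_photon: float = 1e-6, max_iter: int = 3000, seed=None,
           ticks=None, tick: float = DEFAULT_TICK) -> PhotonHMMResults:
    """Unconstrained Baum-Welch fit (best of random restarts)."""
    return PhotonHMM(colors, ticks=ticks, tick=tick).fit(
        n_states=n_states, restarts=restarts, tol_per_photon=tol_per_photon,
        max_iter=max_iter, seed=seed,
    )


def em_fit_restricted_1d(colors, constraint: TopologyConstraint,
                         restarts: int = 50, tol_per_photon: float = 1e-6,
                         max_iter: int = 3000, seed=None, ticks=None,
                         tick: float = DEFAULT_TICK) -> PhotonHMMResults:
    """Sequential-grid fit: emissions frozen, transitions tridiagonal."""
    if constraint.kind != "sequential_grid":
        raise ValueError("constraint must be of kind 'sequential_grid'")
    return PhotonHMM(colors, ticks=ticks, tick=tick, constraint=constraint).fit(
        restarts=restarts, tol_per_photon=tol_per_photon, max_iter=max_iter,
        seed=seed,
    )


def em_fit_global(colors_a, colors_b, n_states: int, restarts: int = 50,
                  tol_per_photon: float = 1e-6, max_iter: int = 3000,
                  seed=None, ticks_a=None, ticks_b=None,
                  tick: float = DEFAULT_TICK) -> GlobalFitResults:
    """Global fit of two datasets with a shared observation matrix.

    The prior and transition matrix are optimized freely and independently
    per dataset; the observation matrix is updated from the pooled emission
    statistics of both, so both conditions share one set of state FRET
    efficiencies.
    """
    if len(colors_a) == 0 or len(colors_b) == 0:
        raise ValueError("both datasets must be nonempty")
    da = PhotonHMM(colors_a, ticks=ticks_a, tick=tick)
    db = PhotonHMM(colors_b, ticks=ticks_b, tick=tick)
    rng = np.random.default_rng(seed)
    tol_total = tol_per_photon * max(da.n_photons + db.n_photons, 1)
    restart_ll = np.full(restarts, -np.inf)
    best = None
    for r in range(restarts):
        pi0, A0, B0 = da._initial_guess(n_states, rng)
        out = _run_global_em(da, db, pi0, A0, B0, tol_total, max_iter)
        restart_ll[r] = out["history"][-1]
        if best is None or restart_ll[r] > best["history"][-1]:
            best = out
    history = best["history"]
    perm = np.argsort(best["B"][:, 1], kind="stable")
    results = []
    for dset, pi, A, occ, ll in (
        (da, best["pi_a"], best["A_a"], best["occ_a"], best["ll_a"]),
        (db, best["pi_b"], best["A_b"], best["occ_b"], best["ll_b"]),
    ):
        params = FretModel(pi, A, best["B"])
        results.append(
            PhotonHMMResults(
                dset, params, loglik=ll, n_iter=len(history),
                converged=best["converged"], restart_logliks=restart_ll,
                best_restart=int(np.argmax(restart_ll)),
                burst_occupancy=occ, ll_history=np.asarray(history),
            )
        )
    # PhotonHMMResults sorts each dataset by its own (shared) E values, so the
    # permutation is identical and the shared-B contract survives relabeling.
    assert np.allclose(results[0].state_fret, results[1].state_fret)
    _ = perm
    return GlobalFitResults(
        results=tuple(results), loglik=float(history[-1]),
        converged=best["converged"], n_iter=len(history),
        restart_logliks=restart_ll,
    )


def _run_global_em(da: PhotonHMM, db: PhotonHMM, pi0, A0, B0, tol_total,
                   max_iter) -> dict:
    pi_a = pi0.copy()
    pi_b = pi0.copy()
    A_a = A0.copy()
    A_b = A0.copy()
    B = B0.copy()
    history = []
    prev = -np.inf
    converged = False
    state = {}
    for _ in range(max_iter):
        ll_a, pn_a, xi_a, gn_a, occ_a = estep(da._obs, da._starts, pi_a, A_a, B)
        ll_b, pn_b, xi_b, gn_b, occ_b = estep(db._obs, db._starts, pi_b, A_b, B)
        ll = ll_a + ll_b
        history.append(ll)
        state = dict(pi_a=pi_a, A_a=A_a, pi_b=pi_b, A_b=A_b, B=B,
                     occ_a=occ_a, occ_b=occ_b, ll_a=ll_a, ll_b=ll_b)
        if ll - prev < tol_total and len(history) > 1:
            converged = True
            break
        prev = ll
        pi_a = pn_a / pn_a.sum()
        pi_b = pn_b / pn_b.sum()
        A_a = _normalize_rows(xi_a, A_a)
        A_b = _normalize_rows(xi_b, A_b)
        B = _normalize_rows(gn_a + gn_b, B)
    state["history"] = history
    state["converged"] = converged
    return state


def _normalize_rows(num, fallback):
    rows = num.sum(axis=1)
    out = fallback.copy()
    nz = rows > 0
    out[nz] = num[nz] / rows[nz, None]
    return out


def viterbi_decode(model: FretModel, colors, ticks=None,
                   tick: float = DEFAULT_TICK,
                   tick_resolved: bool = False,
                   time_step: float | None = None) -> ViterbiSegmentation:
    """Most-probable state path per burst (max-product, log arithmetic).

    Ties break toward the lower state index.  Without tick times, photon
    indices stand in for times (tick = 1).  With ``tick_resolved`` the
    transition matrix is propagated through every elementary clock tick
    between photons; with ``time_step`` through steps of that length — in
    either case a cached matrix power serves as the per-gap propagator.
    """
    model.validate()
    colors = [np.asarray(c, dtype=np.int8) for c in colors]
    if ticks is None:
        ticks = [np.arange(len(c), dtype=np.int64) for c in colors]
        tick = 1.0
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.prior)
        log_B = np.log(model.observation)
    paths = []
    logps = []
    if tick_resolved or time_step is not None:
        cache = {}
        for c, t in zip(colors, ticks):
            if time_step is not None:
                steps = _gap_steps(t, tick, time_step)
            else:
                steps = np.maximum(np.diff(t), 1)
            p, lp = _propagator_viterbi(c, steps, model, cache)
            paths.append(p)
            logps.append(lp)
    else:
        with np.errstate(divide="ignore"):
            log_A = np.log(model.transition)
        obs, starts = pack_sequences(colors)
        flat, lp = viterbi_paths(obs, starts, log_pi, log_A, log_B)
        paths = [flat[starts[b]:starts[b + 1]] for b in range(len(colors))]
        logps = list(lp)
    return ViterbiSegmentation(paths=paths, ticks=list(ticks), tick=tick,
                               logprobs=np.asarray(logps),
                               n_states=model.n_states)


def _propagator_viterbi(colors, steps, model: FretModel, cache: dict):
    """Viterbi with per-gap propagators A^steps[t]; ``cache`` maps k -> log A^k."""
    n = model.n_states
    T = len(colors)
    if T == 0:
        return np.zeros(0, dtype=np.int64), 0.0
    with np.errstate(divide="ignore"):
        log_B = np.log(model.observation)
        delta = np.log(model.prior) + log_B[:, colors[0]]
    psi = np.zeros((T, n), dtype=np.int64)
    for t in range(1, T):
        dk = int(steps[t - 1])
        log_P = cache.get(dk)
        if log_P is None:
            with np.errstate(divide="ignore"):
                log_P = np.log(np.linalg.matrix_power(model.transition, dk))
            cache[dk] = log_P
        cand = delta[:, None] + log_P
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(n)] + log_B[:, colors[t]]
    path = np.zeros(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(np.max(delta))
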