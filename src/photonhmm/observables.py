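"""Derived equilibrium, energetic and spectroscopic quantities.

From a fitted photon-by-photon HMM: Boltzmann-inverted free-energy profiles
V(E) = -kT ln p(E) along the FRET coordinate with Arrhenius barrier heights;
the equilibrium coefficient K12 (population ratio of the low-FRET to the
high-FRET state) per condition and the substrate-response factor R (ratio of
K12 with and without substrate) with burst-bootstrap uncertainties; FRET-to-
distance conversion through the Förster equation; activity-response
correlations across variants; per-burst donor-acceptor fluorescence
cross-correlation curves; and time-resolved anisotropy decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SpectroscopyConstants",
    "FreeEnergyProfile",
    "free_energy_profile",
    "barrier_height",
    "EquilibriumSummary",
    "equilibrium_and_response",
    "activity_correlation",
    "fret_distance",
    "CorrelationCurve",
    "burst_fccs",
    "fit_fccs_relaxation",
    "AnisotropyDecay",
    "anisotropy",
]


@dataclass
class SpectroscopyConstants:
    """Instrument/dye constants used for derived quantities.

    forster_radius : Förster distance R0 in Å (54 Å for this dye pair);
    arrhenius_prefactor : attempt frequency A0 in s^-1 for barrier heights;
    g_factor : polarization sensitivity factor; temperature in K (display).
    """

    forster_radius: float = 54.0
    arrhenius_prefactor: float = 1e5
    g_factor: float = 1.0
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if min(self.forster_radius, self.arrhenius_prefactor,
               self.g_factor, self.temperature) <= 0:
            raise ValueError("spectroscopy constants must be positive")


# ------------------------------------------------------------ free energy
@dataclass
class FreeEnergyProfile:
    """Free energies V_k = -ln p_k (units of kT, minimum shifted to zero)."""

    state_fret: np.ndarray
    occupancies: np.ndarray
    v_kt: np.ndarray

    def local_minima(self, min_occupancy: float = 0.01) -> np.ndarray:
        """Indices of local minima of V along the grid.

        Only states holding at least ``min_occupancy`` of the population
        qualify — a potential well with essentially no occupants is
        statistical noise on the (near-infinite) rim of the profile, not a
        well.
        """
        v = self.v_kt
        idx = []
        for i in range(len(v)):
            if self.occupancies[i] < min_occupancy:
                continue
            left = v[i - 1] if i > 0 else np.inf
            right = v[i + 1] if i < len(v) - 1 else np.inf
            if v[i] < left and v[i] < right:
                idx.append(i)
        return np.asarray(idx, dtype=int)

    def plot(self, ax=None, **kw):
        """Line plot of V(E) in kT with wells marked."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ok = np.isfinite(self.v_kt)
        ax.plot(self.state_fret[ok], self.v_kt[ok], "-o", **kw)
        for i in self.local_minima():
            ax.axvline(self.state_fret[i], ls=":", color="0.7")
        ax.set_xlabel("FRET efficiency")
        ax.set_ylabel(r"V(E)  [$k_\mathrm{B}T$]")
        return ax


def free_energy_profile(state_fret, occupancies,
                        constants: SpectroscopyConstants | None = None
                        ) -> FreeEnergyProfile:
    """Boltzmann inversion of state occupancies along the FRET coordinate.

    ``V_k = -ln p_k`` in kT units, shifted so the deepest well sits at zero;
    zero-occupancy states get ``V = +inf``.
    """
    p = np.asarray(occupancies, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("occupancies must sum to 1")
    p = p / p.sum()
    with np.errstate(divide="ignore"):
        v = -np.log(p)
    v = v - v.min()
    return FreeEnergyProfile(
        state_fret=np.asarray(state_fret, dtype=float), occupancies=p, v_kt=v
    )


def barrier_height(rate: float,
                   constants: SpectroscopyConstants | None = None) -> float:
    """Arrhenius barrier dG = ln(A0 / k) in kT; NaN where k >= A0."""
    constants = constants or SpectroscopyConstants()
    if rate <= 0:
        raise ValueError("rate must be positive")
    if rate >= constants.arrhenius_prefactor:
        return np.nan
    return float(np.log(constants.arrhenius_prefactor / rate))


# ------------------------------------------------------------- equilibrium
@dataclass
class EquilibriumSummary:
    """Two-state populations, K12 coefficients and the response factor R.

    State 1 is the lower-FRET state by convention, so K12 = p1/p2 grows when
    substrate shifts the population toward low FRET.  Uncertainties are
    burst-bootstrap percentile intervals.
    """

    p1: np.ndarray  # (without, with) substrate
    p2: np.ndarray
    k12: np.ndarray
    k12_ci: np.ndarray  # (2, 2): rows conditions, cols lo/hi
    response_factor: float
    response_ci: tuple
    labels: tuple = ("no substrate", "with substrate")
    index_convention: str = "state 1 = lower-FRET state; K12 = p1/p2"

    def summary(self) -> str:
        lines = [
            "Equilibrium coefficients (K12 = p(low-E)/p(high-E))",
            "-" * 58,
        ]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab:>14}: p1={self.p1[i]:.4f} p2={self.p2[i]:.4f} "
                f"K12={self.k12[i]:.4f} "
                f"[{self.k12_ci[i, 0]:.4f}, {self.k12_ci[i, 1]:.4f}]"
            )
        lines.append(
            f"response factor R = {self.response_factor:.4f} "
            f"[{self.response_ci[0]:.4f}, {self.response_ci[1]:.4f}]"
        )
        return "\n".join(lines)


def equilibrium_and_response(fit_without, fit_with, n_boot: int = 200,
                             seed=None) -> EquilibriumSummary:
    """K12 per condition and the substrate-response factor R.

    Populations are the posterior-expected photon-occupancy fractions of the
    two states (results are already sorted by ascending FRET efficiency).
    R = K12(with substrate) / K12(without).  Bootstrap resamples bursts
    independently within each condition.
    """
    for f in (fit_without, fit_with):
        if f.n_states != 2:
            raise ValueError("equilibrium summary requires two-state fits")
    rng = np.random.default_rng(seed)
    p = np.array([fit_without.occupancies, fit_with.occupancies])
    if np.any(p[:, 1] == 0):
        raise ValueError("higher-FRET state has zero population")
    k12 = p[:, 0] / p[:, 1]
    boot_occ = [
        f.bootstrap_occupancy(n_boot=n_boot, seed=rng.integers(2**31))
        for f in (fit_without, fit_with)
    ]
    boot_k12 = np.column_stack([bo[:, 0] / bo[:, 1] for bo in boot_occ])
    ci = np.percentile(boot_k12, [2.5, 97.5], axis=0).T
    boot_r = boot_k12[:, 1] / boot_k12[:, 0]
    r_ci = tuple(np.percentile(boot_r, [2.5, 97.5]))
    return EquilibriumSummary(
        p1=p[:, 0], p2=p[:, 1], k12=k12, k12_ci=ci,
        response_factor=float(k12[1] / k12[0]), response_ci=r_ci,
    )


def activity_correlation(activity, response):
    """OLS of biochemical activity against substrate-response factors.

    Returns ``(slope, intercept, r_squared)``; R^2 is the squared Pearson
    correlation.  Requires at least 3 paired points; zero variance in either
    variable yields NaN R^2.
    """
    x = np.asarray(activity, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------- distance
def fret_distance(e_values, constants: SpectroscopyConstants | None = None):
    """Donor-acceptor distances from FRET efficiencies: r = R0 (1/E - 1)^(1/6).

    E at 0 or 1 maps to inf / 0 and is returned as NaN.  Scalar in, scalar
    out.
    """
    constants = constants or SpectroscopyConstants()
    e = np.asarray(e_values, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    r = np.full(e.shape, np.nan)
    ok = (e > 0) & (e < 1)
    r[ok] = constants.forster_radius * (1.0 / e[ok] - 1.0) ** (1.0 / 6.0)
    return float(r[0]) if scalar else r


def motion_amplitude(e_low: float, e_high: float,
                     constants: SpectroscopyConstants | None = None) -> float:
    """Distance change |r(E_low) - r(E_high)| between the two states, Å."""
    r = fret_distance(np.array([e_low, e_high]), constants)
    return float(abs(r[0] - r[1]))


__all__.append("motion_amplitude")


# --------------------------------------------------------------------- FCS
@dataclass
class CorrelationCurve:
    """Burst-averaged donor-acceptor cross-correlation g_DA(tau)."""

    lag_edges: np.ndarray
    g: np.ndarray
    n_pairs: np.ndarray
    n_bursts: int

    @property
    def lag_centers(self) -> np.ndarray:
        return np.sqrt(self.lag_edges[:-1] * self.lag_edges[1:])


def burst_fccs(donor_times, acceptor_times, durations, lag_min: float = 1e-6,
               lag_max: float | None = None, n_lags: int = 16
               ) -> CorrelationCurve:
    """Per-burst donor-acceptor cross-correlation, averaged over bursts.

    For each burst of duration T the pair-count estimator on a geometric lag
    grid is ``g(tau) = N_pairs(|t_A - t_D| in bin) / E_indep`` with the
    independence expectation ``E_indep = N_D N_A (2 dtau / T)(1 - tau/T)``
    (edge-corrected).  Bursts are combined as the ratio of summed pair
    counts to summed expectations — equivalent to an N_D*N_A-weighted
    average — and the curve is normalized to 1 at the largest lags.
    Bursts without photons of both colors are skipped.

    Parameters are per-burst lists: donor/acceptor arrival times in seconds
    (relative to anywhere) and burst durations in seconds.
    """
    if lag_max is None:
        lag_max = 0.5 * float(np.mean([d for d in durations if d > 0]))
    edges = np.geomspace(lag_min, lag_max, n_lags + 1)
    pair_counts = np.zeros(n_lags)
    expected = np.zeros(n_lags)
    nb = 0
    centers = np.sqrt(edges[:-1] * edges[1:])
    for td, ta, T in zip(donor_times, acceptor_times, durations):
        td = np.asarray(td, dtype=float)
        ta = np.asarray(ta, dtype=float)
        if len(td) == 0 or len(ta) == 0 or T <= 0:
            continue
        nb += 1
        dt = np.abs(ta[None, :] - td[:, None]).ravel()
        pair_counts += np.histogram(dt, bins=edges)[0]
        widths = np.diff(edges)
        edge = np.clip(1.0 - centers / T, 0.0, None)
        expected += len(td) * len(ta) * (2.0 * widths / T) * edge
    if nb == 0:
        raise ValueError("no burst has photons of both colors")
    with np.errstate(invalid="ignore", divide="ignore"):
        g = pair_counts / expected
    # normalize so g -> 1 at the largest lags (mean of the top quartile)
    tail = g[-max(n_lags // 4, 1):]
    tail = tail[np.isfinite(tail)]
    if len(tail) and np.mean(tail) > 0:
        g = g / np.mean(tail)
    return CorrelationCurve(lag_edges=edges, g=g, n_pairs=pair_counts,
                            n_bursts=nb)


def fit_fccs_relaxation(curve: CorrelationCurve):
    """Fit g(tau) = g_inf - a exp(-tau/tau_c); returns (tau_c, a, g_inf).

    A rising donor-acceptor cross-correlation (a > 0) is the signature of
    anticorrelated two-state FRET dynamics with relaxation time
    1/(k12 + k21).
    """
    x = curve.lag_centers
    y = curve.g
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]

    def f(t, tau, a, ginf):
        return ginf - a * np.exp(-t / tau)

    p0 = (x[len(x) // 2], max(1.0 - y[0], 1e-3), 1.0)
    popt, _ = optimize.curve_fit(
        f, x, y, p0=p0, bounds=([x[0] / 10, -1.0, 0.5], [x[-1] * 10, 1.0, 1.5]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


# --------------------------------------------------------------- anisotropy
@dataclass
class AnisotropyDecay:
    """Time-resolved anisotropy r(t) and its steady-state value."""

    time: np.ndarray
    i_par: np.ndarray
    i_perp: np.ndarray
    r: np.ndarray
    r_steady: float


def anisotropy(time, i_par, i_perp,
               constants: SpectroscopyConstants | None = None
               ) -> AnisotropyDecay:
    """Anisotropy decay r(t) = (I_par - G I_perp)/(I_par + 2 G I_perp).

    Inputs are background-corrected parallel/perpendicular decays on a
    common time binning; bins with zero total intensity give NaN.  The
    steady-state value uses the summed intensities.
    """
    constants = constants or SpectroscopyConstants()
    g = constants.g_factor
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + 2.0 * g * i_perp
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (i_par - g * i_perp) / denom, np.nan)
    tot = i_par.sum() + 2.0 * g * i_perp.sum()
    r_ss = (i_par.sum() - g * i_perp.sum()) / tot if tot > 0 else np.nan
    return AnisotropyDecay(time=np.asarray(time, dtype=float), i_par=i_par,
                           i_perp=i_perp, r=r, r_steady=float(r_ss))
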