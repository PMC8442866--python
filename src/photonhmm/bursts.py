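"""Burst detection, FRET/stoichiometry computation, corrections and selection.

Implements the standard diffusion-smFRET burst pipeline for pulsed
interleaved excitation (PIE) data: photon bursts are maximal runs of photons
whose consecutive inter-photon gaps all stay below a cutoff time (5 µs) and
that contain at least 30 photons.  Raw FRET efficiency E and stoichiometry S
per burst locate each molecule in the E-S plane; the donor-only population
(S near 1) calibrates spectral leakage, the acceptor-only population (S near
0) calibrates direct acceptor excitation, and only bursts whose corrected
stoichiometry falls in the double-label window are kept for kinetic
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photons import ACCEPTOR, AEX, DEX, DONOR, PhotonStream

__all__ = [
    "CorrectionSet",
    "detect_bursts",
    "compute_raw_es",
    "estimate_corrections",
    "correct_and_select",
    "burst_variance_analysis",
    "burst_color_sequences",
    "write_burst_table",
]

#: burst-search defaults: 5 us gap cutoff, 30-photon minimum
DEFAULT_CUTOFF = 5e-6
DEFAULT_MIN_PHOTONS = 30


@dataclass
class CorrectionSet:
    """Spectral corrections for PIE burst data.

    ``leakage`` is the donor-to-acceptor crosstalk coefficient expressed as a
    fraction of donor-channel counts; ``direct_excitation`` the direct
    acceptor excitation expressed as a fraction of acceptor-excitation-period
    counts; ``gamma`` the donor/acceptor detection-efficiency ratio.
    """

    leakage: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0
    background_rates: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 <= self.leakage < 1 and 0 <= self.direct_excitation < 1):
            raise ValueError("leakage and direct_excitation must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def detect_bursts(
    stream: PhotonStream,
    cutoff: float = DEFAULT_CUTOFF,
    min_photons: int = DEFAULT_MIN_PHOTONS,
) -> pd.DataFrame:
    """Find photon bursts as maximal runs of sub-cutoff inter-photon gaps.

    A burst is a maximal run of consecutive photons in which every
    inter-photon gap is strictly below ``cutoff`` seconds; runs with fewer
    than ``min_photons`` photons are discarded.  Bursts are returned ordered
    and non-overlapping with per-channel photon counts and raw E/S values.

    Returns a DataFrame with one row per burst: photon index range
    ``[start, stop)``, ``start_tick``, ``duration_s``, the four PIE counts
    ``n_dex_d``, ``n_dex_a``, ``n_aex_d``, ``n_aex_a``, and ``e_raw``,
    ``s_raw`` (NaN where undefined), ``defined`` flag.
    """
    n = len(stream)
    if n == 0:
        return _empty_table()
    gaps = np.diff(stream.ticks)
    if np.any(gaps < 0):
        raise ValueError("photon stream must be time-sorted")
    # exact integer comparison in tick units: a gap is "short" iff it is
    # strictly below the cutoff
    cutoff_ticks = int(np.ceil(cutoff / stream.tick))
    breaks = np.flatnonzero(gaps >= cutoff_ticks)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [n]))
    keep = (stops - starts) >= min_photons
    starts, stops = starts[keep], stops[keep]
    rows = []
    for i0, i1 in zip(starts, stops):
        rows.append(_burst_row(stream, int(i0), int(i1)))
    if not rows:
        return _empty_table()
    return pd.DataFrame(rows).reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    cols = [
        "start", "stop", "start_tick", "duration_s",
        "n_dex_d", "n_dex_a", "n_aex_d", "n_aex_a",
        "e_raw", "s_raw", "defined",
    ]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


def _burst_row(stream: PhotonStream, i0: int, i1: int) -> dict:
    ch = stream.channel[i0:i1]
    ex = stream.excitation[i0:i1]
    n_dex_d = int(np.sum((ch == DONOR) & (ex == DEX)))
    n_dex_a = int(np.sum((ch == ACCEPTOR) & (ex == DEX)))
    n_aex_d = int(np.sum((ch == DONOR) & (ex == AEX)))
    n_aex_a = int(np.sum((ch == ACCEPTOR) & (ex == AEX)))
    e, s, ok = compute_raw_es(n_dex_d, n_dex_a, n_aex_d, n_aex_a)
    return {
        "start": i0,
        "stop": i1,
        "start_tick": int(stream.ticks[i0]),
        "duration_s": float((stream.ticks[i1 - 1] - stream.ticks[i0]) * stream.tick),
        "n_dex_d": n_dex_d,
        "n_dex_a": n_dex_a,
        "n_aex_d": n_aex_d,
        "n_aex_a": n_aex_a,
        "e_raw": e,
        "s_raw": s,
        "defined": ok,
    }


def compute_raw_es(n_dex_d, n_dex_a, n_aex_d, n_aex_a):
    """Raw FRET efficiency and stoichiometry from the four PIE photon counts.

    E_raw uses donor-excitation photons only; S_raw is the fraction of all
    photons that came from donor-excitation periods.  Returns
    ``(e_raw, s_raw, defined)``; a zero denominator yields NaN and
    ``defined=False`` (such bursts are excluded downstream).
    """
    dex = n_dex_d + n_dex_a
    tot = dex + n_aex_d + n_aex_a
    e = n_dex_a / dex if dex > 0 else np.nan
    s = dex / tot if tot > 0 else np.nan
    return e, s, bool(dex > 0 and tot > 0)


def estimate_corrections(
    bursts: pd.DataFrame,
    donor_only_s_min: float = 0.9,
    acceptor_only_s_max: float = 0.2,
    gamma: float = 1.0,
) -> CorrectionSet:
    """Calibrate leakage and direct excitation from the single-label populations.

    Donor-only bursts (S_raw above ``donor_only_s_min``) have no acceptor, so
    their mean raw E is pure leakage: l = <E>_DO / (1 - <E>_DO), the
    crosstalk per donor-channel count.  Acceptor-only bursts (S_raw below
    ``acceptor_only_s_max``) have no donor, so their mean raw S reflects
    direct excitation only: d = <S>_AO / (1 - <S>_AO).
    """
    ok = bursts[bursts["defined"].astype(bool)]
    do = ok[ok["s_raw"] > donor_only_s_min]
    ao = ok[ok["s_raw"] < acceptor_only_s_max]
    if len(do) == 0:
        raise ValueError(
            "no donor-only bursts found; supply manual correction values"
        )
    if len(ao) == 0:
        raise ValueError(
            "no acceptor-only bursts found; supply manual correction values"
        )
    e_do = float(do["e_raw"].mean())
    s_ao = float(ao["s_raw"].mean())
    return CorrectionSet(
        leakage=e_do / (1.0 - e_do),
        direct_excitation=s_ao / (1.0 - s_ao),
        gamma=gamma,
    )


def correct_and_select(
    bursts: pd.DataFrame,
    corrections: CorrectionSet,
    s_window=(0.3, 0.8),
) -> pd.DataFrame:
    """Apply spectral corrections and keep double-labeled bursts.

    The corrected acceptor signal after donor excitation is
    ``F = n_dex_a - l*n_dex_d - d*n_aex_a``; corrected E and S follow with
    the gamma factor weighting the donor counts.  Bursts are selected iff
    their corrected stoichiometry falls inside ``s_window``; corrected E is
    clipped to [0, 1] with a ``clipped`` flag.
    """
    lo, hi = s_window
    if lo >= hi:
        raise ValueError("stoichiometry window is inverted")
    l, d, g = corrections.leakage, corrections.direct_excitation, corrections.gamma
    out = bursts.copy()
    f_a = out["n_dex_a"] - l * out["n_dex_d"] - d * out["n_aex_a"]
    dex = f_a + g * out["n_dex_d"]
    tot = dex + out["n_aex_d"] + out["n_aex_a"]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = f_a / dex
        s = dex / tot
    out["e_corr"] = e.clip(0.0, 1.0)
    out["clipped"] = (e < 0) | (e > 1)
    out["s_corr"] = s
    out["selected"] = (
        out["defined"].astype(bool) & (s >= lo) & (s <= hi) & np.isfinite(e)
    )
    return out


def burst_variance_analysis(
    stream: PhotonStream, bursts: pd.DataFrame, window: int = 5
) -> pd.DataFrame:
    """Shot-noise test for within-burst FRET dynamics.

    Each burst's donor-excitation photons are split into consecutive windows
    of ``window`` photons; the standard deviation of the per-window acceptor
    fraction is compared with the binomial shot-noise expectation
    sqrt(E(1-E)/window).  A static molecule shows sigma at the shot-noise
    level; conformational dynamics inflate it.  Bursts with fewer than two
    full windows are skipped.
    """
    rows = []
    for bid, b in bursts.iterrows():
        i0, i1 = int(b["start"]), int(b["stop"])
        dex = stream.excitation[i0:i1] == DEX
        colors = (stream.channel[i0:i1][dex] == ACCEPTOR).astype(float)
        n_win = len(colors) // window
        if n_win < 2:
            continue
        frac = colors[: n_win * window].reshape(n_win, window).mean(axis=1)
        e_mean = float(colors.mean())
        rows.append(
            {
                "burst_id": bid,
                "e_mean": e_mean,
                "sigma_obs": float(frac.std(ddof=0)),
                "sigma_shot": float(np.sqrt(e_mean * (1 - e_mean) / window)),
                "n_windows": n_win,
            }
        )
    return pd.DataFrame(rows)


def burst_color_sequences(stream: PhotonStream, bursts: pd.DataFrame,
                          selected_only: bool = True):
    """Extract per-burst donor-excitation photon colors and arrival ticks.

    Returns ``(colors, ticks)``: lists of int8 arrays (0 donor, 1 acceptor)
    and int64 tick arrays, one pair per burst — the observation sequences the
    photon-by-photon HMM operates on.
    """
    if selected_only and "selected" in bursts:
        bursts = bursts[bursts["selected"].astype(bool)]
    colors, ticks = [], []
    for _, b in bursts.iterrows():
        i0, i1 = int(b["start"]), int(b["stop"])
        dex = stream.excitation[i0:i1] == DEX
        colors.append((stream.channel[i0:i1][dex] == ACCEPTOR).astype(np.int8))
        ticks.append(stream.ticks[i0:i1][dex])
    return colors, ticks


def write_burst_table(bursts: pd.DataFrame, path) -> None:
    bursts.to_csv(path, sep="\t", index_label="burst_id")
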