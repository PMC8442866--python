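"""Model-validation procedures for photon-by-photon HMM fits.

Three checks establish that a fitted model actually explains the photon
record: (i) Monte-Carlo *recoloring* — photon arrival times are kept fixed,
their colors erased and redrawn from the fitted model, and the recolored
per-burst FRET histogram is compared with the original (two-sample
Kolmogorov-Smirnov); (ii) *segmentation histograms* — Viterbi segments are
histogrammed by assigned state, which must separate the states'
FRET-efficiency distributions; (iii) *dwell-time analysis* — uncensored
Viterbi dwell durations must follow the single-exponential law implied by
the fitted transition rates.  A fourth, HMM-free cross-check splits the
burst FRET histogram at the intersection of the two state histograms and
uses the areas on either side as a model-independent population ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import FretModel, ViterbiSegmentation

__all__ = [
    "recolor_sequences",
    "recolor",
    "RecoloringReport",
    "segmentation_histograms",
    "SegmentHistograms",
    "dwell_time_analysis",
    "DwellTable",
    "split_point_k12",
]


# ------------------------------------------------------------------ recolor
def recolor_sequences(colors, model: FretModel, seed=None):
    """Redraw photon colors from ``model`` along each burst's photon grid.

    For every burst a fresh state sequence is simulated from the prior and
    the per-photon transition matrix; each photon's color is then drawn from
    the occupied state's emission row.  Photon counts and positions are
    untouched — only colors change.
    """
    rng = np.random.default_rng(seed)
    n = model.n_states
    out = []
    cum_A = np.cumsum(model.transition, axis=1)
    cum_pi = np.cumsum(model.prior)
    for c in colors:
        T = len(c)
        if T == 0:
            out.append(np.zeros(0, dtype=np.int8))
            continue
        u = rng.random(T)
        z = np.empty(T, dtype=np.int64)
        z[0] = np.searchsorted(cum_pi, u[0])
        for t in range(1, T):
            z[t] = np.searchsorted(cum_A[z[t - 1]], u[t])
        z = np.clip(z, 0, n - 1)
        e = model.observation[z, 1]
        out.append((rng.random(T) < e).astype(np.int8))
    return out


@dataclass
class RecoloringReport:
    """Original vs recolored per-burst FRET efficiencies with a KS comparison."""

    e_original: np.ndarray
    e_recolored: np.ndarray
    ks_statistic: float
    p_value: float
    hist_original: np.ndarray
    hist_recolored: np.ndarray
    bin_edges: np.ndarray

    def passes(self, alpha: float = 0.01) -> bool:
        """Histograms indistinguishable at level ``alpha``."""
        return self.p_value > alpha


def recolor(colors, model: FretModel, seed=None, bins: int = 40) -> RecoloringReport:
    """Recolor bursts under ``model`` and compare per-burst E distributions."""
    rec = recolor_sequences(colors, model, seed=seed)
    e_orig = np.array([c.mean() for c in colors if len(c)])
    e_rec = np.array([c.mean() for c in rec if len(c)])
    ks = stats.ks_2samp(e_orig, e_rec)
    edges = np.linspace(0.0, 1.0, bins + 1)
    return RecoloringReport(
        e_original=e_orig,
        e_recolored=e_rec,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        hist_original=np.histogram(e_orig, bins=edges)[0],
        hist_recolored=np.histogram(e_rec, bins=edges)[0],
        bin_edges=edges,
    )


# ------------------------------------------------------- segment histograms
@dataclass
class SegmentHistograms:
    """Per-state segment-E histograms (two-state fits) and their crossing."""

    bin_edges: np.ndarray
    hist_state1: np.ndarray  # density, lower-E state
    hist_state2: np.ndarray
    segment_e: tuple
    intersection: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def segmentation_histograms(seg: ViterbiSegmentation, colors,
                            min_photons_per_segment: int = 5,
                            bins: int = 40) -> SegmentHistograms:
    """Histogram Viterbi segments' FRET efficiencies by assigned state.

    Each segment with at least ``min_photons_per_segment`` photons
    contributes its acceptor fraction to the histogram of its state.  The
    intersection point is the abscissa where the two normalized histograms
    cross between their modes (linear interpolation); it serves as the
    model-independent splitting point for :func:`split_point_k12`.
    """
    if seg.n_states != 2:
        raise ValueError("segmentation histograms require a two-state model")
    seg_e = ([], [])
    for _, row in seg.segments.iterrows():
        if row["n_photons"] < min_photons_per_segment:
            continue
        c = colors[int(row["burst_id"])]
        frac = float(np.mean(c[int(row["first"]):int(row["last"]) + 1]))
        seg_e[int(row["state"])].append(frac)
    if not seg_e[0] or not seg_e[1]:
        raise ValueError("a state has no qualifying segments")
    edges = np.linspace(0.0, 1.0, bins + 1)
    h1 = np.histogram(seg_e[0], bins=edges, density=True)[0]
    h2 = np.histogram(seg_e[1], bins=edges, density=True)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    inter = _histogram_intersection(centers, h1, h2)
    return SegmentHistograms(
        bin_edges=edges, hist_state1=h1, hist_state2=h2,
        segment_e=(np.asarray(seg_e[0]), np.asarray(seg_e[1])),
        intersection=inter,
    )


def _histogram_intersection(x, h1, h2) -> float:
    """Crossing abscissa of two histograms between their modes.

    A strict sign change is linearly interpolated; a stretch where both
    histograms vanish (fully separated states) yields the midpoint of the
    empty region.
    """
    m1, m2 = int(np.argmax(h1)), int(np.argmax(h2))
    lo, hi = sorted((m1, m2))
    d = h1 - h2
    i = lo
    while i < hi:
        if d[i] > 0 and d[i + 1] < 0:
            return float(x[i] + (x[i + 1] - x[i]) * d[i] / (d[i] - d[i + 1]))
        if d[i] > 0 and d[i + 1] == 0.0:
            j = i + 1
            while j <= hi and d[j] == 0.0:
                j += 1
            if j > hi or d[j] < 0:
                return float(0.5 * (x[i + 1] + x[min(j, hi) - 1])) \
                    if j - 1 > i + 1 else float(x[i + 1])
        i += 1
    return float(0.5 * (x[m1] + x[m2]))  # no crossing found: midpoint


# ------------------------------------------------------------- dwell times
@dataclass
class DwellTable:
    """Uncensored dwell durations per state with exponential-rate fits.

    ``rates`` holds the maximum-likelihood exponential rate (1 / mean dwell)
    per state, NaN where fewer than ``min_dwells`` uncensored dwells exist;
    ``rate_ci`` the bootstrap confidence interval (2.5/97.5 percentiles).
    """

    dwells: list
    rates: np.ndarray
    rate_ci: np.ndarray
    n_censored: np.ndarray

    def survival(self, state: int):
        """Integrated (complementary cumulative) dwell distribution."""
        d = np.sort(self.dwells[state])
        surv = 1.0 - np.arange(1, len(d) + 1) / len(d)
        return d, surv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": np.arange(len(self.dwells)),
                "n_dwells": [len(d) for d in self.dwells],
                "n_censored": self.n_censored,
                "rate_per_s": self.rates,
                "rate_lo": self.rate_ci[:, 0],
                "rate_hi": self.rate_ci[:, 1],
            }
        )


def dwell_time_analysis(seg: ViterbiSegmentation, min_dwells: int = 10,
                        n_boot: int = 200, seed=None) -> DwellTable:
    """Exponential dwell-time fits from a Viterbi segmentation.

    A dwell is the time from a segment's first photon to the next segment's
    first photon; each burst's first and last segments are censored (entry
    and exit times unobserved) and excluded from the fit.  The exponential
    MLE is 1/mean; uncertainty by bootstrap over dwells.
    """
    rng = np.random.default_rng(seed)
    n = seg.n_states
    segs = seg.segments
    dwells = []
    n_cens = np.zeros(n, dtype=int)
    for s in range(n):
        sel = segs["state"] == s
        cens = segs["censored_start"] | segs["censored_end"]
        d = segs.loc[sel & ~cens, "duration_s"].to_numpy(dtype=float)
        d = d[d > 0]
        dwells.append(d)
        n_cens[s] = int((sel & cens).sum())
    rates = np.full(n, np.nan)
    ci = np.full((n, 2), np.nan)
    for s in range(n):
        d = dwells[s]
        if len(d) < min_dwells:
            continue
        rates[s] = 1.0 / d.mean()
        boot = 1.0 / d[rng.integers(0, len(d), size=(n_boot, len(d)))].mean(axis=1)
        ci[s] = np.percentile(boot, [2.5, 97.5])
    return DwellTable(dwells=dwells, rates=rates, rate_ci=ci, n_censored=n_cens)


# -------------------------------------------------------- split-point K12
def split_point_k12(burst_e_values, split: float):
    """HMM-free population ratio from a FRET-histogram splitting point.

    Counts bursts with mean E below/above ``split`` and returns
    ``(area_low, area_high, k12)`` with ``k12 = area_low / area_high``; an
    empty side yields inf/0 (flagged by the caller through the value
    itself).
    """
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    e = np.asarray(burst_e_values, dtype=float)
    n_low = int(np.sum(e < split))
    n_high = int(np.sum(e >= split))
    if n_high == 0:
        return n_low, 0, np.inf
    return n_low, n_high, n_low / n_high
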