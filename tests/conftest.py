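import numpy as np
import pytest

import photonhmm as ph


@pytest.fixture(scope="session")
def bench_small():
    """500-burst two-state benchmark dataset with a fitted two-state model."""
    cfg = ph.benchmark_config(n_bursts=500, seed=7)
    stream, truth = ph.generate_dataset(cfg)
    colors, ticks = ph.truth_burst_sequences(stream, truth)
    fit = ph.em_fit(colors, 2, restarts=2, tol_per_photon=1e-8, max_iter=600,
                    seed=3, ticks=ticks, tick=stream.tick)
    return {
        "cfg": cfg,
        "stream": stream,
        "truth": truth,
        "colors": colors,
        "ticks": ticks,
        "fit": fit,
    }


@pytest.fixture(scope="session")
def benchmark_sweep():
    """Twenty seeded replicates of the full two-state recovery benchmark.

    Each replicate simulates 5,000 one-millisecond bursts (E = 0.45/0.75,
    k12 = k21 = 2e4 s^-1, 2e5 photons/s), fits a free two-state model, and
    records the recovered efficiencies, per-photon transition probabilities,
    rate conversions and Viterbi dwell rates.
    """
    rows = []
    for i in range(20):
        cfg = ph.benchmark_config(n_bursts=5000, seed=100 + i)
        stream, truth = ph.generate_dataset(cfg)
        colors, ticks = ph.truth_burst_sequences(stream, truth)
        fit = ph.em_fit(colors, 2, restarts=2, tol_per_photon=1e-8,
                        max_iter=600, seed=200 + i, ticks=ticks,
                        tick=stream.tick)
        mean_dt = ph.PhotonHMM(colors, ticks, stream.tick).mean_interphoton_time
        dwell = ph.dwell_time_analysis(fit.viterbi(), seed=i)
        A = fit.transition_matrix
        rows.append(
            {
                "state_fret": fit.state_fret.copy(),
                "a_off": np.array([A[0, 1], A[1, 0]]),
                "mean_dt": mean_dt,
                "h2mm_rates": np.array([A[0, 1], A[1, 0]]) / mean_dt,
                "dwell_rates": dwell.rates.copy(),
                "ll_history": fit.ll_history.copy(),
                "model": fit.params,
            }
        )
    return rows
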