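"""Free energies, equilibrium coefficients, distances, FCS, anisotropy."""

import numpy as np
import pytest

import photonhmm as ph
from photonhmm.observables import (
    SpectroscopyConstants,
    activity_correlation,
    anisotropy,
    barrier_height,
    burst_fccs,
    equilibrium_and_response,
    fit_fccs_relaxation,
    free_energy_profile,
    fret_distance,
    motion_amplitude,
)


class TestFreeEnergy:
    def test_equal_populations_flat(self):
        prof = free_energy_profile([0.4, 0.6], [0.5, 0.5])
        np.testing.assert_allclose(prof.v_kt, [0.0, 0.0], atol=1e-12)

    def test_population_ratio_sets_well_depth(self):
        prof = free_energy_profile([0.4, 0.6], [0.25, 0.75])
        assert prof.v_kt[0] - prof.v_kt[1] == pytest.approx(np.log(3))

    def test_zero_occupancy_infinite(self):
        prof = free_energy_profile([0.2, 0.5, 0.8], [0.5, 0.5, 0.0])
        assert np.isinf(prof.v_kt[2])

    def test_boltzmann_roundtrip(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        prof = free_energy_profile([0.1, 0.3, 0.5, 0.7], p)
        back = np.exp(-prof.v_kt)
        np.testing.assert_allclose(back / back.sum(), p, atol=1e-12)

    def test_arrhenius_barrier(self):
        # k = 1e4 s^-1 with A0 = 1e5 s^-1 -> ln 10 kT
        assert barrier_height(1e4) == pytest.approx(np.log(10.0))
        assert np.isnan(barrier_height(2e5))  # faster than the prefactor
        with pytest.raises(ValueError):
            barrier_height(-1.0)

    def test_unnormalized_occupancies_rejected(self):
        with pytest.raises(ValueError):
            free_energy_profile([0.4, 0.6], [0.5, 0.4])


class _StubFit:
    """Minimal two-state fit stand-in with fixed occupancies (synthetic)."""

    n_states = 2

    def __init__(self, p1, n_bursts=400):
        self.occupancies = np.array([p1, 1 - p1])
        self._n = n_bursts

    def bootstrap_occupancy(self, n_boot=200, seed=None):
        rng = np.random.default_rng(seed)
        counts = rng.binomial(self._n, self.occupancies[0], size=n_boot)
        p = counts / self._n
        return np.column_stack([p, 1 - p])


class TestEquilibrium:
    def test_equal_populations_unit_ratio(self):
        s = equilibrium_and_response(_StubFit(0.5), _StubFit(0.5), seed=0)
        assert s.k12[0] == pytest.approx(1.0)
        assert s.response_factor == pytest.approx(1.0)

    def test_printed_k12_values_reproduce_response_factor(self):
        # K12 = 0.48 -> p1 = 0.48/1.48; K12 = 0.81 -> p1 = 0.81/1.81
        s = equilibrium_and_response(
            _StubFit(0.48 / 1.48), _StubFit(0.81 / 1.81), seed=1
        )
        assert s.k12[0] == pytest.approx(0.48, abs=1e-12)
        assert s.k12[1] == pytest.approx(0.81, abs=1e-12)
        assert s.response_factor == pytest.approx(1.6875, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self):
        s = equilibrium_and_response(_StubFit(0.4), _StubFit(0.55), seed=2)
        for i in range(2):
            assert s.k12_ci[i, 0] < s.k12[i] < s.k12_ci[i, 1]
        assert s.response_ci[0] < s.response_factor < s.response_ci[1]

    def test_recovers_true_ratios_from_fits(self):
        # two simulated conditions with population ratios 0.48 and 0.81
        results = []
        for sd, (k12_rate, k21_rate) in ((61, (2e4, 0.48 * 2e4)),
                                         (62, (2e4, 0.81 * 2e4))):
            cfg = ph.benchmark_config(
                n_bursts=400, seed=sd,
                rate_matrix=np.array([[0.0, k12_rate], [k21_rate, 0.0]]),
            )
            stream, truth = ph.generate_dataset(cfg)
            colors, ticks = ph.truth_burst_sequences(stream, truth)
            results.append(
                ph.em_fit(colors, 2, restarts=2, tol_per_photon=1e-8,
                          max_iter=800, seed=sd, ticks=ticks,
                          tick=stream.tick)
            )
        s = equilibrium_and_response(*results, seed=3)
        # stationary p(low)/p(high) = k21/k12
        assert s.k12[0] == pytest.approx(0.48, abs=0.05)
        assert s.k12[1] == pytest.approx(0.81, abs=0.07)
        assert s.response_factor == pytest.approx(1.6875, rel=0.12)

    def test_summary_mentions_convention(self):
        s = equilibrium_and_response(_StubFit(0.5), _StubFit(0.5), seed=0)
        assert "low-E" in s.summary() or "low" in s.index_convention


class TestActivityCorrelation:
    def test_collinear_points(self):
        slope, icpt, r2 = activity_correlation([1, 2, 3], [2, 4, 6])
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_noise_shrinks_r2_monotonically(self):
        rng = np.random.default_rng(4)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        base = rng.standard_normal(4)
        r2s = [activity_correlation(x, x + 1 + s * base)[2]
               for s in (0.0, 0.1, 0.5)]
        assert r2s[0] == pytest.approx(1.0)
        assert r2s[0] >= r2s[1] >= r2s[2]

    def test_four_point_example(self):
        # hand OLS: Sxy=7, Sxx=5, Syy=10 -> R^2 = 49/50
        _, _, r2 = activity_correlation([1, 2, 3, 4], [2, 3, 5, 6])
        assert r2 == pytest.approx(0.98, abs=1e-12)

    def test_degenerate_inputs(self):
        assert np.isnan(activity_correlation([1, 1, 1], [1, 2, 3])[2])
        with pytest.raises(ValueError):
            activity_correlation([1, 2], [1, 2])


class TestFretDistance:
    def test_half_efficiency_is_forster_radius(self):
        assert fret_distance(0.5) == pytest.approx(54.0)

    def test_benchmark_pair_amplitude(self):
        # r(0.45) = 55.837 A, r(0.75) = 44.965 A at R0 = 54 A
        assert fret_distance(0.45) == pytest.approx(55.8366, abs=1e-3)
        assert fret_distance(0.75) == pytest.approx(44.9649, abs=1e-3)
        amp = motion_amplitude(0.45, 0.75)
        assert amp == pytest.approx(10.8717, abs=1e-3)
        assert amp > 10.0  # more than two substrate residues of motion

    def test_monotone_decreasing_and_invertible(self):
        e = np.linspace(0.01, 0.99, 50)
        r = fret_distance(e)
        assert np.all(np.diff(r) < 0)
        e_back = 1.0 / (1.0 + (r / 54.0) ** 6)
        np.testing.assert_allclose(e_back, e, atol=1e-9)

    def test_edge_values_flagged(self):
        r = fret_distance(np.array([0.0, 1.0, 0.5]))
        assert np.isnan(r[0]) and np.isnan(r[1])


def burst_da_times(colors, ticks, tick):
    donor, acceptor, durations = [], [], []
    for c, t in zip(colors, ticks):
        ts = t * tick
        donor.append(ts[c == 0])
        acceptor.append(ts[c == 1])
        durations.append(ts[-1] - ts[0] if len(ts) > 1 else 0.0)
    return donor, acceptor, durations


class TestBurstFCCS:
    def test_shuffled_colors_flat_at_one(self, bench_small):
        rng = np.random.default_rng(5)
        colors = [rng.permutation(c) for c in bench_small["colors"]]
        d, a, dur = burst_da_times(colors, bench_small["ticks"],
                                   bench_small["stream"].tick)
        curve = burst_fccs(d, a, dur)
        assert np.nanmax(np.abs(curve.g - 1.0)) < 0.06

    def test_two_state_dynamics_produce_rise(self, bench_small):
        d, a, dur = burst_da_times(bench_small["colors"],
                                   bench_small["ticks"],
                                   bench_small["stream"].tick)
        curve = burst_fccs(d, a, dur)
        # anticorrelated donor/acceptor: depressed at short lags, rising
        assert curve.g[0] < 0.97
        tau, amp, _ = fit_fccs_relaxation(curve)
        assert amp > 0

    def test_all_single_color_rejected(self):
        with pytest.raises(ValueError):
            burst_fccs([np.array([1e-4])], [np.array([])], [1e-3])


class TestAnisotropy:
    def test_equal_components_zero(self):
        t = np.arange(5.0)
        dec = anisotropy(t, np.ones(5), np.ones(5))
        np.testing.assert_allclose(dec.r, 0.0, atol=1e-12)
        assert dec.r_steady == pytest.approx(0.0)

    def test_two_to_one_ratio(self):
        dec = anisotropy([0.0], [2.0], [1.0])
        assert dec.r[0] == pytest.approx(0.25)

    def test_g_factor_two_cancels(self):
        consts = SpectroscopyConstants(g_factor=2.0)
        dec = anisotropy([0.0], [2.0], [1.0], consts)
        assert dec.r[0] == pytest.approx(0.0)

    def test_empty_bin_undefined(self):
        dec = anisotropy([0.0, 1.0], [1.0, 0.0], [0.5, 0.0])
        assert np.isnan(dec.r[1])
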