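"""Likelihood, EM, Viterbi: frozen examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photonhmm as ph
from photonhmm.model import FretModel, PhotonHMM, TopologyConstraint

from _oracles import (enum_loglik, enum_viterbi, path_probabilities,
                      random_model)

# shared two-state example: prior (.5,.5), sticky transitions, mirrored colors
M2 = FretModel(
    prior=[0.5, 0.5],
    transition=[[0.9, 0.1], [0.1, 0.9]],
    observation=[[0.8, 0.2], [0.2, 0.8]],
)


class TestSequenceLoglik:
    def test_single_state_product_form(self):
        m = FretModel([1.0], [[1.0]], [[0.7, 0.3]])
        ll = ph.sequence_loglik(m, [np.array([0, 0, 1])])
        assert ll == pytest.approx(np.log(0.7 * 0.7 * 0.3))

    def test_uniform_emissions_are_model_independent(self):
        m = FretModel([0.3, 0.7], [[0.6, 0.4], [0.2, 0.8]],
                      [[0.5, 0.5], [0.5, 0.5]])
        obs = np.array([0, 1, 1, 0, 1])
        ll = ph.sequence_loglik(m, [obs])
        assert ll == pytest.approx(len(obs) * np.log(0.5))

    def test_two_state_donor_acceptor_example(self):
        # exhaustive sum over the 4 paths gives 0.178
        ll = ph.sequence_loglik(M2, [np.array([0, 1])])
        assert np.exp(ll) == pytest.approx(0.178, abs=1e-12)
        oracle = enum_loglik(M2.prior, M2.transition, M2.observation, [0, 1])
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_empty_burst_list_zero(self):
        assert ph.sequence_loglik(M2, []) == 0.0

    def test_bursts_are_independent_chains(self):
        a, b = np.array([0, 1, 1]), np.array([1, 0])
        assert ph.sequence_loglik(M2, [a, b]) == pytest.approx(
            ph.sequence_loglik(M2, [a]) + ph.sequence_loglik(M2, [b])
        )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_forward_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        T = int(rng.integers(1, 13))
        pi, A, B = random_model(rng, n)
        obs = rng.integers(0, 2, size=T)
        m = FretModel(pi, A, B)
        assert ph.sequence_loglik(m, [obs]) == pytest.approx(
            enum_loglik(pi, A, B, obs), rel=1e-9
        )

    def test_tick_resolved_reduces_to_photon_indexed_at_unit_gaps(self):
        obs = np.array([0, 1, 1, 0])
        ticks = np.arange(4, dtype=np.int64)
        hmm = PhotonHMM([obs], ticks=[ticks])
        assert hmm.loglike(M2, tick_resolved=True) == pytest.approx(
            hmm.loglike(M2), rel=1e-12
        )

    def test_tick_resolved_uses_matrix_powers(self):
        obs = np.array([0, 1])
        ticks = np.array([0, 3], dtype=np.int64)
        hmm = PhotonHMM([obs], ticks=[ticks])
        A3 = np.linalg.matrix_power(np.asarray(M2.transition), 3)
        m3 = FretModel(M2.prior, A3, M2.observation)
        assert hmm.loglike(M2, tick_resolved=True) == pytest.approx(
            hmm.loglike(m3), rel=1e-12
        )


class TestViterbi:
    def test_single_state_constant_path(self):
        m = FretModel([1.0], [[1.0]], [[0.4, 0.6]])
        seg = ph.viterbi_decode(m, [np.array([0, 1, 0])])
        np.testing.assert_array_equal(seg.paths[0], [0, 0, 0])

    def test_deterministic_emissions_follow_colors(self):
        m = FretModel([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                      [[1.0, 0.0], [0.0, 1.0]])
        obs = np.array([0, 1, 1, 0, 1])
        seg = ph.viterbi_decode(m, [obs])
        np.testing.assert_array_equal(seg.paths[0], obs)

    def test_two_photon_example_path_and_probability(self):
        seg = ph.viterbi_decode(M2, [np.array([0, 0])])
        np.testing.assert_array_equal(seg.paths[0], [0, 0])
        assert np.exp(seg.logprobs[0]) == pytest.approx(0.288, abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        T = int(rng.integers(1, 13))
        pi, A, B = random_model(rng, n)
        obs = rng.integers(0, 2, size=T)
        seg = ph.viterbi_decode(FretModel(pi, A, B), [obs])
        best, p = enum_viterbi(pi, A, B, obs)
        assert seg.logprobs[0] == pytest.approx(np.log(p), rel=1e-9)
        # the decoded path must attain the maximal probability; with several
        # exactly tied optima any of them is acceptable
        probs = path_probabilities(pi, A, B, obs)
        mine = probs[np.ravel_multi_index(tuple(seg.paths[0]), (n,) * T)]
        assert mine == pytest.approx(p, rel=1e-12)

    def test_segments_tile_bursts_with_alternating_states(self):
        rng = np.random.default_rng(1)
        colors = [rng.integers(0, 2, size=60) for _ in range(20)]
        seg = ph.viterbi_decode(M2, colors)
        for b in range(20):
            rows = seg.segments[seg.segments["burst_id"] == b]
            assert rows["n_photons"].sum() == 60
            states = rows["state"].to_numpy()
            assert np.all(states[1:] != states[:-1])


class TestEMFit:
    def test_single_state_closed_form(self):
        colors = [np.array([1] * 30 + [0] * 70)]
        res = ph.em_fit(colors, n_states=1, restarts=3, seed=0)
        assert res.state_fret[0] == pytest.approx(0.3, abs=1e-9)

    def test_monotone_loglik_and_stochastic_rows(self, bench_small):
        res = bench_small["fit"]
        assert np.all(np.diff(res.ll_history) >= -1e-8)
        for m in (res.params.transition, res.params.observation):
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
        assert res.params.prior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_state_recovery_small(self, bench_small):
        res = bench_small["fit"]
        assert res.state_fret == pytest.approx([0.45, 0.75], abs=0.03)

    def test_states_sorted_by_fret_regardless_of_seed(self, bench_small):
        colors, ticks = bench_small["colors"], bench_small["ticks"]
        r = ph.em_fit(colors[:150], 2, restarts=2, seed=99, ticks=ticks[:150],
                      tol_per_photon=1e-8, max_iter=1000)
        assert r.state_fret[0] < r.state_fret[1]
        r2 = ph.em_fit(colors[:150], 2, restarts=2, seed=1234,
                       ticks=ticks[:150], tol_per_photon=1e-8, max_iter=1000)
        assert r2.state_fret == pytest.approx(r.state_fret, abs=1e-3)

    def test_empty_burst_set_rejected(self):
        with pytest.raises(ValueError):
            ph.em_fit([], n_states=2)

    def test_degenerate_state_pruned_with_warning(self):
        from photonhmm.model import PhotonHMMResults

        data = PhotonHMM([np.array([0, 1, 0])])
        params = FretModel([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]],
                           [[0.6, 0.4], [0.2, 0.8]])
        res = PhotonHMMResults(
            data, params, loglik=-1.0, n_iter=1, converged=True,
            restart_logliks=[-1.0], best_restart=0,
            burst_occupancy=np.array([[3.0, 0.0]]), ll_history=[-1.0],
        )
        with pytest.warns(ph.DegenerateFitWarning):
            res._check_degenerate()
        assert res.n_states == 1
        assert res.params.transition.sum() == pytest.approx(1.0)

    def test_cross_check_against_hmmlearn_likelihood(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        pi, A, B = random_model(rng, 3)
        obs = rng.integers(0, 2, size=200)
        ours = ph.sequence_loglik(FretModel(pi, A, B), [obs])
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, A, B
        assert ours == pytest.approx(ref.score(obs.reshape(-1, 1)), rel=1e-9)


class TestRestrictedGrid:
    def test_off_tridiagonal_entries_stay_zero(self, bench_small):
        con = TopologyConstraint(kind="sequential_grid", n_grid=5,
                                 e_min=0.2, e_max=0.9)
        res = ph.em_fit_restricted_1d(
            bench_small["colors"][:100], con, restarts=1, max_iter=40, seed=0
        )
        A = res.params.transition
        mask = con.transition_mask()
        assert np.all(A[~mask] == 0.0)

    def test_grid_frozen_in_observation_matrix(self, bench_small):
        con = TopologyConstraint(kind="sequential_grid", n_grid=5,
                                 e_min=0.2, e_max=0.9)
        res = ph.em_fit_restricted_1d(
            bench_small["colors"][:100], con, restarts=1, max_iter=40, seed=0
        )
        np.testing.assert_allclose(res.state_fret, con.grid(), atol=1e-12)

    def test_static_data_concentrates_near_true_e(self):
        rng = np.random.default_rng(4)
        colors = [(rng.random(150) < 0.5).astype(np.int8) for _ in range(80)]
        con = TopologyConstraint(kind="sequential_grid", n_grid=9)
        res = ph.em_fit_restricted_1d(colors, con, restarts=2, max_iter=200,
                                      seed=1)
        grid = con.grid()
        near = np.abs(grid - 0.5) <= (grid[1] - grid[0])
        assert res.occupancies[near].sum() > 0.9
        prof = ph.free_energy_profile(res.state_fret, res.occupancies)
        assert len(prof.local_minima()) == 1

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            TopologyConstraint(kind="sequential_grid", n_grid=1)

    def test_wrong_constraint_kind_rejected(self):
        with pytest.raises(ValueError):
            ph.em_fit_restricted_1d([np.array([0, 1])], TopologyConstraint())


class TestGlobalFit:
    def test_identical_datasets_match_single_fit(self, bench_small):
        colors = bench_small["colors"][:200]
        single = ph.em_fit(colors, 2, restarts=2, seed=5,
                           tol_per_photon=1e-8, max_iter=800)
        both = ph.em_fit_global(colors, colors, n_states=2, restarts=2,
                                seed=5, tol_per_photon=1e-8, max_iter=800)
        ra, rb = both.results
        assert ra.state_fret == pytest.approx(rb.state_fret, abs=1e-9)
        np.testing.assert_allclose(ra.params.transition, rb.params.transition,
                                   atol=1e-6)
        assert ra.state_fret == pytest.approx(single.state_fret, abs=5e-3)
        assert both.loglik == pytest.approx(2 * single.loglik, rel=1e-4)

    def test_pooled_b_update_is_occupancy_weighted_average(self, bench_small):
        from photonhmm._kernels import estep, pack_sequences

        ca = bench_small["colors"][:60]
        cb = bench_small["colors"][60:150]
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        B = np.array([[0.6, 0.4], [0.3, 0.7]])
        stats = []
        for c in (ca, cb):
            obs, starts = pack_sequences(c)
            stats.append(estep(obs, starts, pi, A, B))
        g_a, g_b = stats[0][3], stats[1][3]
        pooled = (g_a + g_b) / (g_a + g_b).sum(axis=1, keepdims=True)
        b_a = g_a / g_a.sum(axis=1, keepdims=True)
        b_b = g_b / g_b.sum(axis=1, keepdims=True)
        w_a = (g_a.sum(axis=1) / (g_a + g_b).sum(axis=1))[:, None]
        np.testing.assert_allclose(pooled, w_a * b_a + (1 - w_a) * b_b,
                                   atol=1e-12)

    def test_shared_b_with_distinct_kinetics(self):
        cfg_a = ph.benchmark_config(n_bursts=250, seed=51)
        cfg_b = ph.benchmark_config(
            n_bursts=250, seed=52,
            rate_matrix=np.array([[0.0, 3e4], [1e4, 0.0]]),
        )
        sa, ta = ph.generate_dataset(cfg_a)
        sb, tb = ph.generate_dataset(cfg_b)
        ca, ka = ph.truth_burst_sequences(sa, ta)
        cb, kb = ph.truth_burst_sequences(sb, tb)
        res = ph.em_fit_global(ca, cb, n_states=2, restarts=2, seed=9,
                               tol_per_photon=1e-8, max_iter=800,
                               ticks_a=ka, ticks_b=kb, tick=sa.tick)
        assert res.shared_fret == pytest.approx([0.45, 0.75], abs=0.03)
        occ_a = res.results[0].occupancies
        occ_b = res.results[1].occupancies
        # dataset A symmetric (p1 ~ 0.5); dataset B favors the low-E state
        assert occ_a[0] == pytest.approx(0.5, abs=0.06)
        assert occ_b[0] == pytest.approx(0.25, abs=0.06)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ph.em_fit_global([], [np.array([0, 1])], n_states=2)


class TestModelIO:
    def test_yaml_roundtrip(self, bench_small, tmp_path):
        import yaml

        res = bench_small["fit"]
        path = tmp_path / "model.yaml"
        res.to_yaml(path)
        with open(path) as fh:
            rec = yaml.safe_load(fh)
        m = FretModel.from_dict(rec)
        np.testing.assert_allclose(m.observation, res.params.observation)
        assert rec["loglik"] == pytest.approx(res.loglik)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            FretModel([0.5, 0.6], [[1, 0], [0, 1]], [[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValueError):
            FretModel([0.5, 0.5], [[1.5, -0.5], [0, 1]],
                      [[0.5, 0.5], [0.5, 0.5]])

    def test_summary_reports_states_and_rates(self, bench_small):
        text = bench_small["fit"].summary()
        assert "transition rates" in text
        assert "state" in text and "occupancy" in text
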