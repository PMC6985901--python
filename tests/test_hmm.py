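"""Envelope HMM: input preparation, VB inference, Viterbi decoding, state
metrics and the model-order scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from betadyn import (
    EnvelopeHMM,
    StatePath,
    TrialEvents,
    fit_hmm,
    prepare_hmm_input,
    scan_states,
    state_metrics,
    viterbi_decode,
)
from betadyn.hmm import align_states
from betadyn._chain import viterbi_path

from conftest import make_schedule


def simulate_chain(T, means, covs, A, pi, rng):
    K, P = means.shape
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(K, p=pi)
    for t in range(1, T):
        z[t] = rng.choice(K, p=A[z[t - 1]])
    chols = [np.linalg.cholesky(c) for c in covs]
    X = np.stack([means[z[t]] + chols[z[t]] @ rng.standard_normal(P)
                  for t in range(T)])
    return X, z


@pytest.fixture(scope="module")
def three_state_sim():
    rng = np.random.default_rng(0)
    K, P = 3, 4
    means = np.array([[3.0, 0, 0, 0], [0, 3.0, 0, 0], [0, 0, 3.0, 3.0]])
    covs = np.stack([np.eye(P)] * K)
    A = np.full((K, K), 0.05) + np.eye(K) * 0.85
    pi = np.ones(K) / K
    X, z = simulate_chain(20_000, means, covs, A, pi, rng)
    return X, z, means, A


class TestPrepareInput:
    def test_session_boundary_bookkeeping(self):
        rng = np.random.default_rng(0)
        s1 = rng.standard_normal((3, 6000))
        s2 = rng.standard_normal((3, 12000))
        X, boundaries = prepare_hmm_input([s1, s2], fs=600.0)
        assert boundaries == [0, 1000]
        assert X.shape == (3000, 3)

    def test_standardization(self):
        rng = np.random.default_rng(1)
        X, _ = prepare_hmm_input(rng.standard_normal((4, 30000)), fs=600.0)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-10)

    def test_decimation_band_selectivity(self):
        t = np.arange(60000) / 600.0
        slow = np.sin(2 * np.pi * 5.0 * t)
        fast = np.sin(2 * np.pi * 49.0 * t)
        X, _ = prepare_hmm_input(np.vstack([slow, fast]), fs=600.0,
                                 standardize=False)
        mid = slice(200, -200)
        amp_slow = np.median(X[mid, 0])
        amp_fast = np.median(X[mid, 1])
        assert amp_slow == pytest.approx(1.0, rel=0.01)
        assert amp_fast < 0.1 * amp_slow

    def test_zero_variance_parcel_rejected(self):
        x = np.vstack([np.zeros(30000),
                       np.random.default_rng(0).standard_normal(30000)])
        with pytest.raises(ValueError, match="zero variance"):
            prepare_hmm_input(x, fs=600.0)

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            prepare_hmm_input(np.ones((2, 50)), fs=600.0)


class TestVBFit:
    def test_single_state_matches_sample_moments(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5000, 3)) * [1.0, 2.0, 0.5] + [1.0, -1.0, 0.0]
        res = fit_hmm(X, 1, n_inits=1, seed=0, max_iter=10)
        np.testing.assert_allclose(res.means[0], X.mean(axis=0), atol=0.01)
        np.testing.assert_allclose(res.covariances[0], np.cov(X.T), atol=0.05)
        np.testing.assert_allclose(res.transitions, [[1.0]])

    def test_three_state_recovery(self, three_state_sim):
        X, z, means, A = three_state_sim
        res = fit_hmm(X, 3, n_inits=3, seed=1, max_iter=60)
        perm = align_states(res.means, means)  # est label -> true label
        acc = np.mean(perm[viterbi_decode(res, X).states] == z)
        assert acc > 0.95
        inv = np.argsort(perm)
        A_est = res.transitions[np.ix_(inv, inv)]
        assert np.abs(A_est - A).max() < 0.05

    def test_free_energy_non_increasing_every_init(self, three_state_sim):
        X, *_ = three_state_sim
        res = fit_hmm(X, 3, n_inits=3, seed=2, max_iter=40)
        for trace in res.all_traces:
            diffs = np.diff(trace)
            assert np.all(diffs <= np.abs(trace[:-1]) * 1e-8 + 1e-8)

    def test_best_init_selected(self, three_state_sim):
        X, *_ = three_state_sim
        res = fit_hmm(X, 3, n_inits=3, seed=3, max_iter=25)
        assert res.free_energy == pytest.approx(res.init_free_energies.min())
        assert res.init_free_energies[res.init_index] == res.free_energy

    def test_transition_rows_stochastic(self, three_state_sim):
        X, *_ = three_state_sim
        res = fit_hmm(X, 3, n_inits=1, seed=4, max_iter=15)
        np.testing.assert_allclose(res.transitions.sum(axis=1), 1.0,
                                   atol=1e-10)
        for c in res.covariances:
            np.testing.assert_allclose(c, c.T, atol=1e-12)
            assert np.linalg.eigvalsh(c)[0] > 0

    def test_too_small_problem_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeHMM(np.ones((10, 4)), 3)


class TestViterbi:
    def brute_force(self, ll, lnA, lnpi):
        T, K = ll.shape
        best, best_seq = -np.inf, None
        for seq in itertools.product(range(K), repeat=T):
            score = lnpi[seq[0]] + ll[0, seq[0]]
            for t in range(1, T):
                score += lnA[seq[t - 1], seq[t]] + ll[t, seq[t]]
            if score > best:
                best, best_seq = score, seq
        return np.asarray(best_seq)

    def test_matches_brute_force_on_100_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            T, K = 8, 3
            ll = rng.normal(0, 2, (T, K))
            lnA = np.log(rng.dirichlet(np.ones(K), size=K))
            lnpi = np.log(rng.dirichlet(np.ones(K)))
            path = viterbi_path(ll, lnA, lnpi, [0])
            np.testing.assert_array_equal(path,
                                          self.brute_force(ll, lnA, lnpi))

    def test_dominant_state_gives_constant_path(self):
        T, K = 50, 3
        ll = np.zeros((T, K))
        ll[:, 1] = 10.0
        lnA = np.log(np.full((K, K), 1 / 3))
        path = viterbi_path(ll, lnA, np.log(np.ones(K) / 3), [0])
        assert np.all(path == 1)

    def test_single_state_path_is_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 2))
        res = fit_hmm(X, 1, n_inits=1, seed=0, max_iter=5)
        path = viterbi_decode(res, X)
        assert np.all(path.states == 0)
        assert path.binary().sum(axis=0).min() == 1

    def test_dimension_mismatch_rejected(self, three_state_sim):
        X, *_ = three_state_sim
        res = fit_hmm(X, 3, n_inits=1, seed=0, max_iter=5)
        with pytest.raises(ValueError):
            viterbi_decode(res, X[:, :2])

    def test_matches_hmmlearn_decoder(self, three_state_sim):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        X, *_ = three_state_sim
        res = fit_hmm(X, 3, n_inits=2, seed=5, max_iter=30)
        ext = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ext.startprob_ = res.initial_probs
        ext.transmat_ = res.transitions
        ext.means_ = res.means
        ext.covars_ = res.covariances
        expected = ext.predict(X[:2000])
        ours = viterbi_decode(res, X[:2000]).states
        assert np.mean(ours == expected) > 0.999


class TestStateMetrics:
    def _one_trial_setup(self, states, fs=100.0):
        path = StatePath(states=np.asarray(states), n_states=2, fs=fs)
        sched = make_schedule([2.0], lead_in_s=2.0, rest_s=1.0)
        tab = pd.DataFrame({
            "trial_id": [0], "condition_s": [2.0], "onset_s": [0.0],
            "offset_s": [0.0], "rejected": [False], "reason": [""],
        })
        return path, sched, TrialEvents(tab)

    def test_hand_countable_example(self):
        states = [0, 0, 1, 1, 0, 1, 0, 0, 0, 1, 1, 1]
        path, sched, ev = self._one_trial_setup(states)
        df = state_metrics(path, sched, ev, epochs={"win": (0.0, 0.12)})
        s1 = df[df["state"] == 1].set_index("metric")["value"]
        assert s1["fractional_occupancy"] == pytest.approx(0.5)
        assert s1["n_occurrences"] == 3
        assert s1["mean_lifetime_ms"] == pytest.approx(20.0)
        assert s1["mean_interval_ms"] == pytest.approx(20.0)

    def test_occupancies_sum_to_one(self):
        states = [0, 0, 1, 1, 0, 1, 0, 0, 0, 1, 1, 1]
        path, sched, ev = self._one_trial_setup(states)
        df = state_metrics(path, sched, ev, epochs={"win": (0.0, 0.12)})
        occ = df[df["metric"] == "fractional_occupancy"]["value"]
        assert occ.sum() == pytest.approx(1.0)

    def test_never_active_state_reports_absent(self):
        states = [0] * 12
        path, sched, ev = self._one_trial_setup(states)
        df = state_metrics(path, sched, ev, epochs={"win": (0.0, 0.12)})
        s1 = df[df["state"] == 1].set_index("metric")["value"]
        assert s1["fractional_occupancy"] == 0.0
        assert s1["n_occurrences"] == 0
        assert np.isnan(s1["mean_lifetime_ms"])
        assert np.isnan(s1["mean_interval_ms"])

    def test_beta_amplitude_sample_and_hold(self):
        states = [0, 1, 1, 0]
        path, sched, ev = self._one_trial_setup(states)
        env = np.arange(24, dtype=float)  # 600 Hz: 6 samples per path sample
        df = state_metrics(path, sched, ev, beta_env=env, beta_fs=600.0,
                           epochs={"win": (0.0, 0.04)})
        s1 = df[df["state"] == 1].set_index("metric")["value"]
        assert s1["mean_beta_amplitude"] == pytest.approx(np.mean(np.arange(6, 18)))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 3, 200)
        perm = np.array([2, 0, 1])
        path1 = StatePath(states=states, n_states=3, fs=100.0)
        path2 = StatePath(states=perm[states], n_states=3, fs=100.0)
        sched = make_schedule([2.0], lead_in_s=1.0, rest_s=1.0)
        tab = pd.DataFrame({"trial_id": [0], "condition_s": [2.0],
                            "onset_s": [0.0], "offset_s": [0.0],
                            "rejected": [False], "reason": [""]})
        ev = TrialEvents(tab)
        df1 = state_metrics(path1, sched, ev, epochs={"win": (0.0, 2.0)})
        df2 = state_metrics(path2, sched, ev, epochs={"win": (0.0, 2.0)})
        for s in range(3):
            v1 = df1[df1["state"] == s].set_index("metric")["value"]
            v2 = df2[df2["state"] == perm[s]].set_index("metric")["value"]
            pd.testing.assert_series_equal(v1, v2, check_names=False)

    def test_zero_length_epoch_rejected(self):
        states = [0, 1] * 6
        path, sched, ev = self._one_trial_setup(states)
        with pytest.raises(ValueError, match="zero length"):
            state_metrics(path, sched, ev, epochs={"bad": (1.0, 1.0)})


class TestScan:
    def test_single_k_report(self, three_state_sim):
        X, *_ = three_state_sim
        out = scan_states(X[:5000], K_list=[3], n_inits=1, seed=0, max_iter=15)
        assert list(out.models) == [3]
        assert len(out.report()) == 1

    def test_free_energy_plateau_marks_true_state_count(self, three_state_sim):
        X, *_ = three_state_sim
        out = scan_states(X[:12_000], K_list=[2, 3, 4, 5], n_inits=2, seed=0,
                          max_iter=30)
        fes = {k: f / 12_000 for k, f in out.free_energies.items()}
        # large drop up to the generating K = 3, then a plateau
        assert fes[3] < fes[2]
        drop = fes[2] - fes[3]
        plateau = max(abs(fes[4] - fes[3]), abs(fes[5] - fes[4]))
        assert drop > 10 * plateau

    def test_template_identifies_generating_state(self, three_state_sim):
        X, z, means, _ = three_state_sim
        out = scan_states(X, K_list=[3], template=means[2], n_inits=2, seed=1,
                          max_iter=40)
        res = out.models[3]
        perm = align_states(res.means, means)
        # the template-matched state is the one aligned to generating state 2
        assert perm[out.sensorimotor_state[3]] == 2
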