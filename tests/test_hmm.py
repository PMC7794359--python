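import itertools

import numpy as np
import pytest
import scipy.linalg

from slipfret import fit_hmm, idealize, stitch_traces
from slipfret.hmm import (
    HmmModel,
    fit_hmm_blur,
    forward_log_likelihood,
    path_log_probability,
    viterbi_path,
)
from slipfret.kinetics import rate_matrix_from_traces
from slipfret.pipelines import simulate_tirf_dataset, static_scheme


def brute_force_log_likelihood(model, x):
    """Oracle: sum the joint probability over every possible state path."""
    K = model.n_states
    total = 0.0
    for path in itertools.product(range(K), repeat=len(x)):
        p = model.startprob[path[0]]
        for t in range(1, len(x)):
            p *= model.transmat[path[t - 1], path[t]]
        for t, s in enumerate(path):
            z = (x[t] - model.means[s]) / model.sigmas[s]
            p *= np.exp(-0.5 * z * z) / (model.sigmas[s] * np.sqrt(2 * np.pi))
        total += p
    return np.log(total)


def _alternating_trace(levels=(0.3, 0.7), period=5, n=200):
    states = (np.arange(n) // period) % 2
    return np.array(levels)[states], states


class TestFitHmm:
    def test_noiseless_two_level_recovers_means_exactly(self):
        x, _ = _alternating_trace()
        model = fit_hmm([x], n_states=2, restarts=3, seed=0)
        np.testing.assert_allclose(model.means, [0.3, 0.7], atol=1e-6)

    def test_single_state_mean_is_global_mean(self, rng):
        x = rng.normal(0.5, 0.05, 500).clip(0, 1)
        model = fit_hmm([x], n_states=1, restarts=1, seed=0)
        assert model.means[0] == pytest.approx(x.mean(), abs=1e-9)

    def test_em_loglik_monotone(self, rng):
        x = np.concatenate([rng.normal(0.3, 0.05, 300), rng.normal(0.7, 0.05, 300)])
        model = fit_hmm([x], n_states=2, restarts=2, seed=1)
        assert np.all(np.diff(model.history) >= -1e-8 * np.abs(model.history[:-1]))

    def test_means_sorted_and_distinct(self, rng):
        xs = [rng.normal([0.2, 0.8][i % 2], 0.05, 100).clip(0, 1) for i in range(6)]
        model = fit_hmm(xs, n_states=2, restarts=3, seed=2)
        assert np.all(np.diff(model.means) > 0)
        assert not model.degenerate

    def test_transmat_consistent_with_discretized_ctmc(self):
        """Blur-aware fit at (12.25, 3.38), 50 ms bins, sigma=0.1: per-frame
        transition probabilities should approximate expm(Q dt)."""
        scheme = static_scheme()
        traces = simulate_tirf_dataset(scheme, n_traces=60, duration=60.0, seed=5)
        model = fit_hmm_blur([t.e_apparent for t in traces], n_states=2, seed=6)
        P_true = scipy.linalg.expm(scheme.rate_matrix * 0.05)
        np.testing.assert_allclose(model.transmat, P_true, rtol=0.20)
        np.testing.assert_allclose(model.means, scheme.fret_map, atol=0.02)

    def test_forward_likelihood_matches_hmmlearn(self, rng):
        """Independent cross-check: hmmlearn's forward algorithm scores a
        trace identically under the same parameters."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        x = np.concatenate([rng.normal(0.3, 0.08, 200), rng.normal(0.7, 0.08, 200)])
        model = fit_hmm([x], n_states=2, restarts=3, seed=9)
        ref = hmmlearn_hmm.GaussianHMM(
            n_components=2, covariance_type="diag", init_params="", params=""
        )
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.means[:, None]
        ref.covars_ = (model.sigmas**2)[:, None]
        assert forward_log_likelihood(model, x) == pytest.approx(
            ref.score(x[:, None]), rel=1e-9
        )

    def test_forward_likelihood_matches_path_sum_oracle(self, rng):
        for K, T in [(2, 8), (3, 6), (3, 10)]:
            model = HmmModel(
                means=np.linspace(0.2, 0.8, K),
                sigmas=np.full(K, 0.1),
                transmat=np.full((K, K), 0.1 / (K - 1)) + np.eye(K) * (0.9 - 0.1 / (K - 1)),
                startprob=np.full(K, 1 / K),
                log_likelihood=0.0,
            )
            model.transmat /= model.transmat.sum(axis=1, keepdims=True)
            x = rng.uniform(0, 1, T)
            ll = forward_log_likelihood(model, x)
            assert ll == pytest.approx(brute_force_log_likelihood(model, x), rel=1e-9)


class TestViterbi:
    def test_noiseless_alternating_path_exact(self):
        x, truth = _alternating_trace()
        model = fit_hmm([x], n_states=2, restarts=2, seed=0)
        ideal = idealize(x, model)
        np.testing.assert_array_equal(ideal.states, truth)
        np.testing.assert_allclose(ideal.e_idealized, x, atol=1e-6)

    def test_viterbi_path_beats_true_path_logprob(self, rng):
        x = np.concatenate([rng.normal(0.3, 0.1, 50), rng.normal(0.7, 0.1, 50)]).clip(0, 1)
        truth = np.repeat([0, 1], 50)
        model = fit_hmm([x], n_states=2, restarts=2, seed=3)
        vit = viterbi_path(model, x)
        assert path_log_probability(model, x, vit) >= path_log_probability(model, x, truth)

    def test_high_accuracy_at_moderate_noise(self, rng):
        """sigma=0.05 around means 0.3/0.7: frame accuracy > 99%."""
        n, period = 2000, 20
        truth = (np.arange(n) // period) % 2
        x = np.where(truth == 0, 0.3, 0.7) + rng.normal(0, 0.05, n)
        model = fit_hmm([x], n_states=2, restarts=3, seed=4)
        acc = np.mean(viterbi_path(model, x) == truth)
        assert acc > 0.99


class TestStitching:
    def test_concatenation_and_boundaries(self, rng):
        traces = [rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)]
        st = stitch_traces(traces)
        assert st.values.size == 200
        np.testing.assert_array_equal(st.boundaries, [100])
        parts = st.split()
        np.testing.assert_array_equal(parts[0], traces[0])

    def test_stitched_and_unstitched_rates_agree(self):
        """Dwell-rate estimates from stitched vs per-trace idealization agree
        within one standard error (boundary-spanning dwells are dropped)."""
        scheme = static_scheme()
        traces = simulate_tirf_dataset(scheme, n_traces=30, duration=30.0, seed=21)
        xs = [t.e_apparent for t in traces]
        model = fit_hmm_blur(xs, n_states=2, seed=22)
        paths = [viterbi_path(model, x) for x in xs]
        from slipfret.hmm import StitchedSeries

        stitched = StitchedSeries(np.concatenate(paths),
                                  np.cumsum([p.size for p in paths])[:-1])
        r_split = rate_matrix_from_traces(paths, 2, 0.05)
        r_stitch = rate_matrix_from_traces([stitched], 2, 0.05)
        for pair in [(0, 1), (1, 0)]:
            a, b = r_split[pair], r_stitch[pair]
            assert abs(a.rate - b.rate) <= max(a.stderr, b.stderr)
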