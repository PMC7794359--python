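import numpy as np
import pytest

from slipfret import (
    build_tdp,
    cumulative_dwell_histogram,
    extract_transitions,
    fit_dwell_rate,
    rate_matrix_from_traces,
    simulate_ctmc,
)
from slipfret.kinetics import TransitionEvent, _runs

from conftest import random_reversible_scheme


def brute_force_rle(path):
    """Independent run-length encoder."""
    runs = []
    for s in path:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    return [(s, n) for s, n in runs]


def path_to_events(path, bin_width=0.05):
    return extract_transitions([np.asarray(path)], bin_width, fret_of_state=np.linspace(0.1, 0.9, 9))


class TestExtractTransitions:
    def test_hand_enumerated_example(self):
        """[1,1,1,2,2,1,1,1,1,2]: only the state-2 run of 2 frames is
        uncensored -> one dwell of 0.10 s ending 2 -> 1."""
        events, dwells = path_to_events([1, 1, 1, 2, 2, 1, 1, 1, 1, 2])
        assert len(events) == 2  # 2->1 (dwell 0.10) and 1->2 (dwell 0.20)
        assert dwells[(2, 1)] == pytest.approx([0.10])
        assert dwells[(1, 2)] == pytest.approx([0.20])

    def test_two_state_transitions_alternate(self, rng):
        path = rng.integers(0, 2, 500)
        path = np.array(brute_force_rle(path))[:, 0]  # force alternation
        events, _ = path_to_events(path)
        kinds = [(e.state_start, e.state_end) for e in events]
        for a, b in zip(kinds[:-1], kinds[1:]):
            assert a[1] == b[0]

    def test_run_lengths_match_rle_oracle(self, rng):
        for _ in range(10):
            path = rng.integers(0, 3, 200)
            states, lengths = _runs(path)
            oracle = brute_force_rle(path)
            assert list(zip(states.tolist(), lengths.tolist())) == oracle

    def test_censoring_drops_first_and_last_runs(self):
        events, dwells = path_to_events([0, 1, 0, 1, 0])
        total = sum(v.size for v in dwells.values())
        assert total == 3  # five runs, first and last censored

    def test_single_state_trace_empty(self):
        events, dwells = path_to_events([0, 0, 0, 0])
        assert events == [] and dwells == {}

    def test_dwell_count_conservation(self, rng):
        """Censored + uncensored run durations account for every frame."""
        path = rng.integers(0, 2, 300)
        states, lengths = _runs(path)
        _, dwells = path_to_events(path)
        uncensored = sum(v.sum() for v in dwells.values())
        censored = (lengths[0] + lengths[-1]) * 0.05
        assert uncensored + censored == pytest.approx(path.size * 0.05)


class TestTdp:
    def _two_state_events(self, n=60):
        ev = []
        for i in range(n):
            a, b = (0.3, 0.7) if i % 2 == 0 else (0.7, 0.3)
            ev.append(TransitionEvent(a, b, int(a > b), int(b > a), 0.1, "t", i))
        return ev

    def test_two_state_data_two_mirror_bins(self):
        tdp = build_tdp(self._two_state_events(), min_count=10)
        assert (tdp.counts > 0).sum() == 2
        np.testing.assert_allclose(tdp.counts, tdp.counts.T)
        assert tdp.symmetry_score == pytest.approx(1.0)

    def test_min_count_threshold_zeroes_sparse_bins(self):
        ev = self._two_state_events(18)  # 9 transitions per direction
        tdp = build_tdp(ev, min_count=10)
        assert tdp.counts.sum() == 0
        tdp2 = build_tdp(ev, min_count=2)
        assert tdp2.counts.sum() == 18

    def test_diagonal_bins_always_empty(self):
        ev = [TransitionEvent(0.31, 0.315, 0, 1, 0.1, "t", 0)] * 12  # same bin
        tdp = build_tdp(ev, min_count=1)
        assert np.all(np.diag(tdp.counts) == 0)

    def test_reversible_six_state_simulation_symmetric(self, rng):
        """TDP of a detailed-balance 6-state chain: symmetry score > 0.9."""
        scheme = random_reversible_scheme(6, rng, rate_scale=8.0)
        paths = []
        for s in range(12):
            traj = simulate_ctmc(scheme, 500.0, seed=rng)
            # point-sample at 50 ms to get an idealized-like path
            edges = traj.boundaries()
            tt = np.arange(int(500.0 / 0.05)) * 0.05
            idx = np.clip(np.searchsorted(edges, tt, side="right") - 1, 0, traj.n_segments - 1)
            paths.append(traj.states[idx])
        events, _ = extract_transitions(paths, 0.05, fret_of_state=scheme.fret_map)
        tdp = build_tdp(events, min_count=10)
        assert tdp.symmetry_score > 0.9
        # with the threshold disabled every populated bin has its mirror
        tdp_all = build_tdp(events, min_count=1)
        nz = tdp_all.counts > 0
        assert np.array_equal(nz, nz.T)


class TestDwellRateFit:
    def test_mle_on_exponential_sample(self, rng):
        d = rng.exponential(1 / 3.38, 10_000)
        fit = fit_dwell_rate(d, method="mle", bin_width=1e-6)
        assert fit.rate == pytest.approx(3.38, abs=3 * fit.stderr)

    def test_constant_dwells_inverse_mean(self):
        fit = fit_dwell_rate(np.full(100, 0.5), method="mle")
        assert fit.rate == pytest.approx(2.0)

    def test_lm_histogram_agrees_with_mle(self, rng):
        d = rng.exponential(0.3, 20_000)
        mle = fit_dwell_rate(d, method="mle", bin_width=1e-3)
        lm = fit_dwell_rate(d, method="lm_histogram", bin_width=1e-3)
        assert lm.rate == pytest.approx(mle.rate, rel=0.10)
        assert lm.reduced_chi2 is not None and lm.stderr > 0

    def test_too_few_dwells_flagged(self):
        fit = fit_dwell_rate(np.array([0.5, 0.4]), method="mle")
        assert not fit.ok and np.isnan(fit.rate)


class TestRateMatrix:
    def test_two_state_chain_recovery(self, two_state_scheme, rng):
        """Point-sampled chains at (12.25, 3.38): logm inversion within 10%."""
        paths = []
        for _ in range(40):
            traj = simulate_ctmc(two_state_scheme, 60.0, seed=rng)
            edges = traj.boundaries()
            tt = np.arange(1200) * 0.05
            idx = np.clip(np.searchsorted(edges, tt, side="right") - 1, 0, traj.n_segments - 1)
            paths.append(traj.states[idx])
        rates = rate_matrix_from_traces(paths, 2, 0.05)
        assert rates[(0, 1)].rate == pytest.approx(12.25, rel=0.10)
        assert rates[(1, 0)].rate == pytest.approx(3.38, rel=0.10)

    def test_symmetric_three_state_branching(self, rng):
        """Equal-rate chain: branching fractions 0.5 within binomial error."""
        from slipfret.scheme import KineticScheme

        k = 4.0
        Q = np.full((3, 3), k)
        np.fill_diagonal(Q, -2 * k)
        scheme = KineticScheme([(0, i) for i in range(3)], np.linspace(0.2, 0.8, 3), Q)
        traj = simulate_ctmc(scheme, 5000.0, seed=rng)
        counts = {}
        for a, b in zip(traj.states[:-1], traj.states[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        for i in range(3):
            exits = [counts.get((i, j), 0) for j in range(3) if j != i]
            n = sum(exits)
            frac = exits[0] / n
            assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_detailed_balance_flux(self, rng):
        """Recovered rates satisfy pi_i k_ij ~ pi_j k_ji for a reversible scheme."""
        scheme = random_reversible_scheme(3, rng, rate_scale=6.0)
        pi = scheme.stationary_distribution()
        paths = []
        for _ in range(20):
            traj = simulate_ctmc(scheme, 500.0, seed=rng)
            edges = traj.boundaries()
            tt = np.arange(int(500 / 0.05)) * 0.05
            idx = np.clip(np.searchsorted(edges, tt, side="right") - 1, 0, traj.n_segments - 1)
            paths.append(traj.states[idx])
        rates = rate_matrix_from_traces(paths, 3, 0.05)
        for i in range(3):
            for j in range(i + 1, 3):
                f_ij = pi[i] * rates[(i, j)].rate
                f_ji = pi[j] * rates[(j, i)].rate
                assert f_ij == pytest.approx(f_ji, rel=0.15)

    def test_unobserved_pairs_absent(self):
        paths = [np.array([0, 1, 0, 1, 0, 1, 0])]
        rates = rate_matrix_from_traces(paths, 3, 0.05, min_dwells=1)
        assert (0, 2) not in rates and (2, 0) not in rates


class TestCumulativeDwells:
    def test_single_pair_equals_its_histogram(self, rng):
        d = {(0, 1): rng.exponential(0.3, 500)}
        cum = cumulative_dwell_histogram(d)
        assert cum.dwells.size == 500
        assert cum.mean_dwell == pytest.approx(d[(0, 1)].mean())

    def test_pooled_counts_conserved(self, rng):
        d = {(0, 1): rng.exponential(0.3, 400), (1, 0): rng.exponential(0.1, 600)}
        cum = cumulative_dwell_histogram(d)
        assert cum.dwells.size == 1000
        assert cum.per_pair_n == {(0, 1): 400, (1, 0): 600}

    def test_slower_scheme_has_longer_pooled_dwells(self, rng):
        """Halving all rates (CTG-20/30-like slowdown) increases the pooled
        mean dwell in a paired simulation."""
        from slipfret import JunctionSpec, RateSet, build_scheme

        def pooled_mean(scale, seed):
            scheme = build_scheme(
                JunctionSpec(10, 0), 2, rates=RateSet(12.25 * scale, 3.38 * scale)
            )
            traj = simulate_ctmc(scheme, 2000.0, seed=seed)
            d = {(0, 1): traj.dwells[1:-1][traj.states[1:-1] == 0],
                 (1, 0): traj.dwells[1:-1][traj.states[1:-1] == 1]}
            return cumulative_dwell_histogram(d).mean_dwell

        assert pooled_mean(0.5, 1) > pooled_mean(1.0, 2)
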