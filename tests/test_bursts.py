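import numpy as np
import pytest

from slipfret import detect_bursts, estimate_burst_observables, filter_bursts, static_fret_line
from slipfret.bursts import PhotonBurst
from slipfret.mfd_sim import GREEN_PAR, GREEN_PERP, RED_PAR, PhotonStream


def make_stream(times, channels=None, micro=None):
    times = np.asarray(times, dtype=float)
    ch = np.asarray(channels if channels is not None else np.zeros(times.size), dtype=int)
    mt = np.asarray(micro if micro is not None else np.full(times.size, 1.0), dtype=float)
    return PhotonStream(times, mt, ch, float(times[-1]) if times.size else 0.0, {})


def brute_force_bursts(times, max_gap, min_photons):
    """Oracle: O(n^2) scan over all windows, keeping maximal runs whose
    internal gaps are all <= max_gap and whose size meets the threshold."""
    n = len(times)
    found = []
    i = 0
    for i in range(n):
        if i > 0 and times[i] - times[i - 1] <= max_gap:
            continue  # not a maximal start
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= max_gap:
            j += 1
        if j - i + 1 >= min_photons:
            found.append((i, j + 1))
    return found


class TestDetectBursts:
    def test_single_qualifying_run(self):
        t = np.arange(150) * 1e-5  # 0.01 ms spacing
        bursts = detect_bursts(make_stream(t))
        assert len(bursts) == 1
        assert bursts[0].n_photons == 150

    def test_sparse_photons_no_bursts(self):
        t = np.arange(500) * 2e-4  # all gaps 0.2 ms > 0.1 ms
        assert detect_bursts(make_stream(t)) == []

    def test_empty_stream(self):
        assert detect_bursts(make_stream(np.empty(0))) == []

    def test_matches_exhaustive_window_oracle(self, rng):
        """Burst sets identical to the brute-force scan on random streams."""
        for trial in range(5):
            gaps = rng.choice([2e-5, 5e-4], size=800, p=[0.9, 0.1])
            t = np.cumsum(gaps)
            bursts = detect_bursts(make_stream(t), min_photons=20)
            oracle = brute_force_bursts(t, 1e-4, 20)
            assert [(b.start, b.stop) for b in bursts] == oracle
            # disjointness
            for a, b in zip(bursts[:-1], bursts[1:]):
                assert a.stop <= b.start


class TestFilterBursts:
    def _burst(self, tg, tr, sg=50, sr=50):
        return PhotonBurst(0, sg + sr, sg, sr, tg, tr, 1e-3)

    def test_identical_color_times_kept(self):
        kept = filter_bursts([self._burst(1.0, 1.0)])
        assert len(kept) == 1 and kept[0].pass_filter

    def test_red_leading_by_1ms_rejected(self):
        kept = filter_bursts([self._burst(2.0e-3, 1.0e-3)])
        assert kept == []

    def test_single_color_policy(self):
        b = self._burst(1.0, np.nan, sg=120, sr=0)
        kept = filter_bursts([b])
        assert kept and kept[0].flagged
        assert filter_bursts([self._burst(1.0, np.nan, 120, 0)], keep_single_color=False) == []

    def test_midburst_acceptor_bleach_raises_rejection_rate(self, rng):
        """Simulated in-burst acceptor bleaching (red photons early, green
        late) must be rejected more often than the no-bleach control."""
        def sim(bleach):
            rejected = 0
            for _ in range(100):
                t = np.sort(rng.uniform(0, 2e-3, 200))
                ch = rng.choice([GREEN_PAR, RED_PAR], 200)
                if bleach:
                    cut = 1e-3
                    ch = np.where(t > cut, GREEN_PAR, ch)  # acceptor dark late
                s = make_stream(t, ch)
                bursts = detect_bursts(s, max_interphoton=1e-3, min_photons=50)
                n_pass = len(filter_bursts(bursts))
                rejected += len(bursts) - n_pass
            return rejected

        assert sim(bleach=True) > sim(bleach=False)


class TestObservables:
    def test_proximity_ratio_from_counts(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 1e-3, 100))
        ch = np.array([RED_PAR] * 40 + [GREEN_PAR] * 60)
        s = make_stream(t, ch)
        b = detect_bursts(s, max_interphoton=1e-3, min_photons=50)[0]
        estimate_burst_observables(b, s)
        assert b.e_burst == pytest.approx(0.4)

    def test_lifetime_mle_on_exponential_microtimes(self, rng):
        n = 10_000
        t = np.cumsum(rng.exponential(1e-6, n))
        mt = rng.exponential(2.0, n) % 25.0
        s = make_stream(t, np.full(n, GREEN_PAR), mt)
        b = detect_bursts(s, max_interphoton=1e-2, min_photons=100)[0]
        estimate_burst_observables(b, s)
        assert b.tau_da == pytest.approx(mt.mean(), abs=1e-12)
        assert b.tau_da == pytest.approx(2.0, abs=3 * 2.0 / np.sqrt(n))

    def test_isotropic_emission_zero_anisotropy(self, rng):
        n = 1000
        t = np.cumsum(rng.exponential(1e-6, n))
        ch = np.array([GREEN_PAR, GREEN_PERP] * (n // 2))
        s = make_stream(t, ch)
        b = detect_bursts(s, max_interphoton=1e-2, min_photons=100)[0]
        estimate_burst_observables(b, s)
        assert b.r_d == pytest.approx(0.0, abs=1e-12)

    def test_no_green_photons_flagged(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 1e-3, 120))
        s = make_stream(t, np.full(120, RED_PAR))
        b = detect_bursts(s, max_interphoton=1e-3, min_photons=100)[0]
        estimate_burst_observables(b, s)
        assert b.flagged and np.isnan(b.tau_da)


class TestStaticFretLine:
    @pytest.mark.parametrize("tau,expected", [(4.0, 0.0), (0.0, 1.0), (1.0, 0.75)])
    def test_line_values(self, tau, expected):
        assert static_fret_line(tau, 4.0) == pytest.approx(expected)

    def test_tau_above_tau0_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert static_fret_line(5.0, 4.0) == 0.0

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            static_fret_line(-1.0, 4.0)
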