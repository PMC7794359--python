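import numpy as np
import pytest

from slipfret import bin_trajectory, simulate_ctmc, synthesize_trace
from slipfret.ctmc import StateTrajectory
from slipfret.tirf_sim import FretTrace, read_trace_tsv, write_trace_tsv


def brute_force_bin_average(traj, fret_map, bin_width, n_frames):
    """Independent oracle: per-bin overlap integral of the piecewise-constant
    E(t), computed segment by segment."""
    out = np.zeros(n_frames)
    bounds = traj.boundaries()
    for k in range(n_frames):
        t0, t1 = k * bin_width, (k + 1) * bin_width
        acc = 0.0
        for s, (a, b) in zip(traj.states, zip(bounds[:-1], bounds[1:])):
            overlap = max(0.0, min(b, t1) - max(a, t0))
            acc += overlap * fret_map[s]
        out[k] = acc / bin_width
    return out


class TestBinTrajectory:
    def test_constant_state(self, two_state_scheme):
        traj = StateTrajectory(np.array([1]), np.array([2.0]), 2.0)
        e = bin_trajectory(traj, two_state_scheme, 0.05)
        assert e.size == 40
        np.testing.assert_allclose(e, two_state_scheme.fret_map[1])

    def test_half_split_frame(self, two_state_scheme):
        # 25 ms at E_low then 25 ms at E_high -> midpoint value
        traj = StateTrajectory(np.array([0, 1]), np.array([0.025, 0.025]), 0.05)
        e = bin_trajectory(traj, two_state_scheme, 0.05)
        lo, hi = two_state_scheme.fret_map
        assert e[0] == pytest.approx((lo + hi) / 2, abs=1e-12)

    def test_matches_quadrature_oracle(self, two_state_scheme):
        traj = simulate_ctmc(two_state_scheme, 5.0, seed=9)
        e = bin_trajectory(traj, two_state_scheme, 0.05)
        oracle = brute_force_bin_average(traj, two_state_scheme.fret_map, 0.05, e.size)
        np.testing.assert_allclose(e, oracle, atol=1e-12)

    def test_too_short_trajectory_rejected(self, two_state_scheme):
        traj = StateTrajectory(np.array([0]), np.array([0.01]), 0.01)
        with pytest.raises(ValueError):
            bin_trajectory(traj, two_state_scheme, 0.05)


class TestSynthesizeTrace:
    def test_noiseless_expectation(self):
        e = np.full(100, 0.6)
        tr = synthesize_trace(e, total_rate=1000.0, noise_model="none")
        np.testing.assert_allclose(tr.donor, 400.0)
        np.testing.assert_allclose(tr.acceptor, 600.0)
        np.testing.assert_allclose(tr.e_apparent, 0.6)

    def test_poisson_moments(self):
        e = np.full(10_000, 0.6)
        tr = synthesize_trace(e, total_rate=1000.0, noise_model="poisson", seed=4)
        assert tr.acceptor.mean() == pytest.approx(600.0, abs=3 * np.sqrt(600 / 10_000))
        assert tr.donor.mean() == pytest.approx(400.0, abs=3 * np.sqrt(400 / 10_000))

    def test_frame_count_conserved_through_decoration(self):
        e = np.linspace(0.1, 0.9, 777)
        tr = synthesize_trace(
            e, noise_model="gaussian", background=20.0,
            bleach={"acceptor_lifetime": 10.0}, seed=1,
        )
        assert tr.n_frames == 777

    def test_acceptor_bleach_gives_donor_only_tail(self):
        e = np.full(1200, 0.7)
        tr = synthesize_trace(
            e, total_rate=1000.0, background=5.0,
            bleach={"acceptor_lifetime": 5.0}, seed=8,
        )
        f = tr.metadata["acceptor_bleach_frame"]
        tail = tr.e_apparent[f:]
        assert tail.size > 0
        # zero-FRET peak: background-dominated acceptor, E near 0
        assert np.median(tail) < 0.1
        assert np.median(tr.e_apparent[:f]) > 0.5

    def test_noise_monotonically_widens_e_distribution(self):
        e = np.full(20_000, 0.5)
        stds = [
            synthesize_trace(e, sigma_frac=s, seed=2).e_apparent.std()
            for s in (0.02, 0.05, 0.10)
        ]
        assert stds[0] < stds[1] < stds[2]

    def test_zero_total_frames_flagged(self):
        tr = synthesize_trace(np.array([0.5, 0.5]), total_rate=1.0, noise_model="none",
                              background=0.0)
        assert not tr.zero_total.any()
        tr2 = FretTrace(0.05, np.zeros(3), np.zeros(3), np.zeros(3),
                        zero_total=np.ones(3, bool))
        assert tr2.zero_total.all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            synthesize_trace(np.array([0.5]), total_rate=-1.0)
        with pytest.raises(ValueError):
            synthesize_trace(np.array([0.5]), background=-2.0)
        with pytest.raises(ValueError):
            synthesize_trace(np.array([0.5]), noise_model="cauchy")


class TestTraceIO:
    def test_tsv_round_trip(self, tmp_path):
        e = np.linspace(0.2, 0.8, 50)
        tr = synthesize_trace(e, seed=3, metadata={"trace_index": 7})
        p = tmp_path / "trace_0000.tsv"
        write_trace_tsv(tr, p)
        back = read_trace_tsv(p)
        np.testing.assert_allclose(back.donor, tr.donor, rtol=1e-12)
        np.testing.assert_allclose(back.e_apparent, tr.e_apparent, rtol=1e-12)
        assert back.bin_width == pytest.approx(tr.bin_width)
        assert back.metadata["trace_index"] == 7

    def test_reader_accepts_comma_dialect(self, tmp_path):
        p = tmp_path / "trace.csv"
        p.write_text(
            "frame_index,time_s,donor,acceptor,e_apparent\n"
            "0,0.0,400,600,0.6\n1,0.05,410,590,0.59\n"
        )
        tr = read_trace_tsv(p)
        assert tr.n_frames == 2
        assert tr.acceptor[0] == 600

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError):
            read_trace_tsv(p)
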