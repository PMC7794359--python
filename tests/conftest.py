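import numpy as np
import pytest

from slipfret import JunctionSpec, RateSet, build_scheme


@pytest.fixture
def two_state_scheme():
    """Static 3WJ scheme at the conformational exchange rates (12.25, 3.38)."""
    spec = JunctionSpec(slipout_repeats=10, duplex_repeats=0)
    return build_scheme(spec, conformer_count=2, rates=RateSet(12.25, 3.38, migration=0.0))


@pytest.fixture
def eight_state_scheme():
    """Mobile 3WJ scheme: 4 isomers x 2 conformers, default degenerate map."""
    spec = JunctionSpec(slipout_repeats=10, duplex_repeats=3)
    return build_scheme(spec, conformer_count=2, rates=RateSet(12.25, 3.38, migration=2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_reversible_scheme(n_states, rng, rate_scale=5.0):
    """A detailed-balance CTMC over n_states with random stationary weights.

    Built as k_ij = c_ij / pi_i with symmetric c, so pi_i k_ij = pi_j k_ji
    holds by construction.
    """
    pi = rng.dirichlet(np.ones(n_states) * 3.0)
    c = rng.uniform(0.2, 1.0, (n_states, n_states))
    c = (c + c.T) / 2.0
    Q = c / pi[:, None] * rate_scale / n_states
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    from slipfret.scheme import KineticScheme

    labels = [(0, i) for i in range(n_states)]
    fret = np.linspace(0.1, 0.9, n_states)
    return KineticScheme(state_labels=labels, fret_map=fret, rate_matrix=Q)
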