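"""Kinetic schemes: labelled CTMCs over (isomer, conformer) states with FRET maps.

The generative model of 3WJ dynamics is a continuous-time Markov chain over
``(positional isomer, branchpoint conformer)`` states.  Two processes move the
chain: conformational exchange at the branchpoint (within an isomer, rates
``k_lh`` low->high FRET and ``k_hl`` high->low), and branch migration between
adjacent isomers (plus an optional longer-range jump).  Each state carries a
mean FRET efficiency; degeneracies in that map are what collapse the eight
predicted states of a mobile construct with three duplex repeats down to six
resolvable FRET values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .junction import JunctionSpec, enumerate_isomers

__all__ = [
    "RateSet",
    "KineticScheme",
    "build_scheme",
    "default_fret_map",
    "occupancy_propagator",
]

#: Span of the default evenly spaced FRET values assigned to unique states.
_FRET_SPAN = (0.15, 0.90)


@dataclass(frozen=True)
class RateSet:
    """Rate parameters for a mobile/static scheme, all in s^-1.

    ``low_to_high``/``high_to_low`` are the conformational exchange rates
    shared by all isomers.  ``migration`` connects adjacent isomers (both
    directions), ``jump`` connects isomers two registers apart (default off).
    ``gate_conformer``, if set, restricts migration/jump edges to states in
    that conformer (branch migration gated by branchpoint conformation).
    """

    low_to_high: float = 12.25
    high_to_low: float = 3.38
    migration: float = 2.0
    jump: float = 0.0
    gate_conformer: int | None = None

    def __post_init__(self) -> None:
        for name in ("low_to_high", "high_to_low", "migration", "jump"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")


@dataclass
class KineticScheme:
    """A labelled CTMC with a per-state FRET map.

    Attributes
    ----------
    state_labels
        Ordered ``(isomer_index, conformer_index)`` pairs; state ``i`` of the
        rate matrix is ``state_labels[i]``.
    fret_map
        Mean FRET efficiency of each state, in [0, 1].
    rate_matrix
        Generator matrix Q (s^-1): off-diagonal ``k_ij >= 0``, each diagonal
        entry the negated row sum of the off-diagonals.
    """

    state_labels: list[tuple[int, int]]
    fret_map: np.ndarray
    rate_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.fret_map = np.asarray(self.fret_map, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.state_labels)
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix shape does not match state count")
        if self.fret_map.shape != (n,):
            raise ValueError("fret_map length does not match state count")
        if np.any((self.fret_map < 0) | (self.fret_map > 1)):
            raise ValueError("fret_map values must lie in [0, 1]")
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(self.rate_matrix.sum(axis=1))) > 1e-12 * max(1.0, off.max()):
            raise ValueError("rate_matrix rows must sum to zero")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def exit_rates(self) -> np.ndarray:
        """Total exit rate of each state, ``-Q_ii``."""
        return -np.diag(self.rate_matrix)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi with pi Q = 0, pi >= 0, sum(pi) = 1.

        For a reducible chain this returns one stationary vector (the
        numerically dominant null-space direction of Q^T).
        """
        ns = scipy.linalg.null_space(self.rate_matrix.T)
        if ns.shape[1] == 0:  # pragma: no cover - Q always has a null space
            raise np.linalg.LinAlgError("no stationary distribution found")
        v = ns[:, 0]
        v = np.abs(v)
        return v / v.sum()

    def unique_fret_values(self, decimals: int = 9) -> np.ndarray:
        """Distinct FRET values in the map (sorted ascending)."""
        return np.unique(np.round(self.fret_map, decimals))


def default_fret_map(n_isomers: int, n_conformers: int) -> np.ndarray:
    """Default per-state FRET efficiencies.

    Unique values are evenly spaced over ``[0.15, 0.90]``.  For the canonical
    mobile construct (four isomers x two conformers) the eight states collapse
    to six unique values: both conformers of the last isomer (P4) share one
    value, which also coincides with the high-FRET conformer of P3 — i.e. the
    P4 pair is unresolved and overlaps one P3 state.  Any other geometry gets
    one distinct value per state.
    """
    n_states = n_isomers * n_conformers
    if n_isomers == 4 and n_conformers == 2:
        values = np.linspace(*_FRET_SPAN, 6)
        # (isomer, conformer) order: (P1,c0),(P1,c1),(P2,c0),...,(P4,c1)
        # c0 = low-FRET conformer, c1 = high-FRET conformer of each isomer.
        return np.array([
            values[0], values[5],   # P1
            values[1], values[4],   # P2
            values[2], values[3],   # P3
            values[3], values[3],   # P4: degenerate pair, overlapping P3 high
        ])
    return np.linspace(*_FRET_SPAN, n_states)


def build_scheme(
    spec: JunctionSpec,
    conformer_count: int = 2,
    rates: RateSet | None = None,
    fret_values: np.ndarray | list[float] | None = None,
    rate_overrides: dict[tuple[int, int], float] | None = None,
) -> KineticScheme:
    """Build the CTMC kinetic scheme of a 3WJ construct.

    States are ordered ``(isomer, conformer)`` with conformer fastest, i.e.
    state index ``= isomer * conformer_count + conformer``.  Conformational
    edges connect successive conformers within an isomer (``c -> c+1`` at
    ``low_to_high``, ``c+1 -> c`` at ``high_to_low``).  Migration edges
    connect the same conformer of adjacent isomers at ``rates.migration``
    (both directions); ``rates.jump`` adds edges between isomers two
    registers apart (e.g. P1 <-> P3).  ``rate_overrides`` maps
    ``(state_i, state_j)`` to a rate and replaces any default edge,
    allowing a fully per-edge parameterization.

    Parameters
    ----------
    spec
        The junction construct; ``spec.duplex_repeats + 1`` isomers.
    conformer_count
        Branchpoint conformers per isomer (>= 1; 2 reproduces the observed
        two-state exchange).
    rates
        Shared rate parameters; defaults to the static-CTG exchange pair.
    fret_values
        Per-state mean FRET efficiencies; ``None`` uses :func:`default_fret_map`.

    Returns
    -------
    KineticScheme
        Scheme with ``(m + 1) * conformer_count`` states.
    """
    if conformer_count < 1:
        raise ValueError("conformer_count must be >= 1")
    rates = rates or RateSet()
    n_iso = spec.n_isomers
    n = n_iso * conformer_count

    Q = np.zeros((n, n))
    idx = lambda iso, c: iso * conformer_count + c  # noqa: E731

    for iso in range(n_iso):
        for c in range(conformer_count - 1):
            Q[idx(iso, c), idx(iso, c + 1)] = rates.low_to_high
            Q[idx(iso, c + 1), idx(iso, c)] = rates.high_to_low
    for c in range(conformer_count):
        if rates.gate_conformer is not None and c != rates.gate_conformer:
            continue
        for iso in range(n_iso - 1):
            Q[idx(iso, c), idx(iso + 1, c)] = rates.migration
            Q[idx(iso + 1, c), idx(iso, c)] = rates.migration
        if rates.jump > 0:
            for iso in range(n_iso - 2):
                Q[idx(iso, c), idx(iso + 2, c)] = rates.jump
                Q[idx(iso + 2, c), idx(iso, c)] = rates.jump

    if rate_overrides:
        for (i, j), k in rate_overrides.items():
            if i == j:
                raise ValueError("rate_overrides must address off-diagonal edges")
            if k < 0:
                raise ValueError("override rates must be >= 0")
            Q[i, j] = k

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    if fret_values is None:
        fret = default_fret_map(n_iso, conformer_count)
    else:
        fret = np.asarray(fret_values, dtype=float)

    labels = [(iso, c) for iso in range(n_iso) for c in range(conformer_count)]
    return KineticScheme(state_labels=labels, fret_map=fret, rate_matrix=Q)


def occupancy_propagator(
    scheme: KineticScheme,
    t: float,
    initial_distribution: np.ndarray | list[float],
) -> np.ndarray:
    """Propagate a state distribution for time ``t``: ``p(t) = p(0) expm(Q t)``.

    Serves as the closed-form oracle for empirical occupancies from sampled
    trajectories.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    p0 = np.asarray(initial_distribution, dtype=float)
    if p0.shape != (scheme.n_states,):
        raise ValueError("initial_distribution has wrong length")
    if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < -1e-12):
        raise ValueError("initial_distribution must be a probability vector")
    return p0 @ scipy.linalg.expm(scheme.rate_matrix * t)
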