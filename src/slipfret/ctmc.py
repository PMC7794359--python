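"""Exact stochastic simulation of kinetic-scheme state trajectories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import KineticScheme

__all__ = ["StateTrajectory", "simulate_ctmc"]


@dataclass
class StateTrajectory:
    """A realization of a CTMC: ordered (state, dwell) segments.

    ``states[k]`` is occupied for ``dwells[k]`` seconds; dwells sum to
    ``total_duration``.  Consecutive segments always differ in state (the
    final segment may be truncated by the requested duration).
    """

    states: np.ndarray      # int state indices, one per segment
    dwells: np.ndarray      # segment durations, s
    total_duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.states.shape != self.dwells.shape:
            raise ValueError("states and dwells must have equal length")
        if np.any(self.dwells <= 0):
            raise ValueError("all dwell durations must be > 0")
        if abs(self.dwells.sum() - self.total_duration) > 1e-9:
            raise ValueError("dwells must sum to total_duration")
        if self.states.size > 1 and np.any(np.diff(self.states) == 0):
            raise ValueError("consecutive segments must change state")

    @property
    def n_segments(self) -> int:
        return self.states.size

    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time (length n_segments+1)."""
        return np.concatenate(([0.0], np.cumsum(self.dwells)))

    def state_at(self, t: float) -> int:
        """State occupied at time ``t`` (right-continuous)."""
        if not 0 <= t <= self.total_duration:
            raise ValueError("t outside trajectory")
        k = np.searchsorted(self.boundaries(), t, side="right") - 1
        return int(self.states[min(k, self.n_segments - 1)])

    def occupancy(self, n_states: int) -> np.ndarray:
        """Fraction of total time spent in each of ``n_states`` states."""
        occ = np.bincount(self.states, weights=self.dwells, minlength=n_states)
        return occ / self.total_duration


def simulate_ctmc(
    scheme: KineticScheme,
    duration: float,
    initial_state: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> StateTrajectory:
    """Sample a state trajectory by the Gillespie algorithm.

    Dwell in state ``i`` is Exponential(-Q_ii); the successor ``j`` is drawn
    with probability ``k_ij / sum_j k_ij``.  The trajectory is truncated at
    ``duration``.  States with zero exit rate are absorbing: the trajectory
    ends with a single terminal segment.

    Parameters
    ----------
    initial_state
        Starting state index; ``None`` draws from the stationary distribution.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    exit_rates = scheme.exit_rates()
    n = scheme.n_states
    # Per-state successor distributions (rows with zero exit are absorbing).
    jump_probs = scheme.rate_matrix.copy()
    np.fill_diagonal(jump_probs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_probs = np.where(
            exit_rates[:, None] > 0, jump_probs / np.where(exit_rates == 0, 1.0, exit_rates)[:, None], 0.0
        )
    jump_cdf = np.cumsum(jump_probs, axis=1)

    if initial_state is None:
        state = int(rng.choice(n, p=scheme.stationary_distribution()))
    else:
        if not 0 <= initial_state < n:
            raise ValueError("initial_state out of range")
        state = int(initial_state)

    states: list[int] = []
    dwells: list[float] = []
    t = 0.0
    while t < duration:
        k_exit = exit_rates[state]
        if k_exit <= 0.0:  # absorbing
            dwell = duration - t
            next_state = state
        else:
            dwell = rng.exponential(1.0 / k_exit)
            if t + dwell >= duration:
                dwell = duration - t
                next_state = state
            else:
                next_state = int(np.searchsorted(jump_cdf[state], rng.random(), side="right"))
        if dwell > 0:
            if states and states[-1] == state:
                dwells[-1] += dwell  # merge truncation remainder
            else:
                states.append(state)
                dwells.append(dwell)
        t += dwell
        if next_state == state and (k_exit <= 0.0 or t >= duration):
            break
        state = next_state

    # Guard against floating-point shortfall in the final segment.
    total = sum(dwells)
    if dwells and abs(total - duration) > 0:
        dwells[-1] += duration - total
    return StateTrajectory(np.array(states), np.array(dwells), duration)
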