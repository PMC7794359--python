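"""Hidden Markov idealization of binned FRET traces.

Traces are modelled as a discrete-time HMM with one Gaussian emission per
FRET state (the convention of camera-trace HMM tools for this assay).
Fitting is maximum likelihood by Baum-Welch over a collection of traces,
with starting emission means evenly distributed over [0, 1] plus randomized
restarts; idealization is the Viterbi most-likely state path.  The
forward/backward recursions are batched over equal-length traces so that a
few hundred one-minute traces fit in well under a minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tirf_sim import FretTrace

__all__ = [
    "HmmModel",
    "IdealizedTrace",
    "StitchedSeries",
    "fit_hmm",
    "fit_hmm_blur",
    "forward_log_likelihood",
    "viterbi_path",
    "viterbi_boundary_path",
    "idealize",
    "stitch_traces",
]

_SIGMA_FLOOR = 1e-3
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmModel:
    """A fitted Gaussian-emission HMM.

    States are ordered by ascending emission mean.  ``transmat`` is the
    per-frame transition probability matrix (rows sum to 1); ``history`` the
    per-iteration log-likelihoods of the winning restart.
    """

    means: np.ndarray
    sigmas: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False
    history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return self.means.size

    def validate(self) -> None:
        if np.any(self.sigmas <= 0):
            raise ValueError("emission standard deviations must be > 0")
        if np.max(np.abs(self.transmat.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")


@dataclass
class IdealizedTrace:
    """Viterbi state path over one trace, with per-frame idealized E."""

    states: np.ndarray
    e_idealized: np.ndarray
    source_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.states.size


@dataclass
class StitchedSeries:
    """Concatenation of several traces with recorded internal boundaries.

    ``boundaries`` are the start indices of every trace after the first;
    dwells spanning a boundary must be discarded downstream.
    """

    values: np.ndarray
    boundaries: np.ndarray

    def split(self) -> list[np.ndarray]:
        return np.split(self.values, self.boundaries)


def _as_series(traces) -> list[np.ndarray]:
    out = []
    for tr in traces:
        x = tr.e_apparent if isinstance(tr, FretTrace) else np.asarray(tr, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("each trace must be a non-empty 1-D series")
        out.append(x)
    return out


def _log_emission(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Log N(x | mean_k, sigma_k) with shape x.shape + (K,)."""
    z = (x[..., None] - means) / sigmas
    return -0.5 * (z * z + _LOG2PI) - np.log(sigmas)


def _forward_backward(batch: np.ndarray, model_params):
    """Scaled forward-backward on a (B, T) batch.

    Returns per-sequence log-likelihoods and the pooled sufficient
    statistics (gamma sums, gamma-weighted moments, xi sums, start counts).
    """
    means, sigmas, A, pi = model_params
    B_, T = batch.shape
    K = means.size
    em = np.exp(_log_emission(batch, means, sigmas)) + 1e-300  # (B,T,K)

    alpha = np.empty((B_, T, K))
    c = np.empty((B_, T))
    a = pi * em[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * em[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((B_, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = em[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]  # (B,K)
        beta[:, t] = w @ A.T
        # xi_t[k,l] = alpha_t[k] A[k,l] w[l]; pooled over batch and time
        xi_sum += alpha[:, t].T @ w * A

    gamma = alpha * beta  # (B,T,K), rows sum to 1
    loglik = np.log(c).sum(axis=1)
    g_flat = gamma.reshape(-1, K)
    x_flat = batch.reshape(-1)
    stats = {
        "gamma_sum": g_flat.sum(axis=0),
        "gamma_x": g_flat.T @ x_flat,
        "gamma_xx": g_flat.T @ (x_flat * x_flat),
        "xi_sum": xi_sum,
        "start": gamma[:, 0].sum(axis=0),
        "n_obs": float(g_flat.shape[0]),
    }
    return loglik, stats


def _em_fit(groups, K, means0, sigmas0, A0, pi0, max_iter, tol):
    means, sigmas, A, pi = means0.copy(), sigmas0.copy(), A0.copy(), pi0.copy()
    history = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for it in range(max_iter):
        total_ll = 0.0
        agg = None
        for batch in groups:
            ll, stats = _forward_backward(batch, (means, sigmas, A, pi))
            total_ll += ll.sum()
            if agg is None:
                agg = stats
            else:
                for k in stats:
                    agg[k] = agg[k] + stats[k]
        # EM must not decrease the likelihood (up to round-off).
        if total_ll < prev - 1e-8 * max(1.0, abs(prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {prev} -> {total_ll}"
            )
        history.append(total_ll)
        n_iter = it + 1
        if np.isfinite(prev) and abs(total_ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = total_ll

        g = agg["gamma_sum"]
        means = agg["gamma_x"] / g
        var = agg["gamma_xx"] / g - means**2
        sigmas = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        xi = agg["xi_sum"]
        rows = xi.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi / np.where(rows == 0, 1.0, rows), 1.0 / K)
        pi = agg["start"] / agg["start"].sum()
    return means, sigmas, A, pi, np.array(history), converged, n_iter


def fit_hmm(
    traces,
    n_states: int,
    restarts: int = 10,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmModel:
    """Fit a Gaussian-emission HMM to a collection of FRET traces.

    Restart 0 starts from emission means evenly distributed over [0, 1]
    (``linspace(1, K, K) / (K + 1)``); further restarts jitter those means.
    The best model by log-likelihood is returned, states sorted by emission
    mean.  Models whose means collapse within 1e-3 are flagged
    ``degenerate``.

    Parameters
    ----------
    traces
        Iterable of :class:`FretTrace` or 1-D ``e_apparent`` arrays; unequal
        lengths are allowed (equal-length traces are batched internally).
    """
    series = _as_series(traces)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = n_states

    by_len: dict[int, list[np.ndarray]] = {}
    for x in series:
        by_len.setdefault(x.size, []).append(x)
    groups = [np.stack(v) for v in by_len.values()]

    base_means = np.linspace(1, K, K) / (K + 1)
    sigmas0 = np.full(K, 0.1)
    A0 = np.full((K, K), 0.05 / max(K - 1, 1))
    np.fill_diagonal(A0, 0.95)
    pi0 = np.full(K, 1.0 / K)

    best = None
    for r in range(max(restarts, 1)):
        means0 = base_means if r == 0 else np.clip(
            base_means + rng.uniform(-0.1, 0.1, K), 0.0, 1.0
        )
        means, sigmas, A, pi, hist, conv, n_iter = _em_fit(
            groups, K, means0, sigmas0, A0, pi0, max_iter, tol
        )
        ll = hist[-1]
        if best is None or ll > best[0]:
            best = (ll, means, sigmas, A, pi, hist, conv, n_iter)

    ll, means, sigmas, A, pi, hist, conv, n_iter = best
    order = np.argsort(means)
    means, sigmas = means[order], sigmas[order]
    A = A[np.ix_(order, order)]
    pi = pi[order]
    degen = K > 1 and np.any(np.diff(means) < 1e-3)
    model = HmmModel(
        means=means,
        sigmas=sigmas,
        transmat=A,
        startprob=pi,
        log_likelihood=float(ll),
        n_iter=n_iter,
        converged=conv,
        degenerate=bool(degen),
        history=hist,
    )
    model.validate()
    return model


def forward_log_likelihood(model: HmmModel, trace) -> float:
    """Log-likelihood of one trace under the model (scaled forward pass)."""
    (x,) = _as_series([trace])
    ll, _ = _forward_backward(
        x[None, :], (model.means, model.sigmas, model.transmat, model.startprob)
    )
    return float(ll[0])


def viterbi_path(model: HmmModel, trace) -> np.ndarray:
    """Most-likely state path of one trace (Viterbi, log space)."""
    (x,) = _as_series([trace])
    logA = np.log(model.transmat + 1e-300)
    logB = _log_emission(x, model.means, model.sigmas)
    T, K = logB.shape
    delta = np.log(model.startprob + 1e-300) + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_log_probability(model: HmmModel, trace, path: np.ndarray) -> float:
    """Joint log-probability of (path, observations) under the model."""
    (x,) = _as_series([trace])
    path = np.asarray(path, dtype=int)
    logB = _log_emission(x, model.means, model.sigmas)
    lp = np.log(model.startprob[path[0]] + 1e-300) + logB[0, path[0]]
    lp += np.sum(np.log(model.transmat[path[:-1], path[1:]] + 1e-300))
    lp += logB[np.arange(1, x.size), path[1:]].sum()
    return float(lp)


def idealize(trace, model: HmmModel, source_id: str = "") -> IdealizedTrace:
    """Idealize one trace: Viterbi path plus per-frame state emission mean."""
    path = viterbi_path(model, trace)
    return IdealizedTrace(states=path, e_idealized=model.means[path], source_id=source_id)


# ---------------------------------------------------------------------------
# Motional-blur-aware variant
#
# A camera frame integrates the trajectory over its full exposure, so a frame
# containing a transition shows an intermediate E (the duration-weighted
# average), which a purely state-wise Gaussian emission model must absorb into
# inflated state widths — biasing transition probabilities and hence rates at
# exchange rates comparable to the frame rate.  The blur-aware model instead
# conditions each frame's emission on the *pair* of states at the frame
# boundaries: equal boundary states emit the plain state Gaussian, while a
# transition frame i -> j emits a uniform average u*mu_i + (1-u)*mu_j
# (u ~ U(0,1), one transition per frame) convolved with the channel noise.
# The inferred boundary chain is then the point-sampled CTMC, whose per-frame
# transition matrix is exactly expm(Q dt) and inverts without blur bias.
# ---------------------------------------------------------------------------

from scipy.special import ndtr


def _edge_emission(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Emission densities conditioned on frame-boundary state pairs.

    Returns shape ``x.shape + (K, K)``: entry (i, j) is the density of a
    frame that starts in state i and ends in state j.
    """
    K = means.size
    lo = np.minimum.outer(means, means)          # (K,K)
    hi = np.maximum.outer(means, means)
    s_pair = 0.5 * (sigmas[:, None] + sigmas[None, :])
    span = hi - lo
    xb = x[..., None, None]
    # Uniform(lo,hi) + N(0,s): density = (Phi((x-lo)/s) - Phi((x-hi)/s)) / span
    with np.errstate(invalid="ignore", divide="ignore"):
        flat = (ndtr((xb - lo) / s_pair) - ndtr((xb - hi) / s_pair)) / span
    z = (xb - means[None, :]) / sigmas[None, :]  # gaussian at the *end* state
    gauss_end = np.exp(-0.5 * z * z) / (sigmas[None, :] * np.sqrt(2 * np.pi))
    narrow = span < 3.0 * s_pair  # degenerate/nearby pair: fall back to Gaussian
    em = np.where(narrow, gauss_end, flat)
    diag = np.arange(K)
    zd = (x[..., None] - means) / sigmas
    em[..., diag, diag] = np.exp(-0.5 * zd * zd) / (sigmas * np.sqrt(2 * np.pi))
    return em + 1e-300


def _forward_backward_blur(batch: np.ndarray, params):
    """Scaled forward-backward over the boundary-state chain of a (B, T)
    batch; observations live on edges.  Returns per-sequence log-likelihoods
    and pooled sufficient statistics."""
    means, sigmas, A, pi = params
    B_, T = batch.shape
    K = means.size
    em = _edge_emission(batch, means, sigmas)          # (B,T,K,K)
    W = em * A                                          # edge weights

    alpha = np.empty((B_, T + 1, K))
    c = np.ones((B_, T + 1))
    alpha[:, 0] = pi
    for t in range(T):
        a = np.einsum("bi,bij->bj", alpha[:, t], W[:, t])
        c[:, t + 1] = a.sum(axis=1)
        alpha[:, t + 1] = a / c[:, t + 1, None]

    beta = np.empty((B_, T + 1, K))
    beta[:, T] = 1.0
    xi_sum = np.zeros((K, K))
    xi_diag_x = np.zeros(K)
    xi_diag_xx = np.zeros(K)
    xi_diag_n = np.zeros(K)
    for t in range(T - 1, -1, -1):
        bnext = beta[:, t + 1] / c[:, t + 1, None]
        beta[:, t] = np.einsum("bij,bj->bi", W[:, t], bnext)
        xi = alpha[:, t, :, None] * W[:, t] * bnext[:, None, :]  # (B,K,K)
        xi_sum += xi.sum(axis=0)
        d = np.einsum("bkk->bk", xi)                   # diagonal responsibilities
        x_t = batch[:, t]
        xi_diag_n += d.sum(axis=0)
        xi_diag_x += d.T @ x_t
        xi_diag_xx += d.T @ (x_t * x_t)

    gamma0 = alpha[:, 0] * beta[:, 0]
    gamma0 /= gamma0.sum(axis=1, keepdims=True)
    loglik = np.log(c[:, 1:]).sum(axis=1)
    stats = {
        "xi_sum": xi_sum,
        "diag_n": xi_diag_n,
        "diag_x": xi_diag_x,
        "diag_xx": xi_diag_xx,
        "start": gamma0.sum(axis=0),
    }
    return loglik, stats


def fit_hmm_blur(
    traces,
    n_states: int,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    init: HmmModel | None = None,
    restarts: int = 3,
) -> HmmModel:
    """Fit the motional-blur-aware HMM (pair-conditioned emissions).

    Emission means and widths are re-estimated from the *pure* frames only
    (equal boundary states), so blurred transition frames no longer inflate
    state widths.  Initialized from a plain :func:`fit_hmm` fit unless
    ``init`` is given.  The fitted ``transmat`` estimates the point-sampled
    chain ``expm(Q dt)`` and is therefore suitable for direct rate-matrix
    inversion.
    """
    series = _as_series(traces)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if init is None:
        init = fit_hmm(series, n_states, restarts=restarts, seed=rng, max_iter=200)
    K = n_states
    by_len: dict[int, list[np.ndarray]] = {}
    for x in series:
        by_len.setdefault(x.size, []).append(x)
    groups = [np.stack(v) for v in by_len.values()]

    means, sigmas = init.means.copy(), init.sigmas.copy()
    A, pi = init.transmat.copy(), init.startprob.copy()
    # The emission update below refits means/widths from pure-frame
    # responsibilities only; that is a generalized-EM step (the off-diagonal
    # edge emissions share those parameters), so the likelihood is tracked
    # and the best-scoring parameters kept rather than asserting strict
    # monotonicity as in the plain Baum-Welch fit.
    prev = -np.inf
    history = []
    best = None
    converged = False
    n_iter = 0
    for it in range(max_iter):
        total_ll = 0.0
        agg = None
        for batch in groups:
            ll, stats = _forward_backward_blur(batch, (means, sigmas, A, pi))
            total_ll += ll.sum()
            if agg is None:
                agg = stats
            else:
                for k in stats:
                    agg[k] = agg[k] + stats[k]
        history.append(total_ll)
        n_iter = it + 1
        if best is None or total_ll > best[0]:
            best = (total_ll, means.copy(), sigmas.copy(), A.copy(), pi.copy())
        if total_ll < prev - 1e-8 * max(1.0, abs(prev)):
            converged = True  # generalized-EM step overshot; keep best
            break
        if np.isfinite(prev) and abs(total_ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = total_ll

        xi = agg["xi_sum"]
        A = xi / xi.sum(axis=1, keepdims=True)
        pi = agg["start"] / agg["start"].sum()
        n = np.maximum(agg["diag_n"], 1e-12)
        means = agg["diag_x"] / n
        var = agg["diag_xx"] / n - means**2
        sigmas = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
    _, means, sigmas, A, pi = best

    order = np.argsort(means)
    model = HmmModel(
        means=means[order],
        sigmas=sigmas[order],
        transmat=A[np.ix_(order, order)],
        startprob=pi[order],
        log_likelihood=float(max(history)),
        n_iter=n_iter,
        converged=converged,
        degenerate=bool(K > 1 and np.any(np.diff(means[order]) < 1e-3)),
        history=np.array(history),
    )
    model.validate()
    return model


def viterbi_boundary_path(model: HmmModel, trace) -> np.ndarray:
    """Most-likely boundary-state path (length n_frames + 1) under the
    blur-aware model; run lengths of this chain are point-sampled dwells."""
    (x,) = _as_series([trace])
    logW = np.log(_edge_emission(x, model.means, model.sigmas)) + np.log(
        model.transmat + 1e-300
    )
    T = x.size
    K = model.n_states
    delta = np.log(model.startprob + 1e-300)
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(T):
        cand = delta[:, None] + logW[t]
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)]
    path = np.empty(T + 1, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, -1, -1):
        path[t] = psi[t][path[t + 1]]
    return path


def stitch_traces(traces) -> StitchedSeries:
    """Concatenate traces end-to-end with recorded boundaries.

    The returned boundaries let downstream dwell extraction drop any dwell
    spanning a join between molecules.
    """
    series = _as_series(traces)
    lengths = np.array([s.size for s in series])
    boundaries = np.cumsum(lengths)[:-1]
    return StitchedSeries(values=np.concatenate(series), boundaries=boundaries)
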