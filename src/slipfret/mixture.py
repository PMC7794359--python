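"""Gaussian mixture fitting of burst FRET-efficiency histograms.

Burst E histograms are fitted by maximum likelihood (EM on the unbinned
values) to one donor-only component whose mean is constrained near zero
plus N free FRET components.  A model-selection mode scans N over 1..8 and
picks the BIC optimum — the route by which the number of resolvable FRET
states of a construct is counted.  A binned least-squares mode is offered
for parity with histogram-fitting workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

__all__ = ["MixtureFit", "fit_fret_histogram", "select_n_fret", "fit_fret_histogram_binned"]

_DONOR_ONLY_BOX = (-0.02, 0.05)  # allowed donor-only mean range
_SIGMA_FLOOR = 5e-3
_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture over burst E values.

    When ``donor_only`` is True, component 0 is the donor-only peak (mean
    constrained to [-0.02, 0.05]); FRET components follow, sorted by mean.
    """

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    donor_only: bool
    log_likelihood: float
    bic: float
    n_samples: int
    converged: bool = True
    icl: float = np.nan

    @property
    def n_components(self) -> int:
        return self.means.size

    @property
    def n_fret(self) -> int:
        return self.n_components - (1 if self.donor_only else 0)

    @property
    def fret_means(self) -> np.ndarray:
        return self.means[1:] if self.donor_only else self.means

    @property
    def donor_only_weight(self) -> float:
        return float(self.weights[0]) if self.donor_only else 0.0


def _em(x, means, sigmas, weights, donor_only, max_iter, tol):
    n = x.size
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        z = (x[:, None] - means) / sigmas
        log_comp = -0.5 * z * z - np.log(sigmas * _SQRT2PI) + np.log(weights + 1e-300)
        m = log_comp.max(axis=1, keepdims=True)
        p = np.exp(log_comp - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        resp = p / tot
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = resp.T @ x / nk
        if donor_only:
            means[0] = np.clip(means[0], *_DONOR_ONLY_BOX)
        var = resp.T @ (x * x) / nk - means**2
        sigmas = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
    return means, sigmas, weights, prev if not converged else ll, converged


def _peak_means(x: np.ndarray, n: int) -> np.ndarray:
    """Histogram-peak-guided starting means: centers of the ``n`` tallest
    non-adjacent local maxima of a lightly smoothed 50-bin histogram,
    padded with evenly spaced values if fewer peaks exist."""
    counts, edges = np.histogram(x, bins=50, range=(0.0, 1.0))
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    is_max = (smooth >= np.roll(smooth, 1)) & (smooth >= np.roll(smooth, -1)) & (smooth > 0)
    order = np.argsort(smooth[is_max])[::-1]
    cand = centers[is_max][order]
    picked: list[float] = []
    for c in cand:
        if all(abs(c - p) > 0.04 for p in picked):
            picked.append(float(c))
        if len(picked) == n:
            break
    if len(picked) < n:
        picked += list(np.linspace(0.1, 0.95, n - len(picked)))
    return np.sort(np.array(picked[:n]))


def fit_fret_histogram(
    e_values: np.ndarray,
    n_fret_states: int,
    donor_only: bool = True,
    n_starts: int = 6,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_bursts: int = 50,
) -> MixtureFit:
    """Fit the burst-E mixture by maximum likelihood with multi-start EM.

    Deterministic starts place FRET means at histogram peaks, at evenly
    spaced quantiles of the non-zero-peak values, and evenly over
    [0.1, 0.95]; further starts jitter the quantile means.  Returns the
    best-likelihood fit, FRET components sorted by mean, flagged
    ``converged=False`` if no restart converged.

    Raises if fewer than ``min_bursts`` values are supplied.
    """
    x = np.asarray(e_values, dtype=float)
    if x.size < min_bursts:
        raise ValueError(f"need >= {min_bursts} bursts, got {x.size}")
    if n_fret_states < 1:
        raise ValueError("n_fret_states must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = n_fret_states + (1 if donor_only else 0)

    fret_x = x[x > 0.1] if donor_only and np.any(x > 0.1) else x
    qs = np.quantile(fret_x, np.linspace(0.1, 0.9, n_fret_states))
    inits = [
        _peak_means(fret_x, n_fret_states),
        qs,
        np.linspace(0.1, 0.95, n_fret_states),
    ]
    while len(inits) < max(n_starts, 1):
        inits.append(np.clip(qs + rng.normal(0, 0.05, n_fret_states), 0.0, 1.0))
    best = None
    for fret_means in inits[: max(n_starts, 3)]:
        if donor_only:
            means = np.concatenate(([0.0], np.sort(fret_means)))
            sigmas = np.concatenate(([0.02], np.full(n_fret_states, 0.03)))
        else:
            means = np.sort(fret_means)
            sigmas = np.full(n_fret_states, 0.03)
        weights = np.full(K, 1.0 / K)
        out = _em(x, means.copy(), sigmas.copy(), weights, donor_only, max_iter, tol)
        if best is None or out[3] > best[3]:
            best = out
    means, sigmas, weights, ll, converged = best
    return _package_fit(x, means, sigmas, weights, donor_only, ll, converged)


def _package_fit(x, means, sigmas, weights, donor_only, ll, converged) -> MixtureFit:
    """Order components, attach BIC/ICL, and wrap into a MixtureFit."""
    if donor_only:
        order = np.concatenate(([0], 1 + np.argsort(means[1:])))
    else:
        order = np.argsort(means)
    means, sigmas, weights = means[order], sigmas[order], weights[order]
    n_params = 3 * means.size - 1
    bic = -2.0 * ll + n_params * np.log(x.size)
    # ICL = BIC + 2 * assignment entropy; penalizes overlapping components
    # and is robust to the heavier-than-Gaussian tails of proximity ratios
    # pooled over variable burst sizes.
    z = (x[:, None] - means) / sigmas
    lc = -0.5 * z * z - np.log(sigmas * _SQRT2PI) + np.log(weights + 1e-300)
    m = lc.max(axis=1, keepdims=True)
    p = np.exp(lc - m)
    resp = p / p.sum(axis=1, keepdims=True)
    entropy = -float(np.sum(resp * np.log(resp + 1e-300)))
    return MixtureFit(
        means=means,
        sigmas=sigmas,
        weights=weights,
        donor_only=donor_only,
        log_likelihood=ll,
        bic=bic,
        n_samples=x.size,
        converged=converged,
        icl=bic + 2.0 * entropy,
    )


def _refit_from(x, fit: MixtureFit, means, sigmas, weights, score, max_iter=500, tol=1e-8):
    """Run EM from an explicit start; keep the result if it improves the
    model-selection score (ICL-style classification criterion, or plain
    likelihood/BIC)."""
    m, s, w, ll, conv = _em(
        x, np.asarray(means, float), np.asarray(sigmas, float),
        np.asarray(weights, float), fit.donor_only, max_iter, tol,
    )
    cand = _package_fit(x, m, s, w, fit.donor_only, ll, conv)
    return cand if score(cand) < score(fit) else fit


def _merge_closest(fit: MixtureFit):
    """Warm start with one fewer component: pool the two closest FRET comps."""
    lo = 1 if fit.donor_only else 0
    d = np.diff(fit.means[lo:])
    i = lo + int(np.argmin(d))
    m, s, w = fit.means.copy(), fit.sigmas.copy(), fit.weights.copy()
    wi, wj = w[i], w[i + 1]
    mu = (wi * m[i] + wj * m[i + 1]) / (wi + wj)
    var = (wi * (s[i] ** 2 + (m[i] - mu) ** 2) + wj * (s[i + 1] ** 2 + (m[i + 1] - mu) ** 2)) / (wi + wj)
    m[i], s[i], w[i] = mu, np.sqrt(var), wi + wj
    keep = np.arange(m.size) != i + 1
    return m[keep], s[keep], w[keep]


def _split_widest(fit: MixtureFit):
    """Warm start with one more component: split the highest-variance-mass
    FRET component into mean -+ sigma halves."""
    lo = 1 if fit.donor_only else 0
    i = lo + int(np.argmax(fit.weights[lo:] * fit.sigmas[lo:] ** 2))
    m, s, w = fit.means, fit.sigmas, fit.weights
    m2 = np.concatenate([m, [m[i] + s[i]]])
    s2 = np.concatenate([s, [max(s[i] / 2, 1e-2)]])
    w2 = np.concatenate([w, [w[i] / 2]])
    m2[i] -= s[i]
    s2[i] = max(s[i] / 2, 1e-2)
    w2[i] /= 2
    return m2, s2, w2 / w2.sum()


def select_n_fret(
    e_values: np.ndarray,
    max_states: int = 8,
    donor_only: bool = True,
    seed: int | np.random.Generator | None = None,
    criterion: str = "icl",
    **kwargs,
) -> tuple[int, dict[int, MixtureFit]]:
    """Choose the number of FRET components over 1..``max_states``.

    Each candidate N is fitted by multi-start EM and then refined by
    cascade warm starts (merging the two closest components of the N+1
    fit; splitting the broadest component of the N-1 fit).  Within each N
    the candidate optimizing the selection criterion itself is retained
    (for ICL this is the usual classification-likelihood refinement: a
    higher-likelihood solution that splits a state into strongly
    overlapping shadows is rejected in favor of the well-separated one),
    which guards the across-N comparison against local optima.

    ``criterion`` is ``"icl"`` (default) or ``"bic"``.  Plain BIC tends to
    over-split well-populated states because per-burst shot noise varies
    with burst size, giving each state heavier-than-Gaussian tails; the
    entropy term of ICL rejects such strongly overlapping shadow
    components.  Returns the optimal component count and the per-N fits.
    """
    if criterion not in ("icl", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    score = (lambda f: f.icl) if criterion == "icl" else (lambda f: f.bic)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.asarray(e_values, dtype=float)
    fits = {
        n: fit_fret_histogram(x, n, donor_only=donor_only, seed=rng, **kwargs)
        for n in range(1, max_states + 1)
    }
    for _ in range(2):  # two sweeps let good solutions propagate both ways
        for n in range(max_states - 1, 0, -1):  # downward: merge from N+1
            fits[n] = _refit_from(x, fits[n], *_merge_closest(fits[n + 1]), score)
        for n in range(2, max_states + 1):  # upward: split from N-1
            fits[n] = _refit_from(x, fits[n], *_split_widest(fits[n - 1]), score)
    best_n = min(fits, key=lambda n: score(fits[n]))
    return best_n, fits


def fit_fret_histogram_binned(
    e_values: np.ndarray,
    n_fret_states: int,
    donor_only: bool = True,
    bins: int = 50,
    e_range: tuple[float, float] = (-0.1, 1.1),
    seed: int | np.random.Generator | None = None,
) -> MixtureFit:
    """Binned least-squares variant: fit a Gaussian sum to the 50-bin display
    histogram.  Offered for parity with histogram-based workflows; the ML
    (unbinned) fit is the default estimator."""
    x = np.asarray(e_values, dtype=float)
    counts, edges = np.histogram(x, bins=bins, range=e_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    start = fit_fret_histogram(x, n_fret_states, donor_only=donor_only, seed=seed)
    K = start.n_components
    bw = edges[1] - edges[0]

    def model(c, *p):
        w = np.abs(p[:K])
        mu = np.array(p[K : 2 * K])
        sg = np.abs(p[2 * K :]) + _SIGMA_FLOOR
        comp = w * np.exp(-0.5 * ((c[:, None] - mu) / sg) ** 2) / (sg * _SQRT2PI)
        return comp.sum(axis=1) * x.size * bw

    p0 = np.concatenate([start.weights, start.means, start.sigmas])
    try:
        popt, _ = scipy.optimize.curve_fit(model, centers, counts, p0=p0, maxfev=20000)
        w = np.abs(popt[:K])
        w = w / w.sum()
        mu = popt[K : 2 * K]
        sg = np.abs(popt[2 * K :]) + _SIGMA_FLOOR
        converged = True
    except RuntimeError:
        w, mu, sg, converged = start.weights, start.means, start.sigmas, False
    return MixtureFit(
        means=mu,
        sigmas=sg,
        weights=w,
        donor_only=donor_only,
        log_likelihood=np.nan,
        bic=np.nan,
        n_samples=x.size,
        converged=converged,
    )
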