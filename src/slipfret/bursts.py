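"""Burst search, burst filtering, and per-burst observable estimation.

Bursts are maximal runs of photons whose successive interphoton gaps all
stay below a threshold (0.1 ms default) and that contain at least a minimum
number of photons (100 default).  Bursts in which the acceptor bleached are
rejected by the macroscopic-time criterion |T_G - T_R| < 0.55 ms, where T_G
and T_R are the mean arrival times of the green and red photons of the
burst.  Per-burst observables are the proximity-ratio FRET efficiency
E = S_R/(S_G+S_R), the donor lifetime tau_D(A) (maximum-likelihood
exponential mean of green micro-times, background-naive), and the donor
anisotropy r_D from the parallel/perpendicular green split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mfd_sim import EXCITATION_PERIOD_NS, GREEN_PAR, RED_PAR, PhotonStream

__all__ = [
    "PhotonBurst",
    "detect_bursts",
    "filter_bursts",
    "estimate_burst_observables",
    "static_fret_line",
    "burst_table",
]

DEFAULT_MAX_INTERPHOTON = 1e-4     # s
DEFAULT_MIN_PHOTONS = 100
DEFAULT_MAX_TG_TR_DIFF = 0.55e-3   # s


@dataclass
class PhotonBurst:
    """One detected burst with derived observables.

    ``t_green``/``t_red`` (T_G, T_R) are the mean macro-times of the green
    and red photons; either is NaN when the burst has no photon of that
    color, in which case ``tg_tr_defined`` is False.
    """

    start: int                 # index of first photon in the source stream
    stop: int                  # one past the last photon
    s_green: int
    s_red: int
    t_green: float
    t_red: float
    duration: float
    e_burst: float = np.nan
    tau_da: float = np.nan
    r_d: float = np.nan
    pass_filter: bool = True
    flagged: bool = False

    @property
    def n_photons(self) -> int:
        return self.s_green + self.s_red

    @property
    def tg_tr_defined(self) -> bool:
        return np.isfinite(self.t_green) and np.isfinite(self.t_red)


def detect_bursts(
    stream: PhotonStream,
    max_interphoton: float = DEFAULT_MAX_INTERPHOTON,
    min_photons: int = DEFAULT_MIN_PHOTONS,
) -> list[PhotonBurst]:
    """Find bursts: maximal runs of photons with all gaps <= ``max_interphoton``
    and at least ``min_photons`` photons.  Bursts are disjoint by
    construction.  An empty stream yields an empty list."""
    t = stream.macro_time
    if t.size == 0:
        return []
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps > max_interphoton)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [t.size]))
    green = stream.is_green()
    bursts = []
    for a, b in zip(starts, stops):
        if b - a < min_photons:
            continue
        g = green[a:b]
        tg = float(t[a:b][g].mean()) if g.any() else np.nan
        tr = float(t[a:b][~g].mean()) if (~g).any() else np.nan
        bursts.append(
            PhotonBurst(
                start=int(a),
                stop=int(b),
                s_green=int(g.sum()),
                s_red=int((~g).sum()),
                t_green=tg,
                t_red=tr,
                duration=float(t[b - 1] - t[a]),
            )
        )
    return bursts


def filter_bursts(
    bursts: list[PhotonBurst],
    max_tg_tr_diff: float = DEFAULT_MAX_TG_TR_DIFF,
    keep_single_color: bool = True,
) -> list[PhotonBurst]:
    """Apply the acceptor-bleach rejection |T_G - T_R| < ``max_tg_tr_diff``.

    Bursts with photons of only one color have an undefined T for the empty
    color; the default policy retains them flagged (they are typically
    donor-only molecules, which carry no bleach information), and
    ``keep_single_color=False`` drops them instead.  ``pass_filter`` is set
    on every burst; the returned list holds the survivors.
    """
    kept = []
    for b in bursts:
        if not b.tg_tr_defined:
            b.flagged = True
            b.pass_filter = keep_single_color
        else:
            b.pass_filter = abs(b.t_green - b.t_red) < max_tg_tr_diff
        if b.pass_filter:
            kept.append(b)
    return kept


def estimate_burst_observables(
    burst: PhotonBurst,
    stream: PhotonStream,
    tau_D0: float = 4.0,
) -> PhotonBurst:
    """Fill in E, tau_D(A) and r_D for one burst (in place; also returned).

    ``E = S_R / (S_G + S_R)`` (uncorrected proximity ratio);
    ``tau_DA`` is the exponential-MLE mean of green micro-times (ns),
    background-naive; ``r_D = (N_par - N_perp) / (N_par + 2 N_perp)`` from
    the green polarization split (G-factor 1).  A burst without green
    photons has undefined lifetime/anisotropy and is flagged.
    """
    sl = slice(burst.start, burst.stop)
    ch = stream.channel[sl]
    green = stream.is_green()[sl]
    burst.e_burst = burst.s_red / max(burst.n_photons, 1)
    if burst.s_green == 0:
        burst.flagged = True
        return burst
    mt = stream.micro_time[sl][green]
    burst.tau_da = float(mt.mean())
    n_par = int(np.sum(ch[green] == GREEN_PAR))
    n_perp = burst.s_green - n_par
    burst.r_d = (n_par - n_perp) / (n_par + 2.0 * n_perp) if burst.s_green else np.nan
    return burst


def static_fret_line(tau: float | np.ndarray, tau_D0: float) -> float | np.ndarray:
    """The static FRET line ``E = 1 - tau / tau_D0``.

    Populations of molecules whose FRET state does not change during a
    transit fall on this line in the (tau_D(A), E) plane.  Lifetimes above
    ``tau_D0`` (estimator noise) are clipped with a warning.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if np.any(tau > tau_D0):
        warnings.warn("tau > tau_D0 clipped to the FRET line endpoint", stacklevel=2)
        tau = np.minimum(tau, tau_D0)
    e = 1.0 - tau / tau_D0
    return float(e) if e.ndim == 0 else e


def burst_table(bursts: list[PhotonBurst]) -> pd.DataFrame:
    """Tabulate bursts (one row each) for TSV export."""
    return pd.DataFrame(
        {
            "s_green": [b.s_green for b in bursts],
            "s_red": [b.s_red for b in bursts],
            "t_green_s": [b.t_green for b in bursts],
            "t_red_s": [b.t_red for b in bursts],
            "e_burst": [b.e_burst for b in bursts],
            "tau_da_ns": [b.tau_da for b in bursts],
            "r_d": [b.r_d for b in bursts],
            "duration_s": [b.duration for b in bursts],
            "pass_filter": [b.pass_filter for b in bursts],
            "flagged": [b.flagged for b in bursts],
        }
    )
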