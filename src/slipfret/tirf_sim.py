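"""Camera-binned donor/acceptor trace synthesis for the immobilized (TIRF) assay.

A continuous-time state trajectory is integrated over camera frames (50 ms
default exposure), so transitions inside a frame produce motionally blurred
intermediate FRET values; the binned efficiency is then decorated with
photon-budget scaling, background, channel noise and optional photobleaching
to yield donor/acceptor intensity traces like those extracted from single
spots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmc import StateTrajectory
from .scheme import KineticScheme

__all__ = ["FretTrace", "bin_trajectory", "synthesize_trace", "write_trace_tsv", "read_trace_tsv"]

DEFAULT_BIN_WIDTH = 0.050  # s, camera exposure time


@dataclass
class FretTrace:
    """A time-binned donor/acceptor intensity trace.

    ``e_apparent`` is the uncorrected proximity ratio acceptor/(donor+acceptor)
    per frame; frames with zero total intensity get ``e_apparent = 0`` and are
    flagged in ``zero_total``.
    """

    bin_width: float
    donor: np.ndarray
    acceptor: np.ndarray
    e_apparent: np.ndarray
    zero_total: np.ndarray = field(default=None)  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.e_apparent = np.asarray(self.e_apparent, dtype=float)
        if self.zero_total is None:
            self.zero_total = np.zeros(self.donor.shape, dtype=bool)
        if not (self.donor.shape == self.acceptor.shape == self.e_apparent.shape):
            raise ValueError("donor, acceptor, e_apparent must have equal length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        ok = ~self.zero_total
        if np.any((self.e_apparent[ok] < 0) | (self.e_apparent[ok] > 1)):
            raise ValueError("e_apparent must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.bin_width


def bin_trajectory(
    traj: StateTrajectory,
    scheme: KineticScheme,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Time-average the state FRET map over camera frames (motional blurring).

    Frame ``k`` covers ``[k*bin_width, (k+1)*bin_width)``; its value is the
    duration-weighted mean of ``scheme.fret_map`` over the states occupied in
    that window.  ``floor(total_duration / bin_width)`` frames are returned.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_frames = int(np.floor(traj.total_duration / bin_width + 1e-9))
    if n_frames < 1:
        raise ValueError("trajectory shorter than one bin")
    # Cumulative integral of the piecewise-constant E(t) is piecewise linear,
    # so per-frame means come from interpolating it at the frame edges.
    bounds = traj.boundaries()
    e_seg = scheme.fret_map[traj.states]
    cum = np.concatenate(([0.0], np.cumsum(e_seg * traj.dwells)))
    edges = np.arange(n_frames + 1) * bin_width
    integral = np.interp(edges, bounds, cum)
    return np.diff(integral) / bin_width


def synthesize_trace(
    e_frames: np.ndarray,
    total_rate: float = 1000.0,
    noise_model: str = "gaussian",
    sigma_frac: float = 0.10,
    background: float | tuple[float, float] = 0.0,
    bleach: dict | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int | np.random.Generator | None = None,
    metadata: dict | None = None,
) -> FretTrace:
    """Decorate a binned FRET series into a noisy donor/acceptor trace.

    Per frame the noiseless expectation is ``acceptor = E * total_rate`` and
    ``donor = (1 - E) * total_rate`` (anti-correlated), plus per-channel
    background.  ``noise_model`` is ``"gaussian"`` (per-channel sigma =
    ``sigma_frac * total_rate``, the emission model assumed downstream by the
    HMM) or ``"poisson"`` (shot noise).  ``"none"`` disables noise.

    ``bleach``, if given, holds exponential mean lifetimes in seconds:
    ``{"acceptor_lifetime": ..., "donor_lifetime": ...}`` (either optional).
    From the frame containing the acceptor-bleach event onward the acceptor
    falls to background and the donor recovers the full photon budget (the
    donor-only tail that produces the zero-FRET peak); after donor bleach both
    channels fall to background.

    Negative Gaussian-noise excursions are clipped at zero counts.
    """
    if total_rate <= 0:
        raise ValueError("total_rate must be > 0")
    bg_d, bg_a = (background, background) if np.isscalar(background) else background
    if bg_d < 0 or bg_a < 0:
        raise ValueError("background must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    e = np.asarray(e_frames, dtype=float)
    n = e.size
    acceptor = e * total_rate
    donor = (1.0 - e) * total_rate

    meta = dict(metadata or {})
    if bleach:
        t_a = bleach.get("acceptor_lifetime")
        t_d = bleach.get("donor_lifetime")
        f_a = int(rng.exponential(t_a) / bin_width) if t_a else n
        f_d = int(rng.exponential(t_d) / bin_width) if t_d else n
        if f_a < min(n, f_d):
            acceptor[f_a:] = 0.0
            donor[f_a:] = total_rate
            meta["acceptor_bleach_frame"] = f_a
        if f_d < n:
            acceptor[f_d:] = 0.0
            donor[f_d:] = 0.0
            meta["donor_bleach_frame"] = f_d

    donor = donor + bg_d
    acceptor = acceptor + bg_a

    if noise_model == "gaussian":
        sigma = sigma_frac * total_rate
        donor = np.clip(donor + rng.normal(0.0, sigma, n), 0.0, None)
        acceptor = np.clip(acceptor + rng.normal(0.0, sigma, n), 0.0, None)
    elif noise_model == "poisson":
        donor = rng.poisson(donor).astype(float)
        acceptor = rng.poisson(acceptor).astype(float)
    elif noise_model != "none":
        raise ValueError(f"unknown noise_model {noise_model!r}")

    total = donor + acceptor
    zero = total <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        e_app = np.where(zero, 0.0, acceptor / np.where(zero, 1.0, total))
    return FretTrace(
        bin_width=bin_width,
        donor=donor,
        acceptor=acceptor,
        e_apparent=e_app,
        zero_total=zero,
        metadata=meta,
    )


_COLUMNS = ["frame_index", "time_s", "donor", "acceptor", "e_apparent"]


def write_trace_tsv(trace: FretTrace, path: str | Path) -> None:
    """Write one trace as TSV (columns frame_index, time_s, donor, acceptor,
    e_apparent); metadata goes to a sidecar ``<path>.json`` if present."""
    df = pd.DataFrame(
        {
            "frame_index": np.arange(trace.n_frames),
            "time_s": trace.times,
            "donor": trace.donor,
            "acceptor": trace.acceptor,
            "e_apparent": trace.e_apparent,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    if trace.metadata:
        Path(str(path) + ".json").write_text(json.dumps(trace.metadata, indent=1, sort_keys=True))


def read_trace_tsv(path: str | Path, bin_width: float | None = None) -> FretTrace:
    """Read a trace written by :func:`write_trace_tsv`; accepts tab or comma
    delimiters.  ``bin_width`` is inferred from ``time_s`` when omitted."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing columns {missing}")
    if bin_width is None:
        t = df["time_s"].to_numpy()
        bin_width = float(np.median(np.diff(t))) if t.size > 1 else DEFAULT_BIN_WIDTH
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    donor = df["donor"].to_numpy(float)
    acceptor = df["acceptor"].to_numpy(float)
    return FretTrace(
        bin_width=bin_width,
        donor=donor,
        acceptor=acceptor,
        e_apparent=df["e_apparent"].to_numpy(float),
        zero_total=(donor + acceptor) <= 0,
        metadata=meta,
    )
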