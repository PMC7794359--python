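"""Photon-record simulation for the confocal MFD (burst) experiment.

Freely diffusing molecules transit the confocal volume one at a time,
producing bursts of photons on four detectors (green/red x parallel/
perpendicular) under 40 MHz pulsed excitation.  Each transit gets a Gaussian
intensity envelope; the molecule's FRET efficiency is frozen for the transit
(a stationary draw from the kinetic scheme — conformational exchange is slow
on the ~200 us diffusion timescale), photon color is Bernoulli(E), green
micro-times are exponential with the quenched donor lifetime
``tau_DA = tau_D0 * (1 - E)``, and polarization follows the two-detector
intensity ratio for anisotropy ``r``.  Uniform background photons are added
per detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import KineticScheme

__all__ = ["TransitSpec", "PhotonStream", "simulate_photon_stream", "CHANNELS"]

#: Detector channel codes.
CHANNELS = ("green_parallel", "green_perpendicular", "red_parallel", "red_perpendicular")
GREEN_PAR, GREEN_PERP, RED_PAR, RED_PERP = range(4)

EXCITATION_PERIOD_NS = 25.0  # 40 MHz pulsed excitation
#: Acceptor fluorescence lifetime used for red micro-times (ns); cosmetic,
#: no downstream estimator reads it.
ACCEPTOR_LIFETIME_NS = 1.5


@dataclass(frozen=True)
class TransitSpec:
    """Parameters of single-molecule transits through the confocal volume.

    ``mean_transit`` is the 1/e half-width of the Gaussian intensity
    envelope (s); ``peak_rate`` the detection rate at the envelope center
    (photons/s); ``background_rate`` the total background over all four
    detectors (photons/s, split evenly); ``tau_D0`` the unquenched donor
    lifetime (ns); ``anisotropy`` the steady-state donor anisotropy used for
    the parallel/perpendicular split; ``transit_spread`` the log-normal
    sigma of per-transit duration variation.
    """

    mean_transit: float = 200e-6
    peak_rate: float = 1.0e6
    background_rate: float = 1500.0
    tau_D0: float = 4.0
    anisotropy: float = 0.15
    transit_spread: float = 0.3
    mean_interval: float = 5e-3  # mean gap between molecule arrivals, s

    def __post_init__(self) -> None:
        if self.mean_transit <= 0 or self.peak_rate < 0 or self.background_rate < 0:
            raise ValueError("transit rates/durations must be positive")
        if self.tau_D0 <= 0:
            raise ValueError("tau_D0 must be > 0")
        if not -0.2 <= self.anisotropy <= 0.4:
            raise ValueError("anisotropy outside physical range [-0.2, 0.4]")


@dataclass
class PhotonStream:
    """Time-ordered photon records from one simulated measurement."""

    macro_time: np.ndarray  # s, non-decreasing
    micro_time: np.ndarray  # ns in [0, 25)
    channel: np.ndarray     # int codes, see CHANNELS
    duration: float
    metadata: dict

    def __post_init__(self) -> None:
        if np.any(np.diff(self.macro_time) < 0):
            raise ValueError("macro_times must be non-decreasing")
        if np.any((self.micro_time < 0) | (self.micro_time >= EXCITATION_PERIOD_NS)):
            raise ValueError("micro_times must lie in the excitation period")

    @property
    def n_photons(self) -> int:
        return self.macro_time.size

    def is_green(self) -> np.ndarray:
        return self.channel <= GREEN_PERP

    def is_parallel(self) -> np.ndarray:
        return (self.channel == GREEN_PAR) | (self.channel == RED_PAR)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "macro_time_s": self.macro_time,
                "micro_time_ns": self.micro_time,
                "channel": [CHANNELS[c] for c in self.channel],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhotonStream":
        df = pd.read_csv(path, sep=None, engine="python")
        code = {name: i for i, name in enumerate(CHANNELS)}
        mt = df["macro_time_s"].to_numpy(float)
        return cls(
            macro_time=mt,
            micro_time=df["micro_time_ns"].to_numpy(float),
            channel=np.array([code[c] for c in df["channel"]]),
            duration=float(mt[-1]) if mt.size else 0.0,
            metadata={},
        )


def _polarization(n: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli split onto the parallel detector: P(par) = (1+2r)/(2+r)."""
    return rng.random(n) < (1.0 + 2.0 * r) / (2.0 + r)


def simulate_photon_stream(
    scheme: KineticScheme,
    transit: TransitSpec | None = None,
    n_molecules: int = 1000,
    donor_only_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
    crosstalk: float = 0.0,
) -> PhotonStream:
    """Simulate the photon record stream of an MFD measurement.

    Molecules arrive as a sparse Poisson process (mean spacing
    ``transit.mean_interval``); each transit emits ``Poisson`` photons under
    a Gaussian envelope whose width is ``mean_transit`` with log-normal
    spread.  With probability ``donor_only_fraction`` a molecule carries no
    active acceptor (E = 0, unquenched donor lifetime); otherwise its E is
    the FRET value of a stationary-distribution draw from ``scheme``, frozen
    for the whole transit.  ``crosstalk`` is the probability that a donor
    photon is detected in a red channel (default 0).

    Returns a time-sorted :class:`PhotonStream` including uniform background
    photons on all four detectors.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not 0.0 <= donor_only_fraction <= 1.0:
        raise ValueError("donor_only_fraction must lie in [0, 1]")
    transit = transit or TransitSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    arrivals = np.cumsum(rng.exponential(transit.mean_interval, n_molecules)) + 3 * transit.mean_transit
    duration = float(arrivals[-1] + 10 * transit.mean_transit)
    pi = scheme.stationary_distribution()

    # Warn (once) if lifetimes overflow the excitation window appreciably.
    if transit.tau_D0 > EXCITATION_PERIOD_NS / 3:
        import warnings

        warnings.warn("tau_D0 is large relative to the 25 ns excitation period", stacklevel=2)

    times, micro, chan = [], [], []
    widths = transit.mean_transit * rng.lognormal(0.0, transit.transit_spread, n_molecules)
    donor_only = rng.random(n_molecules) < donor_only_fraction
    states = rng.choice(scheme.n_states, size=n_molecules, p=pi)
    e_values = np.where(donor_only, 0.0, scheme.fret_map[states])

    for m in range(n_molecules):
        w = widths[m]
        n_phot = rng.poisson(transit.peak_rate * w * np.sqrt(2.0 * np.pi))
        if n_phot == 0:
            continue
        t = rng.normal(arrivals[m], w, n_phot)
        e = e_values[m]
        red = rng.random(n_phot) < e
        # crosstalk: donor photons leaking into red detection channels
        if crosstalk > 0:
            red |= (~red) & (rng.random(n_phot) < crosstalk)
        tau_da = transit.tau_D0 * (1.0 - e)
        mt = np.where(
            red,
            rng.exponential(ACCEPTOR_LIFETIME_NS, n_phot),
            rng.exponential(max(tau_da, 1e-6), n_phot),
        ) % EXCITATION_PERIOD_NS
        par = _polarization(n_phot, transit.anisotropy, rng)
        code = np.where(red, np.where(par, RED_PAR, RED_PERP), np.where(par, GREEN_PAR, GREEN_PERP))
        times.append(t)
        micro.append(mt)
        chan.append(code)

    n_bg = rng.poisson(transit.background_rate * duration)
    if n_bg:
        times.append(rng.uniform(0.0, duration, n_bg))
        micro.append(rng.uniform(0.0, EXCITATION_PERIOD_NS, n_bg))
        chan.append(rng.integers(0, 4, n_bg))

    if times:
        t_all = np.concatenate(times)
        order = np.argsort(t_all, kind="stable")
        t_all = np.clip(t_all[order], 0.0, None)
        t_all = np.maximum.accumulate(t_all)
        mt_all = np.concatenate(micro)[order]
        ch_all = np.concatenate(chan)[order]
    else:  # pragma: no cover - zero-rate corner
        t_all = np.empty(0)
        mt_all = np.empty(0)
        ch_all = np.empty(0, dtype=int)

    meta = {
        "n_molecules": int(n_molecules),
        "donor_only_fraction": float(donor_only_fraction),
        "mean_transit_s": transit.mean_transit,
        "peak_rate_hz": transit.peak_rate,
        "background_rate_hz": transit.background_rate,
        "tau_D0_ns": transit.tau_D0,
        "anisotropy": transit.anisotropy,
        "true_e_per_molecule": e_values.tolist() if n_molecules <= 10000 else None,
    }
    return PhotonStream(t_all, mt_all, ch_all, duration, meta)
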