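"""Scheme configuration files and reproducible run manifests.

A scheme config is a small YAML (or JSON — YAML is a superset) document::

    junction:
      slipout_repeats: 10
      duplex_repeats: 3
      repeat_unit: CAG
    conformers: 2
    rates:
      conformational: {low_to_high: 12.25, high_to_low: 3.38}
      migration: 2.0
      jump: 0.0
    fret_map: default       # or an explicit per-state list

Configs round-trip bit-exactly: :func:`dump_config` produces canonical text
(sorted keys, explicit flow style off) so ``load -> dump -> load`` is the
identity and ``dump`` is idempotent.
"""

from __future__ import annotations

import datetime
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .junction import JunctionSpec
from .scheme import KineticScheme, RateSet, build_scheme

__all__ = [
    "default_config",
    "load_config",
    "dump_config",
    "save_config",
    "scheme_from_config",
    "RunManifest",
]


def default_config() -> dict:
    """The canonical mobile-construct configuration."""
    return {
        "junction": {"slipout_repeats": 10, "duplex_repeats": 3, "repeat_unit": "CAG"},
        "conformers": 2,
        "rates": {
            "conformational": {"low_to_high": 12.25, "high_to_low": 3.38},
            "migration": 2.0,
            "jump": 0.0,
        },
        "fret_map": "default",
    }


_REQUIRED = ("junction", "conformers", "rates")


def load_config(path: str | Path) -> dict:
    """Load and validate a scheme config (YAML or JSON text)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    missing = [k for k in _REQUIRED if k not in cfg]
    if missing:
        raise ValueError(f"config {path} missing keys {missing}")
    return cfg


def dump_config(cfg: dict) -> str:
    """Canonical YAML text of a config (stable key order, idempotent)."""
    return yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(dump_config(cfg))


def scheme_from_config(cfg: dict) -> KineticScheme:
    """Build the kinetic scheme described by a config mapping."""
    j = cfg["junction"]
    spec = JunctionSpec(
        slipout_repeats=int(j["slipout_repeats"]),
        duplex_repeats=int(j.get("duplex_repeats", 0)),
        repeat_unit=str(j.get("repeat_unit", "CTG")),
    )
    r = cfg["rates"]
    conf = r.get("conformational", {})
    rates = RateSet(
        low_to_high=float(conf.get("low_to_high", 12.25)),
        high_to_low=float(conf.get("high_to_low", 3.38)),
        migration=float(r.get("migration", 2.0)),
        jump=float(r.get("jump", 0.0)),
        gate_conformer=r.get("gate_conformer"),
    )
    fret = cfg.get("fret_map", "default")
    fret_values = None if fret == "default" else fret
    overrides = cfg.get("rate_overrides")
    if overrides:
        overrides = {tuple(map(int, k.split("-"))): float(v) for k, v in overrides.items()}
    return build_scheme(
        spec,
        conformer_count=int(cfg.get("conformers", 2)),
        rates=rates,
        fret_values=fret_values,
        rate_overrides=overrides,
    )


@dataclass
class RunManifest:
    """Record of one pipeline stage run: config snapshot, seeds, outputs."""

    stage: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "stage": self.stage,
            "config": self.config,
            "seeds": self.seeds,
            "outputs": self.outputs,
            "extra": self.extra,
            "versions": {"slipfret": __version__, "python": platform.python_version()},
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
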