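"""Run configuration: a flat key-value text format tying the pipeline
together.

A run config names the radiobiological parameter set, the response
levels, the fractionation, and the phantom / beamlet / engine / swarm
settings, under dotted keys::

    parameter_set = 1
    levels.tcp_min = 0.85
    swarm.n_particles = 20
    phantom.preset = small

One seed governs every stochastic component through named sub-streams, so
a full run is reproducible from the config alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from .engine import EngineConfig
from .phantom import PhantomConfig, small_phantom_config
from .radbio import FractionationScheme
from .swarm import ResponseLevels, SwarmConfig

__all__ = ["RunConfig", "ConfigError", "read_keyvalues", "write_keyvalues"]


class ConfigError(ValueError):
    """Malformed configuration input, with the offending key named."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a prescription-free optimization run needs."""

    parameter_set: int = 1
    n_fractions: int = 20
    seed: int = 0
    levels: ResponseLevels = field(default_factory=ResponseLevels)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    phantom_preset: str = "small"  # "small" | "default"
    prostate_volume_cm3: float = 41.0
    gtv_fraction: float = 0.118
    n_beams: int = 8
    beamlet_width_mm: float = 10.0
    attenuation_coeff: float = 0.005
    dvh_bin_width_gy: float = 0.05

    def __post_init__(self) -> None:
        if self.parameter_set not in (1, 2, 3):
            raise ConfigError(f"parameter_set must be 1, 2 or 3, got {self.parameter_set}")
        if self.phantom_preset not in ("small", "default"):
            raise ConfigError(f"unknown phantom preset {self.phantom_preset!r}")

    @property
    def scheme(self) -> FractionationScheme:
        return FractionationScheme(self.n_fractions)

    def phantom_config(self) -> PhantomConfig:
        make = small_phantom_config if self.phantom_preset == "small" else PhantomConfig
        return make(
            prostate_volume_cm3=self.prostate_volume_cm3,
            gtv_fraction=self.gtv_fraction,
        )

    def sub_seeds(self) -> Dict[str, int]:
        """Named child seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("phantom", "pso", "cohort")
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    # -- text round trip ---------------------------------------------------

    def to_keyvalues(self) -> Dict[str, str]:
        flat: Dict[str, str] = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name in ("levels", "swarm", "engine"):
                for sub_f in fields(value):
                    flat[f"{f.name}.{sub_f.name}"] = repr(getattr(value, sub_f.name))
            else:
                flat[f.name] = repr(value)
        return flat

    def to_file(self, path: str | Path) -> None:
        write_keyvalues(path, self.to_keyvalues())

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_keyvalues(path)
        simple: Dict[str, object] = {}
        nested: Dict[str, Dict[str, object]] = {"levels": {}, "swarm": {}, "engine": {}}
        valid_simple = {f.name for f in fields(cls)} - set(nested)
        valid_nested = {
            group: {f.name for f in fields(klass)}
            for group, klass in (
                ("levels", ResponseLevels),
                ("swarm", SwarmConfig),
                ("engine", EngineConfig),
            )
        }
        for key, (value, line_no) in raw.items():
            if "." in key:
                group, _, sub = key.partition(".")
                if group not in nested or sub not in valid_nested.get(group, ()):
                    raise ConfigError(f"unknown config key {key!r} (line {line_no})")
                nested[group][sub] = _coerce(value, key, line_no)
            else:
                if key not in valid_simple:
                    raise ConfigError(f"unknown config key {key!r} (line {line_no})")
                simple[key] = _coerce(value, key, line_no)
        try:
            return cls(
                levels=ResponseLevels(**nested["levels"]),
                swarm=SwarmConfig(**nested["swarm"]),
                engine=EngineConfig(**nested["engine"]),
                **simple,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def _coerce(value: str, key: str, line_no: int):
    text = value.strip().strip("'\"")
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    if text == "":
        raise ConfigError(f"empty value for key {key!r} (line {line_no})")
    return text


def read_keyvalues(path: str | Path) -> Dict[str, Tuple[str, int]]:
    """Parse a ``key = value`` text file; returns value and line number."""
    out: Dict[str, Tuple[str, int]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"expected 'key = value' on line {line_no}: {line!r}")
        key, _, value = stripped.partition("=")
        out[key.strip()] = (value.strip(), line_no)
    return out


def write_keyvalues(path: str | Path, values: Dict[str, str]) -> None:
    lines = [f"{key} = {value}" for key, value in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")
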