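"""Run configuration: a single YAML file, losslessly round-tripped.

A :class:`RunConfig` gathers everything a run needs — parameter ranges and
grid settings, neighbor-network settings, fitness constants, signal level,
and the experiment design — plus the output directory and log level.  Every
run archives its resolved configuration and a content hash in a JSON
manifest next to its outputs, so results are attributable to an exact
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grn import DEFAULT_KR_RATIO, EnvSignal, FitnessConstants
from .landscape import DEFAULT_RANGES, GridConfig, ParamRange
from .experiments import ExperimentDesign

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]

_REQUIRED_RANGE_KEYS = ("name", "min", "max")


class ConfigError(ValueError):
    """Malformed configuration, with the offending key named."""


@dataclass
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    fitness_constants: FitnessConstants = field(default_factory=FitnessConstants)
    env: EnvSignal = field(default_factory=EnvSignal)
    kr_ratio: float = DEFAULT_KR_RATIO
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "grid": {
                "n_levels": self.grid.n_levels,
                "seed": self.grid.seed,
                "ranges": [
                    {"name": r.name, "min": r.min, "max": r.max, "scale": r.scale}
                    for r in self.grid.ranges
                ],
            },
            "design": asdict(self.design) | {
                "K_values": list(self.design.K_values),
                "start_fitnesses": list(self.design.start_fitnesses),
            },
            "fitness_constants": asdict(self.fitness_constants),
            "env": asdict(self.env),
            "kr_ratio": self.kr_ratio,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            gd = d.get("grid", {})
            ranges = gd.get("ranges")
            if ranges is None:
                prs = DEFAULT_RANGES
            else:
                prs = []
                for entry in ranges:
                    for key in _REQUIRED_RANGE_KEYS:
                        if key not in entry:
                            raise ConfigError(
                                f"range entry {entry.get('name', '<unnamed>')!r} "
                                f"is missing required key {key!r}")
                    prs.append(ParamRange(entry["name"], float(entry["min"]),
                                          float(entry["max"]),
                                          entry.get("scale", "log")))
                prs = tuple(prs)
            grid = GridConfig(ranges=prs, n_levels=int(gd.get("n_levels", 1000)),
                              seed=int(gd.get("seed", 0)))
            dd = dict(d.get("design", {}))
            if "K_values" in dd:
                dd["K_values"] = tuple(int(k) for k in dd["K_values"])
            if "start_fitnesses" in dd:
                dd["start_fitnesses"] = tuple(float(f) for f in dd["start_fitnesses"])
            design = ExperimentDesign(**dd)
            fc = FitnessConstants(**d.get("fitness_constants", {}))
            env = EnvSignal(**d.get("env", {}))
        except ConfigError:
            raise
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e
        return cls(grid=grid, design=design, fitness_constants=fc, env=env,
                   kr_ratio=float(d.get("kr_ratio", DEFAULT_KR_RATIO)),
                   output_dir=str(d.get("output_dir", "results")),
                   log_level=str(d.get("log_level", "INFO")))


def load_config(path: str | Path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of the resolved configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, path: str | Path, **extra) -> None:
    manifest = {"config": cfg.to_dict(), "config_hash": config_hash(cfg)} | extra
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
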