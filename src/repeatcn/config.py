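"""Run configuration: YAML schema, defaults and run records."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import Hyperparams


@dataclass
class MCMCConfig:
    """Chain lengths; the defaults are the out-of-box settings of each stage."""

    control_iters: int = 20000
    control_burn: int = 5000
    call_iters: int = 50000
    call_burn: int = 20000
    thin: int = 5
    K_max: int = 25
    seed: int | None = None

    # shorter preset used for dilution-series screening runs
    DILUTION_ITERS = 30000
    DILUTION_BURN = 5000


@dataclass
class PipelineConfig:
    primer: str = ""
    max_mismatch: int = 5
    target_len: int = 100
    min_phred: int = 20


@dataclass
class RunConfig:
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        return {
            "hyperparams": self.hyperparams.to_dict(),
            "mcmc": asdict(self.mcmc),
            "pipeline": asdict(self.pipeline),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            hyperparams=Hyperparams.from_dict(d.get("hyperparams", {})),
            mcmc=MCMCConfig(**d.get("mcmc", {})),
            pipeline=PipelineConfig(**d.get("pipeline", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_run_record(
    path: str | Path, command: str, config: RunConfig, inputs: list[str | Path]
) -> None:
    """JSON sidecar recording what produced an output: command, config, seed, input digests."""
    from . import __version__

    record = {
        "tool": "repeatcn",
        "version": __version__,
        "command": command,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(record, indent=2))
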