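"""Run configuration: a single YAML file with per-stage sections, plus the
seed hierarchy that every stochastic stage derives from the master seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquisition import NoiseConfig
from .phantom import PathologySpec, PhantomConfig
from .tracking import ControllerConfig

__all__ = ["RunConfig", "child_seeds"]


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    seed: int = 0
    motion_profile: str = "healthy"
    scan_kind: str = "volume"
    scan_overrides: dict = field(default_factory=dict)
    n_depth: int = 1024
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pathologies: list[PathologySpec] = field(default_factory=list)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    compensation: bool = True
    output_dir: str = "runs"

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "motion_profile": self.motion_profile,
            "scan_kind": self.scan_kind,
            "scan_overrides": dict(self.scan_overrides),
            "n_depth": self.n_depth,
            "phantom": asdict(self.phantom),
            "pathologies": [asdict(p) for p in self.pathologies],
            "controller": asdict(self.controller),
            "noise": asdict(self.noise),
            "compensation": self.compensation,
            "output_dir": self.output_dir,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "phantom" in doc:
            ph = dict(doc["phantom"])
            for key in ("onh_center_mm",):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            if "inner_bands" in ph:
                ph["inner_bands"] = tuple(tuple(b) for b in ph["inner_bands"])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "pathologies" in doc:
            kwargs["pathologies"] = [
                PathologySpec(
                    kind=p["kind"], center=tuple(p["center"]),
                    extent=p["extent"], magnitude=p["magnitude"],
                )
                for p in doc["pathologies"]
            ]
        if "controller" in doc:
            kwargs["controller"] = ControllerConfig(**doc["controller"])
        if "noise" in doc:
            kwargs["noise"] = NoiseConfig(**doc["noise"])
        return cls(**kwargs)
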