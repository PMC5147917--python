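"""Pipeline configuration: one YAML file covering every stage.

A single global seed fans out to fixed per-stage substreams (derivation
order: synthetic, split, forest), so rerunning one stage alone is stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import yaml

from .evaluation import SplitConfig
from .features import FeatureConfig
from .forest import ForestConfig
from .synthetic import CohortConfig, PhenotypeParams

__all__ = ["PipelineConfig", "config_hash"]

_STAGES = ("synthetic", "split", "forest")


def _substream_seeds(seed: int) -> dict:
    """Derive one child seed per stage from the global seed, fixed order."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for every pipeline stage."""

    seed: int = 0
    verbosity: int = 0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    synthetic: CohortConfig = field(default_factory=CohortConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every stage seed from a new global seed."""
        sub = _substream_seeds(seed)
        return replace(
            self, seed=seed,
            synthetic=replace(self.synthetic, seed=sub["synthetic"]),
            split=replace(self.split, seed=sub["split"]),
            forest=replace(self.forest, seed=sub["forest"]),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_jsonable()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = dict(d.get("synthetic", {}))
        if "phenotypes" in syn:
            syn["phenotypes"] = {k: PhenotypeParams(**v)
                                 for k, v in syn["phenotypes"].items()}
        if "faller_weights" in syn:
            syn["faller_weights"] = tuple(syn["faller_weights"])
        return cls(
            seed=d.get("seed", 0),
            verbosity=d.get("verbosity", 0),
            features=FeatureConfig(**d.get("features", {})),
            forest=ForestConfig(**d.get("forest", {})),
            split=SplitConfig(**d.get("split", {})),
            synthetic=CohortConfig(**syn),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable digest identifying a configuration, embedded in artifacts."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
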