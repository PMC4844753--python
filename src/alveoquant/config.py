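"""Run configuration: a YAML file of every pipeline tunable.

One documented key set drives both the library defaults and the CLI; every
CLI flag mirrors a config key and overrides it.  A run manifest (inputs,
config hash, seed, package version) is written next to every output so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .ploidy import PopulationSpec
from .segmentation import SegmentationParams
from .synthetic import SceneSpec
from .volume import VoxelSpacing

__all__ = ["Config", "load_config", "write_manifest"]

_SECTIONS = ("scene", "segmentation", "nuclei_segmentation", "population")


class Config:
    """Validated view over the YAML key set.

    Sections: ``seed`` (global random seed), ``scene`` (synthetic scene,
    :class:`SceneSpec` keys), ``segmentation`` / ``nuclei_segmentation``
    (:class:`SegmentationParams` keys) and ``population``
    (:class:`PopulationSpec` keys).  Unknown keys are rejected.
    """

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        self.seed = int(raw.pop("seed", 0))
        self._raw = {}
        for section in _SECTIONS:
            self._raw[section] = dict(raw.pop(section, {}) or {})
        if raw:
            raise ValueError(f"unknown config sections: {sorted(raw)}")

    def override(self, section: str, **kwargs) -> "Config":
        for key, value in kwargs.items():
            if value is not None:
                self._raw[section][key] = value
        return self

    def scene_spec(self) -> SceneSpec:
        d = dict(self._raw["scene"])
        d.setdefault("seed", self.seed)
        return SceneSpec.from_dict(d)

    def segmentation_params(self, nuclei: bool = False) -> SegmentationParams:
        section = "nuclei_segmentation" if nuclei else "segmentation"
        d = dict(self._raw[section])
        if "smooth_sigma" in d:
            d["smooth_sigma"] = tuple(d["smooth_sigma"])
        base = SegmentationParams.for_nuclei() if nuclei else SegmentationParams()
        merged = {**asdict(base), **d}
        return SegmentationParams(**merged)

    def population_spec(self) -> PopulationSpec:
        d = dict(self._raw["population"])
        d.setdefault("seed", self.seed)
        return PopulationSpec(**d)

    def to_dict(self) -> dict:
        return {"seed": self.seed, **{s: self._raw[s] for s in _SECTIONS}}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    with open(path) as fh:
        return Config(yaml.safe_load(fh) or {})


def write_manifest(path: str | Path, config: Config, inputs: list[str],
                   outputs: list[str]) -> Path:
    from . import __version__

    manifest = {
        "alveoquant_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
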