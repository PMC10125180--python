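"""Run configuration and manifests for reproducible CLI runs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .burden import BurdenThresholds
from .cohort import CohortSpec, default_spec
from .errors import ConfigError
from .plans import DrugParams

__all__ = ["RunConfig", "load_spec", "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to replay a run bit-identically.

    Defaults reproduce the study's pilot configuration: dosage plan
    "70-60-50", pilot cost plan, 10% CHE share, 4978 RMB poverty line,
    guideline drug parameters, B = 1000 bootstrap replicates.
    """

    cohort: str | None = None
    scheme: str = "dosage"
    plan: str = "70-60-50"
    bootstrap: int = 1000
    seed: int = 0
    include_nonmedical: bool = False
    out_dir: str = "."
    thresholds: BurdenThresholds = field(default_factory=BurdenThresholds)
    drug: DrugParams = field(default_factory=DrugParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = BurdenThresholds(**d["thresholds"])
        if "drug" in d and isinstance(d["drug"], dict):
            d["drug"] = DrugParams(**d["drug"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_spec(path: str | Path | None, seed: int | None = None) -> CohortSpec:
    """Load a cohort spec from YAML/JSON, or the defaults when no path."""
    if path is None:
        return default_spec(seed=seed if seed is not None else 0)
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
        spec = CohortSpec.from_dict(data)
    except (yaml.YAMLError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid cohort spec {path}: {exc}") from exc
    if seed is not None:
        spec = CohortSpec(pediatric=spec.pediatric, adult=spec.adult, seed=seed)
    return spec


def write_manifest(out_dir: str | Path, command: str, config: dict) -> Path:
    """Write a replay manifest (command, config, seed, package version)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "pompesim",
        "version": __version__,
        "command": command,
        "config": config,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
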