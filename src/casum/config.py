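"""YAML experiment configuration: validation and deterministic seeding.

A config file fully determines every output: each stochastic step
(slice generation, pre-condition trials, post-condition trials, traces)
consumes a named seed, so re-running an identical config reproduces
byte-identical result tables.

Sections::

    slice:         generator settings (see SliceConfig)
    noise:         noise_sd override
    perturbation:  kind + parameters (optional)
    trace:         trace synthesis settings (optional)
    seeds:         slice / pre_trials / post_trials / trace
    analysis:      model, detection_floor, normalize_both_axes, trials
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .slice_model import PerturbationSpec, SliceConfig
from .traces import TraceConfig

_SECTIONS = {"slice", "noise", "perturbation", "trace", "seeds", "analysis"}


class ConfigError(ValueError):
    """Malformed experiment configuration, with the offending field named."""


@dataclass(frozen=True)
class Seeds:
    slice: int = 0
    pre_trials: int = 1000
    post_trials: int = 2000
    trace: int = 3000


@dataclass(frozen=True)
class AnalysisOptions:
    model: str = "model1"
    detection_floor: float = 0.0
    normalize_both_axes: bool = True
    trials: int = 3
    paired_ttest: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("model0", "model1"):
            raise ConfigError(f"analysis.model must be 'model0' or 'model1', got {self.model!r}")
        if self.trials < 1:
            raise ConfigError("analysis.trials must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    slice: SliceConfig = field(default_factory=SliceConfig)
    perturbation: Optional[PerturbationSpec] = None
    trace: Optional[TraceConfig] = None
    seeds: Seeds = field(default_factory=Seeds)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def config_hash(self) -> str:
        """Stable hash of the full config, for run manifests."""
        blob = json.dumps(to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, section: str, data: dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def from_dict(raw: dict[str, Any]) -> ExperimentConfig:
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}")
    slice_data = dict(raw.get("slice", {}))
    noise = raw.get("noise", {})
    if noise:
        if set(noise) - {"noise_sd"}:
            raise ConfigError(f"noise: unknown field(s) {sorted(set(noise) - {'noise_sd'})}")
        slice_data["noise_sd"] = noise["noise_sd"]
    seeds = _build(Seeds, "seeds", dict(raw.get("seeds", {})))
    slice_data.setdefault("seed", seeds.slice)
    slice_cfg = _build(SliceConfig, "slice", slice_data)
    pert = None
    if raw.get("perturbation"):
        pert = _build(PerturbationSpec, "perturbation", dict(raw["perturbation"]))
    trace = _build(TraceConfig, "trace", dict(raw["trace"])) if raw.get("trace") else None
    analysis = _build(AnalysisOptions, "analysis", dict(raw.get("analysis", {})))
    return ExperimentConfig(
        slice=slice_cfg, perturbation=pert, trace=trace, seeds=seeds, analysis=analysis
    )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    return from_dict(raw)


def to_dict(cfg: ExperimentConfig) -> dict[str, Any]:
    out: dict[str, Any] = {
        "slice": dataclasses.asdict(cfg.slice),
        "seeds": dataclasses.asdict(cfg.seeds),
        "analysis": dataclasses.asdict(cfg.analysis),
    }
    if cfg.perturbation is not None:
        out["perturbation"] = dataclasses.asdict(cfg.perturbation)
    if cfg.trace is not None:
        out["trace"] = dataclasses.asdict(cfg.trace)
    return out


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def write_manifest(
    path: str | Path, cfg: ExperimentConfig, files: list[str | Path]
) -> dict[str, Any]:
    """Run manifest: config hash, artifact version, timestamp, file inventory.

    The config hash pins provenance — re-running an identical config
    reproduces byte-identical result tables, so hash + inventory fully
    identify a run's outputs.
    """
    import datetime

    from . import __version__

    inventory = []
    for f in files:
        f = Path(f)
        inventory.append(
            {
                "file": f.name,
                "bytes": f.stat().st_size,
                "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
            }
        )
    manifest = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "files": inventory,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
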