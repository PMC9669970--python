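"""Experiment configuration files and run manifests.

Configs are YAML with a fixed schema: a ``model`` name, optional
``overrides`` applied to that model's parameter dataclass (keys are
validated against the dataclass fields, unknown keys are rejected), an
optional ``protocol`` section, a ``seed`` and a ``dt``.  Every run writes
its fully resolved configuration plus provenance (package version, seed,
wall time) next to its outputs, so any output directory can be re-run
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import InvalidArgumentError

MODELS = ("rate", "discrete", "continuous", "race", "single_readout")

_TOP_KEYS = {"model", "overrides", "protocol", "seed", "dt", "duration", "out"}


@dataclass
class ExperimentConfig:
    model: str
    overrides: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    seed: int = 0
    dt: float = 0.1
    duration: float | None = None
    out: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InvalidArgumentError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )

    # -- materialization --------------------------------------------------
    def config_object(self):
        """Instantiate the model's parameter dataclass with overrides."""
        from .continuous import ContinuousConfig
        from .discrete import DiscreteConfig
        from .rate_model import RateModelParams
        from .readout import ReadoutSpec

        cls = {
            "rate": RateModelParams,
            "discrete": DiscreteConfig,
            "continuous": ContinuousConfig,
            "race": ReadoutSpec,
            "single_readout": ReadoutSpec,
        }[self.model]
        _check_keys(self.overrides, cls, "overrides")
        return cls(**{k: _coerce(v) for k, v in self.overrides.items()})

    def protocol_object(self):
        from .continuous import StimulusSpec
        from .discrete import StimulusProtocol

        if self.model == "discrete":
            _check_keys(self.protocol, StimulusProtocol, "protocol")
            kw = {k: _coerce(v) for k, v in self.protocol.items()}
            if "epochs" in kw:
                kw["epochs"] = tuple(tuple(e) for e in kw["epochs"])
            return StimulusProtocol(**kw)
        if self.model in ("continuous", "race", "single_readout"):
            _check_keys(self.protocol, StimulusSpec, "protocol")
            kw = {k: _coerce(v) for k, v in self.protocol.items()}
            if "epochs" in kw:
                kw["epochs"] = tuple(tuple(e) for e in kw["epochs"])
            if "onset_window" in kw:
                kw["onset_window"] = tuple(kw["onset_window"])
            return StimulusSpec(**kw)
        return None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "overrides": dict(self.overrides),
            "protocol": dict(self.protocol),
            "seed": self.seed,
            "dt": self.dt,
            "duration": self.duration,
            "out": self.out,
        }


def _coerce(v):
    if isinstance(v, list):
        return [_coerce(x) for x in v]
    return v


def _check_keys(d: dict, cls, section: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = sorted(set(d) - valid)
    if bad:
        raise InvalidArgumentError(
            f"unknown {section} key(s) {bad} for {cls.__name__}; "
            f"valid keys: {sorted(valid)}"
        )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidArgumentError("config root must be a mapping")
    bad = sorted(set(raw) - _TOP_KEYS)
    if bad:
        raise InvalidArgumentError(
            f"unknown top-level key(s) {bad}; valid keys: {sorted(_TOP_KEYS)}"
        )
    cfg = ExperimentConfig(**raw)
    cfg.config_object()  # validate overrides eagerly
    if cfg.protocol:
        cfg.protocol_object()
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def write_manifest(out_dir, cfg: ExperimentConfig, t_start: float, extra: dict | None = None) -> None:
    """Record the resolved configuration and provenance of a run."""
    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "package_version": __version__,
        "wall_time_s": round(time.time() - t_start, 2),
    }
    if extra:
        manifest.update(extra)
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_config(cfg, Path(out_dir, "config.yaml"))
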