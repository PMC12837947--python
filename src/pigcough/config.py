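"""Run configuration: YAML-backed structured settings and seed fan-out.

A single ``run_seed`` is expanded into independent per-stage seeds by
hashing the stage name (CRC-32) into a ``numpy.random.SeedSequence``
together with the run seed, so every stage is reproducible in isolation
and stages stay decoupled when one of them changes.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .audio import StftConfig, ValidationError
from .backbone import BackboneConfig
from .model import VariantConfig
from .synth import CoughSynthSpec, NoiseSynthSpec
from .tfds import TfdsConfig
from .train import TrainConfig


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(run_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


@dataclass
class SynthesisConfig:
    n_cough: int = 107
    n_noise: int = 590
    cough: CoughSynthSpec = field(default_factory=CoughSynthSpec)
    noise: NoiseSynthSpec = field(default_factory=NoiseSynthSpec)


@dataclass
class FeatureConfig:
    stft: StftConfig = field(default_factory=StftConfig)
    n_mels: int = 64
    fmin: float = 0.0
    fmax: float = 4000.0
    floor_eps: float = 1e-10
    log_base: str = "natural"
    target_len: int = 8000


@dataclass
class EvaluationConfig:
    test_frac: float = 0.15
    k_folds: int = 5
    n_permutations: int = 100
    calibration_bins: int = 10
    decision_threshold: float = 0.5


@dataclass
class RunConfig:
    run_seed: int = 0
    output_dir: str = "runs/default"
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    tfds: TfdsConfig = field(default_factory=TfdsConfig)
    variant: VariantConfig = field(default_factory=VariantConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


def _build(cls, data):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    if not dataclasses.is_dataclass(cls):
        if isinstance(cls, type) and isinstance(data, list) and cls is tuple:
            return tuple(data)
        return data
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default_factory() \
            if fields[name].default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build(type(default), value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; missing file or None yields defaults.

    ``overrides`` maps dotted keys (``"training.epochs"``) to values applied
    after the file.
    """
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _build(RunConfig, data)
    for key, value in (overrides or {}).items():
        obj = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        if not hasattr(obj, parts[-1]):
            raise ValidationError(f"unknown config key {key!r}")
        setattr(obj, parts[-1], value)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def setup_logging(run_dir: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if run_dir is not None:
        Path(run_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(run_dir) / "run.log"))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
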