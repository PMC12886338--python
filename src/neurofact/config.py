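"""YAML run configuration with strict parsing, and named seed substreams.

Unknown keys are rejected so a typo in a loss-weight name can never silently
zero a term. The resolved (default-filled) configuration is echoed back into
every run directory so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .losses import LossWeights
from .model import ModelConfig
from .phantom import PhantomConfig
from .training import OptimConfig


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    cdaa: LossWeights = field(default_factory=LossWeights)
    optim: OptimConfig = field(default_factory=OptimConfig)
    seed: int = 0


_SECTIONS = {"phantom": PhantomConfig, "model": ModelConfig,
             "cdaa": LossWeights, "optim": OptimConfig}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValidationError(
            f"unknown key(s) {unknown} in section '{section}'")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValidationError(f"bad value in section '{section}': {exc}")


def load_config(path) -> RunConfig:
    """Parse a YAML file into a fully validated RunConfig (strict keys)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = sorted(set(raw) - set(_SECTIONS) - {"seed"})
    if unknown:
        raise ValidationError(f"unknown top-level key(s) {unknown}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sect = raw.get(name, {})
        if not isinstance(sect, dict):
            raise ValidationError(f"section '{name}' must be a mapping")
        # lists from YAML become tuples where dataclasses expect them
        sect = {k: tuple(v) if isinstance(v, list) else v
                for k, v in sect.items()}
        kwargs[name] = _build_section(cls, sect, name)
    kwargs["seed"] = int(raw.get("seed", 0))
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> Path:
    """Write the resolved configuration back out as YAML."""
    path = Path(path)
    data = {name: asdict(getattr(cfg, name)) for name in _SECTIONS}
    for sect in data.values():
        for k, v in sect.items():
            if isinstance(v, tuple):
                sect[k] = list(v)
    data["seed"] = cfg.seed
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# Seeding: named substreams of one global seed
# --------------------------------------------------------------------------

_GLOBAL_SEED: int | None = None


def set_global_seed(seed: int) -> None:
    """Register the run seed all named substreams derive from."""
    global _GLOBAL_SEED
    _GLOBAL_SEED = int(seed)


def get_stream(name: str, seed: int | None = None) -> np.random.Generator:
    """Independent generator for the named component.

    The stream depends only on (seed, name), so e.g. changing the batch size
    or adding streams never perturbs the phantom stream.
    """
    if seed is None:
        seed = _GLOBAL_SEED
    if seed is None:
        raise ValidationError("no global seed set; call set_global_seed")
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def substream_seed(name: str, seed: int | None = None) -> int:
    """A 31-bit integer seed derived from the named substream."""
    return int(get_stream(name, seed).integers(0, 2**31))
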