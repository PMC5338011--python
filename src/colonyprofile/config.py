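"""Run configuration: one flat YAML file driving simulate / analyze runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from colonyprofile.preprocess import PreprocessParams
from colonyprofile.radial_profile import RadialSweepParams
from colonyprofile.synthetic_data import SyntheticColonySpec


class ConfigError(ValueError):
    """Invalid run configuration; message carries field-level detail."""


@dataclass
class InputPaths:
    green_tiff: str
    red_tiff: str
    pixel_size_um: float
    center_px: tuple[float, float]
    inoc_radius_um: float


@dataclass
class RunConfig:
    """Exactly one of ``inputs`` (real TIFF pair) or ``synthetic`` is set."""

    output_dir: str
    inputs: InputPaths | None = None
    synthetic: SyntheticColonySpec | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    sweep: RadialSweepParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ConfigError("exactly one of 'inputs' or 'synthetic' must be given")


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    inputs = None
    if "inputs" in raw:
        sec = dict(raw["inputs"])
        if "center_px" in sec:
            sec["center_px"] = tuple(sec["center_px"])
        inputs = _build(InputPaths, sec, "inputs")
    synthetic = None
    if "synthetic" in raw:
        synthetic = _build(SyntheticColonySpec, dict(raw["synthetic"]), "synthetic")
    pp = _build(PreprocessParams, dict(raw.get("preprocess", {})), "preprocess")
    sweep = None
    if "sweep" in raw:
        sweep = _build(RadialSweepParams, dict(raw["sweep"]), "sweep")
    if "output_dir" not in raw:
        raise ConfigError("output_dir is required")
    try:
        return RunConfig(
            output_dir=str(raw["output_dir"]),
            inputs=inputs,
            synthetic=synthetic,
            preprocess=pp,
            sweep=sweep,
            seed=int(raw.get("seed", 0)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
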