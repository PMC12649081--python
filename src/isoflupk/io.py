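"""Configuration files, CSV schemas and run manifests.

All tables are plain CSV with header rows; time is hours (float),
concentrations ng/mL; censored values are flagged in a dedicated
``blq`` column and never stored as zeros in the value column.  Every
pipeline run emits a JSON manifest recording the command, the config
snapshot, the seed and SHA-256 digests of inputs and outputs, so a
deterministic command can be verified to reproduce byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .pk_model import PKParams
from .population import PopulationModel
from .synthetic import StudyConfig

__all__ = ["load_config", "config_to_dict", "RunManifest", "file_digest"]

_POP_KEYS = {"tv_ka", "tv_v_f", "tv_cl_f", "omega2_ka", "omega2_v", "omega2_cl", "stdev0"}


def _build_pop(section: dict) -> PopulationModel:
    unknown = set(section) - _POP_KEYS
    if unknown:
        raise ValueError(f"unknown population keys: {sorted(unknown)}")
    return PopulationModel(
        tv=PKParams(
            ka=float(section.get("tv_ka", 8.34)),
            cl_f=float(section.get("tv_cl_f", 10.1)),
            v_f=float(section.get("tv_v_f", 27.9)),
        ),
        omega2_ka=float(section.get("omega2_ka", 0.5969)),
        omega2_v=float(section.get("omega2_v", 0.1233)),
        omega2_cl=float(section.get("omega2_cl", 0.0492)),
        stdev0=float(section.get("stdev0", 0.187)),
    )


def load_config(path: str | Path | None = None, seed: int | None = None) -> StudyConfig:
    """Load a StudyConfig from YAML; absent path returns the defaults.

    The file has a flat ``study`` section mirroring StudyConfig fields
    and a ``population`` section (tv_ka, tv_v_f, tv_cl_f, omega2_*,
    stdev0).  Unknown keys raise, naming the offending key.
    """
    if path is None:
        cfg = StudyConfig()
        return dataclasses.replace(cfg, seed=seed) if seed is not None else cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(StudyConfig)} - {"pop"}
    study = raw.get("study", {}) or {}
    unknown = set(study) - known
    if unknown:
        raise ValueError(f"unknown study config keys: {sorted(unknown)}")
    kwargs = dict(study)
    for key in ("plasma_schedule_h", "urine_schedule_h"):
        if key in kwargs:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    if "population" in raw and raw["population"]:
        kwargs["pop"] = _build_pop(raw["population"])
    extra = set(raw) - {"study", "population"}
    if extra:
        raise ValueError(f"unknown config sections: {sorted(extra)}")
    if seed is not None:
        kwargs["seed"] = seed
    return StudyConfig(**kwargs)


def config_to_dict(config: StudyConfig) -> dict:
    """JSON-serializable snapshot of a StudyConfig."""
    d = dataclasses.asdict(config)
    d["plasma_schedule_h"] = list(d["plasma_schedule_h"])
    d["urine_schedule_h"] = list(d["urine_schedule_h"])
    return d


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: command, config, seed, file digests."""

    command: str
    config: dict
    seed: int | None
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    timestamp: str = ""
    version: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        from . import __version__

        self.timestamp = datetime.now(timezone.utc).isoformat()
        self.version = __version__
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
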