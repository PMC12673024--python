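"""Run configuration and provenance.

A run is fully described by a flat, YAML-serializable configuration:
geometry, baseline-conductivity file, protocol, fit settings, engine,
seed.  A stored configuration re-runs to identical outputs in the
deterministic engines, and every artifact carries a provenance record
(config hash, package version, stage timings).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import yaml

from .mesh.build import GeometryParams
from .personalize import FitSettings

__all__ = ["RunConfig", "ProvenanceRecord", "load_config", "save_config"]


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    baseline_file: str | None = None   # None = packaged defaults
    fit: FitSettings = field(default_factory=FitSettings)
    quiescent_ms: float = 1000.0
    cycle_length_ms: float = 600.0
    n_beats: int = 1
    engine: str = "eikonal"
    seed: int = 0
    output_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d["fit"] = asdict(self.fit)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ProvenanceRecord:
    config_hash: str
    package_version: str
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    created: float = field(default_factory=time.time)

    def as_dict(self) -> dict:
        return asdict(self)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def save_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geo_raw = raw.pop("geometry", {})
    for k in ("lv_epi_semi", "rv_center", "rv_epi_semi"):
        if k in geo_raw and isinstance(geo_raw[k], list):
            geo_raw[k] = tuple(geo_raw[k])
    fit_raw = raw.pop("fit", {})
    if "r_bounds_um" in fit_raw and isinstance(fit_raw["r_bounds_um"], list):
        fit_raw["r_bounds_um"] = tuple(fit_raw["r_bounds_um"])
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(geometry=GeometryParams(**geo_raw),
                     fit=FitSettings(**fit_raw), **raw)
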