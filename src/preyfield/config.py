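"""Run configuration: camera, prey, allometry and analysis options.

Configs are YAML mappings with optional sections; anything omitted falls
back to the deployed-instrument defaults.  Documented keys::

    camera:
      width_px: 1280
      height_px: 960
      hfov_deg: 31.0
      vfov_deg: 24.0
    prey:
      mean_mm: 43.0
      sd_mm: 4.3
      median_mm: 42.0
      min_mm: 31.0
      max_mm: 60.0
    allometry:
      a: 2.236e-6
      b: 3.314
    sensitivity:
      n: 1000
      seed: 0
      sd_px: 10.5            # near-boundary sd; omit to take it from the fit
      min_res_px: 14.9
      min_unres_px: 9.9
    simulate:                # forwarded to SimulationConfig
      true_density_per_m3: 48.0
      n_images: 124
      true_r_res_mm: 1949.0
      ...
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .density import AllometryParams
from .errors import ValidationError
from .optics import CameraModel, PreyLengthModel


@dataclass(frozen=True)
class RunConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    prey: PreyLengthModel = field(default_factory=PreyLengthModel)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    sensitivity: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = {
            "camera": asdict(self.camera),
            "prey": asdict(self.prey),
            "allometry": asdict(self.allometry),
            "sensitivity": self.sensitivity,
            "simulate": self.simulate,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = {"camera", "prey", "allometry", "sensitivity", "simulate"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config section(s) {sorted(unknown)}")
    try:
        return RunConfig(
            camera=CameraModel(**raw.get("camera", {})),
            prey=PreyLengthModel(**raw.get("prey", {})),
            allometry=AllometryParams(**raw.get("allometry", {})),
            sensitivity=dict(raw.get("sensitivity", {})),
            simulate=dict(raw.get("simulate", {})),
        )
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from None
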