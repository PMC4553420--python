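"""Run configuration: one file addressing every pipeline parameter by name.

The configuration is a nested mapping with sections ``geometry``, ``field``,
``designs``, ``imaging``, ``stats``, ``evaluation`` plus a master ``seed``
and an ``output`` directory.  It round-trips losslessly through YAML or
JSON; :func:`reference_config` writes a file with every default spelled
out.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import yaml

from .designs import DESIGN_NAMES
from .errors import ConfigError
from .field import FieldParams
from .geometry import LeafGeometry
from .imaging import ImageCalibration
from .stats import DEFAULT_SUBSTITUTION

__all__ = ["RunConfig", "load_config", "reference_config"]


@dataclass
class RunConfig:
    geometry: LeafGeometry = dc_field(default_factory=LeafGeometry)
    field: FieldParams = dc_field(default_factory=FieldParams)
    designs: list[str] = dc_field(default_factory=lambda: list(DESIGN_NAMES))
    imaging: ImageCalibration = dc_field(default_factory=ImageCalibration)
    substitution: float = DEFAULT_SUBSTITUTION
    quantile_rule: str = "fitted"
    pilot_mode: str = "measured"
    n_replicates: int = 200
    seed: int = 0
    output_dir: str = "pollendep_out"

    def to_dict(self) -> dict[str, Any]:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "field": dataclasses.asdict(self.field),
            "designs": list(self.designs),
            "imaging": {
                "magnification": self.imaging.magnification,
                "field_area_mm2": self.imaging.field_area_mm2,
                "image_width_px": self.imaging.image_width_px,
                "image_height_px": self.imaging.image_height_px,
            },
            "stats": {
                "substitution": self.substitution,
                "quantile_rule": self.quantile_rule,
                "pilot_mode": self.pilot_mode,
            },
            "evaluation": {"n_replicates": self.n_replicates},
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        def build(section: str, typ, known: dict):
            payload = raw.get(section, {})
            if not isinstance(payload, dict):
                raise ConfigError(section, "must be a mapping")
            for key in payload:
                if key not in known:
                    raise ConfigError(f"{section}.{key}", "unknown parameter")
            try:
                return typ(**payload)
            except (TypeError, ValueError) as exc:
                raise ConfigError(section, str(exc)) from exc

        geometry = build("geometry", LeafGeometry,
                         {f.name for f in dataclasses.fields(LeafGeometry)})
        field = build("field", FieldParams,
                      {f.name for f in dataclasses.fields(FieldParams)})
        imaging = build("imaging", ImageCalibration,
                        {"magnification", "field_area_mm2",
                         "image_width_px", "image_height_px"})
        designs = raw.get("designs", list(DESIGN_NAMES))
        for d in designs:
            if d not in DESIGN_NAMES:
                raise ConfigError("designs", f"unknown design '{d}'")
        stats = raw.get("stats", {})
        substitution = stats.get("substitution", DEFAULT_SUBSTITUTION)
        if not isinstance(substitution, (int, float)) or substitution <= 0:
            raise ConfigError("stats.substitution", "must be a positive number")
        quantile_rule = stats.get("quantile_rule", "fitted")
        if quantile_rule not in ("fitted", "empirical"):
            raise ConfigError("stats.quantile_rule", "must be 'fitted' or 'empirical'")
        pilot_mode = stats.get("pilot_mode", "measured")
        if pilot_mode not in ("measured", "truth"):
            raise ConfigError("stats.pilot_mode", "must be 'measured' or 'truth'")
        evaluation = raw.get("evaluation", {})
        n_replicates = evaluation.get("n_replicates", 200)
        if not isinstance(n_replicates, int) or n_replicates < 2:
            raise ConfigError("evaluation.n_replicates", "must be an integer >= 2")
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("seed", "must be an integer")
        return cls(
            geometry=geometry, field=field, designs=list(designs),
            imaging=imaging, substitution=float(substitution),
            quantile_rule=quantile_rule, pilot_mode=pilot_mode,
            n_replicates=n_replicates, seed=seed,
            output_dir=str(raw.get("output_dir", "pollendep_out")),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML or JSON config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    raw = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "config must be a mapping")
    return RunConfig.from_dict(raw)


def reference_config(path: str | Path) -> RunConfig:
    """Write a config file with every default value spelled out."""
    cfg = RunConfig()
    cfg.save(path)
    return cfg
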