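"""Self-contained synthetic fixture bundle.

Everything the test-suite and the worked examples need — one deposition
field, all five designs sampled once, one rendered 27-grain image and the
measurement table — generated from a single seed, with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .designs import PilotScan, SamplingDesign, make_design
from .field import DepositionField, generate_field
from .imaging import SpotImage, count_grains, render_spot_image
from .stats import SpotMeasurement, apply_censoring, measure_design

__all__ = ["FixtureBundle", "make_fixtures", "write_fixtures"]


@dataclass
class FixtureBundle:
    config: RunConfig
    field: DepositionField
    pilot: PilotScan
    designs: dict[str, SamplingDesign]
    measurements: dict[str, list[SpotMeasurement]]
    image: SpotImage
    seed: int

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for name, ms in self.measurements.items():
            for i, m in enumerate(ms):
                rows.append({
                    "design": name, "spot_index": i,
                    "x_cm": m.spot.x_cm, "y_cm": m.spot.y_cm,
                    "area_cm2": m.spot.area_cm2, "count": m.count,
                    "density": m.density, "censored": m.censored,
                })
        return pd.DataFrame(rows)


def make_fixtures(seed: int = 0, config: RunConfig | None = None) -> FixtureBundle:
    """Build the in-memory fixture bundle for ``seed``."""
    cfg = config or RunConfig()
    cfg.seed = int(seed)
    field = generate_field(cfg.field.with_seed(seed), cfg.geometry)
    pilot = PilotScan.from_field(field, mode=cfg.pilot_mode)
    designs = {
        name: make_design(name, cfg.geometry, pilot=pilot, seed=seed)
        for name in cfg.designs
    }
    measurements = {
        name: apply_censoring(measure_design(field, d, seed=seed),
                              cfg.substitution)
        for name, d in designs.items()
    }
    image = render_spot_image(27, cfg.imaging, seed=seed)
    return FixtureBundle(config=cfg, field=field, pilot=pilot, designs=designs,
                         measurements=measurements, image=image, seed=seed)


def write_fixtures(out_dir: str | Path, seed: int = 0,
                   config: RunConfig | None = None) -> FixtureBundle:
    """Write the bundle to ``out_dir`` (CSV + PNG); byte-stable for a seed."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_fixtures(seed, config)
    bundle.field.to_frame(grid_step_cm=0.5).to_csv(out / "field_grid.csv", index=False)
    bundle.measurements_frame().to_csv(out / "measurements.csv", index=False)
    pd.concat([d.to_frame() for d in bundle.designs.values()]).to_csv(
        out / "designs.csv", index=False)
    Image.fromarray(bundle.image.pixels, mode="L").save(out / "spot_image.png")
    bundle.image.truth_frame().to_csv(out / "image_truth.csv", index=False)
    detection = count_grains(bundle.image)
    pd.DataFrame({"diameter_um": detection.detected_diameters_um}).assign(
        count=detection.count, overlap_flag=detection.overlap_flag
    ).to_csv(out / "image_detections.csv", index=False)
    bundle.config.save(out / "config.yaml")
    return bundle
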