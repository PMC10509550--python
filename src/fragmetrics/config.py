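"""Pipeline configuration.

One structured file (YAML or JSON) drives the whole pipeline; CLI flags
override individual fields, and all randomness flows from the single
``seed``.  Measurement thresholds live here: the 3 mm fragmentation
linkage threshold, the minimum fragment area, the width estimator choice,
and the slide spacing used to turn per-slide areas into volumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .detectability import EXAMPLE_MODALITIES, ModalitySpec
from .mask_io import DEFAULT_LABEL_MAP, load_structured
from .synthetic import GeneratorConfig

__all__ = ["PipelineConfig", "load_pipeline_config", "load_modalities"]

_WIDTH_ESTIMATORS = ("inscribed_disk", "min_feret")


@dataclass
class PipelineConfig:
    """Everything the measure/summarize/detect stages need."""

    pixel_size_mm: float = 0.02
    slide_spacing_mm: float = 3.0
    linkage_threshold_mm: float = 3.0
    min_area_mm2: float = 0.001
    width_estimator: str = "inscribed_disk"
    seed: int = 0
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    modalities: tuple[ModalitySpec, ...] = EXAMPLE_MODALITIES
    generator: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        if min(self.pixel_size_mm, self.slide_spacing_mm, self.linkage_threshold_mm) <= 0:
            raise ValueError("pixel size, slide spacing and linkage threshold must be positive")
        if self.min_area_mm2 < 0:
            raise ValueError("min_area_mm2 must be non-negative")
        if self.width_estimator not in _WIDTH_ESTIMATORS:
            raise ValueError(
                f"width_estimator must be one of {_WIDTH_ESTIMATORS}, got {self.width_estimator!r}"
            )

    def make_generator_config(self, **overrides) -> GeneratorConfig:
        """Generator config consistent with this pipeline config."""
        if self.generator is not None:
            base = dataclasses.asdict(self.generator)
            # dataclasses.asdict flattens tuples to lists; restore nothing
            # fancy, GeneratorConfig accepts sequences
            base.update(overrides)
            return GeneratorConfig(**base)
        return GeneratorConfig(
            pixel_size_mm=self.pixel_size_mm,
            slide_spacing_mm=self.slide_spacing_mm,
            seed=self.seed,
            label_map=dict(self.label_map),
            **overrides,
        )

    def content_hash(self) -> str:
        """Stable hash of the configuration, for the run log."""
        payload = dataclasses.asdict(self)
        payload["modalities"] = [dataclasses.asdict(m) for m in self.modalities]
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional file plus overrides."""
    data: dict = {}
    if path is not None:
        data = load_structured(path)
    if "modalities" in data:
        data["modalities"] = tuple(
            ModalitySpec(**m) if isinstance(m, dict) else m for m in data["modalities"]
        )
    if "generator" in data and isinstance(data["generator"], dict):
        gen = dict(data["generator"])
        for key in (
            "width_range_mm",
            "depth_range_mm",
            "n_fragments_range",
            "n_slides_range",
            "separation_range_mm",
            "aspect_range",
            "slide_scale_range",
        ):
            if key in gen:
                gen[key] = tuple(gen[key])
        data["generator"] = GeneratorConfig(**gen)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def load_modalities(path: str | Path) -> tuple[ModalitySpec, ...]:
    """Read a modalities table (CSV with header, or JSON/YAML list)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        df = pd.read_csv(path)
        records = df.to_dict("records")
    else:
        raw = json.loads(path.read_text()) if path.suffix.lower() == ".json" else None
        if raw is None:
            import yaml

            raw = yaml.safe_load(path.read_text())
        records = raw if isinstance(raw, list) else raw.get("modalities", [])
    return tuple(
        ModalitySpec(
            name=str(r["name"]),
            resolution_mm=float(r["resolution_mm"]),
            imaging_depth_mm=float(r["imaging_depth_mm"]),
        )
        for r in records
    )
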