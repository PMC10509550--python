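"""Label-mask, annotation and table I/O.

The raw input to the pipeline is a per-slide *label mask*: a single-channel
integer raster in which each pixel carries one of four tissue classes
(background/lumen, vital tumor, normal mucosa, other tissue such as
fibrosis or muscle), together with a physical pixel size.  This module
defines that container, its file dialects (indexed PNG / single-plane
TIFF), GeoJSON luminal-surface polylines, the per-patient measurement
table, and YAML/JSON configuration reading.

Conventions fixed here and relied on everywhere else:

* coordinates are 0-based ``(row, col)`` with pixel-center semantics;
* all physical distances are in mm, areas in mm^2, volumes in mm^3;
* the pixel size is isotropic metadata supplied by the caller/config, never
  read from image headers (header conventions vary across scanners).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "DEFAULT_LABEL_MAP",
    "LabelMask",
    "LuminalSurface",
    "PatientRecord",
    "CohortInput",
    "read_mask",
    "write_mask",
    "infer_luminal_surface",
    "read_surface_geojson",
    "write_surface_geojson",
    "write_measurements",
    "read_measurements",
    "load_structured",
]

#: Default class encoding, matching the usual four-class tissue
#: segmentation of post-treatment rectal slides.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "background": 0,
    "tumor": 1,
    "mucosa": 2,
    "other": 3,
}

_REQUIRED_CLASSES = frozenset(DEFAULT_LABEL_MAP)

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class LabelMask:
    """A per-slide multi-class tissue raster with physical pixel size."""

    patient_id: str
    slide_id: str
    grid: np.ndarray
    pixel_size_mm: float
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D raster")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must be an integer raster")
        if not self.pixel_size_mm > 0:
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        missing = _REQUIRED_CLASSES - set(self.label_map)
        if missing:
            raise ValueError(f"label_map missing classes: {sorted(missing)}")
        known = set(self.label_map.values())
        present = set(np.unique(self.grid).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(
                f"grid contains values absent from label_map: {sorted(unknown)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one tissue class."""
        return self.grid == self.label_map[name]


@dataclass
class LuminalSurface:
    """Pixels of the tissue boundary facing the rectal lumen.

    ``points`` is an ``(n, 2)`` integer array of ``(row, col)`` pixel
    coordinates; every point is a tissue pixel 4-adjacent to a background
    pixel.  ``source`` records whether the surface came from an explicit
    annotation or was inferred from the mask.
    """

    points: np.ndarray
    source: str = "annotated"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.int64))
        if self.points.size == 0 or self.points.shape[1] != 2:
            raise ValueError("surface needs at least one (row, col) point")
        if self.source not in ("annotated", "inferred"):
            raise ValueError(f"unknown surface source {self.source!r}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PatientRecord:
    """One patient of a cohort: TRG label plus serial slides."""

    patient_id: str
    trg: int
    slides: list[LabelMask]
    surfaces: list[LuminalSurface] | None = None

    def __post_init__(self) -> None:
        if self.trg not in (2, 3):
            raise ValueError(f"trg must be 2 or 3, got {self.trg}")
        if not self.slides:
            raise ValueError("patient needs at least one slide")
        if self.surfaces is not None and len(self.surfaces) != len(self.slides):
            raise ValueError("surfaces must align 1:1 with slides")


@dataclass
class CohortInput:
    """The full study input: TRG 2/3 patients with their label masks."""

    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("cohort is empty")

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# raster I/O


def read_mask(
    path: str | Path,
    pixel_size_mm: float,
    label_map: Mapping[str, int] | None = None,
    patient_id: str = "",
    slide_id: str = "",
) -> LabelMask:
    """Read a single-channel indexed raster (PNG or TIFF) as a LabelMask.

    The grid is taken verbatim from the file (lossless round trip with
    :func:`write_mask`); every pixel value must appear in ``label_map``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = np.asarray(tifffile.imread(path))
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "P", "I", "I;16"):
                raise ValueError(
                    f"{path.name}: expected a single-channel raster, got mode {im.mode!r}"
                )
            grid = np.asarray(im)
    if grid.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel raster")
    lm = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    if not slide_id:
        slide_id = path.stem
    return LabelMask(
        patient_id=patient_id,
        slide_id=slide_id,
        grid=grid,
        pixel_size_mm=float(pixel_size_mm),
        label_map=lm,
    )


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a LabelMask grid to PNG (8-bit) or TIFF, losslessly."""
    path = Path(path)
    grid = mask.grid
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, grid.astype(np.uint16))
    else:
        if grid.min() < 0 or grid.max() > 255:
            raise ValueError("PNG dialect stores 8-bit labels; use TIFF instead")
        Image.fromarray(grid.astype(np.uint8), mode="L").save(path, format="PNG")
    return path


# ---------------------------------------------------------------------------
# luminal surface


def infer_luminal_surface(mask: LabelMask) -> LuminalSurface:
    """Infer the luminal surface from a label mask.

    The lumen is identified as the background connected component (4-
    connectivity) sharing the greatest boundary length with mucosa-class
    pixels; the surface is the set of tissue pixels 4-adjacent to that
    component.  Falls back to the largest background component when no
    background pixel touches mucosa.  Used when no explicit surface
    annotation is available.
    """
    bg = mask.class_mask("background")
    if not bg.any() or bg.all():
        raise ValueError("surface undefined: mask needs both background and tissue")
    labels, n = ndimage.label(bg, structure=_CROSS)
    mucosa = mask.class_mask("mucosa")

    counts = np.zeros(n + 1, dtype=np.int64)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(mucosa, shift, axis=axis)
        # roll wraps around; kill the wrapped border
        if axis == 0:
            if shift == 1:
                shifted[0, :] = False
            else:
                shifted[-1, :] = False
        else:
            if shift == 1:
                shifted[:, 0] = False
            else:
                shifted[:, -1] = False
        sel = shifted & (labels > 0)
        counts += np.bincount(labels[sel], minlength=n + 1)

    if counts[1:].max() > 0:
        lumen_label = int(np.argmax(counts[1:]) + 1)
    else:  # no mucosa contact anywhere: largest background component
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        sizes[0] = 0
        lumen_label = int(np.argmax(sizes))

    lumen = labels == lumen_label
    near_lumen = ndimage.binary_dilation(lumen, structure=_CROSS)
    surface = near_lumen & ~bg
    rows, cols = np.nonzero(surface)
    order = np.lexsort((rows, cols))  # left-to-right polyline order
    points = np.column_stack([rows[order], cols[order]])
    return LuminalSurface(points=points, source="inferred")


def write_surface_geojson(surface: LuminalSurface, path: str | Path) -> Path:
    """Write a surface polyline as a GeoJSON LineString in pixel units.

    GeoJSON coordinate order is ``[x, y]`` = ``[col, row]``.
    """
    path = Path(path)
    coords = [[int(c), int(r)] for r, c in surface.points]
    feature = {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {"kind": "luminal_surface", "source": surface.source},
    }
    path.write_text(json.dumps(feature, indent=1))
    return path


def read_surface_geojson(path: str | Path) -> LuminalSurface:
    feature = json.loads(Path(path).read_text())
    geom = feature.get("geometry", feature)
    if geom.get("type") != "LineString":
        raise ValueError(f"{path}: expected a LineString surface annotation")
    pts = np.array([[r, c] for c, r in geom["coordinates"]], dtype=np.int64)
    source = feature.get("properties", {}).get("source", "annotated")
    return LuminalSurface(points=pts, source=source)


# ---------------------------------------------------------------------------
# tables & config

#: Fixed column order of the per-patient measurement table.
MEASUREMENT_COLUMNS = (
    "patient_id",
    "trg",
    "pattern",
    "n_clusters",
    "max_width_mm",
    "min_depth_mm",
    "central_slide_area_mm2",
    "volume_mm3",
)


def write_measurements(rows: Sequence, path: str | Path) -> Path:
    """Serialize per-patient summary rows to CSV.

    Columns follow :data:`MEASUREMENT_COLUMNS`; numbers keep full repr
    precision so the table re-reads losslessly.
    """
    if len(rows) == 0:
        raise ValueError("refusing to write an empty measurement table")
    records = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in rows
    ]
    df = pd.DataFrame.from_records(records)
    df = df[[c for c in MEASUREMENT_COLUMNS if c in df.columns]]
    # shortest round-trip float repr keeps the table lossless
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return Path(path)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def load_structured(path: str | Path) -> dict:
    """Load a YAML or JSON configuration/manifest file as a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
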