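"""Synthetic label-mask cohorts with known ground truth.

Real post-chemoradiotherapy cohorts are not publicly deposited, so every
downstream stage is exercised against generated slides whose geometry is
known exactly.  The generator emulates the structure such a cohort
exhibits:

* two regression patterns — *shrinkage* (one residual bulk) and
  *fragmentation* (>= 2 tumor clusters separated by >= 3 mm edge-to-edge,
  enforced by construction);
* fragment short-axis widths spanning 0.06-14.9 mm and tumor-to-lumen
  depths spanning 0.001-8.9 mm (the ranges observed across TRG 2/3
  resection specimens), drawn log-uniformly so the submillimeter regime is
  well represented;
* several serial slides per patient, with each fragment at full size on
  the patient's central slide and smaller cross-sections on neighbors.

Each slide is a four-class raster: a background (lumen) band on top, the
luminal surface, a mucosa band beneath it, "other" tissue (fibrosis,
muscle) below, and tumor fragments rendered as filled capsules (rectangles
with semicircular caps).  Capsules make the true short-axis width
analytically known — it is the capsule diameter — so width recovery is a
well-posed test; the capsule's top point sits exactly at the drawn depth
below the surface pixel row.

Every draw flows from ``(seed, patient_index)``, so patients are
independently bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mask_io import (
    DEFAULT_LABEL_MAP,
    CohortInput,
    LabelMask,
    LuminalSurface,
    PatientRecord,
)

__all__ = [
    "GeneratorConfig",
    "FragmentTruth",
    "SyntheticGroundTruth",
    "generate_patient",
    "generate_cohort",
    "write_truths",
    "read_truths",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the observed cohort structure: 30 patients, 16/30
    fragmentation, widths 0.06-14.9 mm, depths 0.001-8.9 mm, ~6-7 serial
    slides per patient (198/30), 3 mm slide spacing, 0.02 mm/px (so the
    smallest 0.06 mm fragment is still 3 px wide).
    """

    n_patients: int = 30
    p_fragmentation: float = 16 / 30
    width_range_mm: tuple[float, float] = (0.06, 14.9)
    depth_range_mm: tuple[float, float] = (0.001, 8.9)
    n_fragments_range: tuple[int, int] = (2, 5)
    n_slides_range: tuple[int, int] = (3, 10)
    pixel_size_mm: float = 0.02
    slide_spacing_mm: float = 3.0
    seed: int = 0
    # geometry nuisance parameters
    separation_range_mm: tuple[float, float] = (3.2, 6.0)  # edge-to-edge gaps
    aspect_range: tuple[float, float] = (1.0, 2.5)  # long axis / width
    tilt_max_deg: float = 25.0
    slide_scale_range: tuple[float, float] = (0.5, 0.95)  # off-center slides
    mucosa_band_mm: float = 0.5
    background_band_mm: float = 0.6
    margin_mm: float = 1.0
    max_raster_px: int = 4096
    max_attempts: int = 25
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        for name in (
            "width_range_mm",
            "depth_range_mm",
            "n_fragments_range",
            "n_slides_range",
            "separation_range_mm",
            "aspect_range",
            "slide_scale_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high, got {lo}, {hi}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.p_fragmentation <= 1.0:
            raise ValueError("p_fragmentation must be in [0, 1]")
        if self.width_range_mm[0] <= 0 or self.depth_range_mm[0] < 0:
            raise ValueError("widths must be positive and depths non-negative")
        if self.n_fragments_range[0] < 2:
            raise ValueError("fragmentation needs at least 2 fragments")
        if self.n_slides_range[0] < 1:
            raise ValueError("need at least one slide per patient")
        if self.pixel_size_mm <= 0 or self.slide_spacing_mm <= 0:
            raise ValueError("pixel size and slide spacing must be positive")
        if self.separation_range_mm[0] < 3.0:
            raise ValueError("fragment separation below the 3 mm fragmentation rule")


@dataclass
class FragmentTruth:
    """Exact geometry of one generated fragment (full-size rendering)."""

    center_mm: tuple[float, float]  # (row, col) from raster origin
    width_mm: float  # capsule diameter = short axis
    length_mm: float  # total long-axis extent
    orientation_deg: float
    lumen_dist_mm: float  # capsule top point to surface pixel row
    slide_span: tuple[int, int]  # inclusive slide indices where present


@dataclass
class SyntheticGroundTruth:
    """Per-patient oracle record for recovery tests."""

    patient_id: str
    trg: int
    pattern: str
    fragments: list[FragmentTruth]
    n_slides: int
    central_slide: int
    slide_areas_mm2: dict[str, float]  # rasterized tumor area per slide
    volume_mm3: float
    max_width_mm: float
    min_depth_mm: float
    seed_entropy: tuple[int, int]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    if lo <= 0:  # degenerate guard for a zero lower depth bound
        lo = max(lo, 1e-6)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _rasterize_capsule(
    grid: np.ndarray,
    value: int,
    center: tuple[float, float],
    half_seg_px: float,
    radius_px: float,
    theta_rad: float,
) -> None:
    """Fill pixels whose centers lie within ``radius_px`` of the capsule's
    axis segment.  Operates on a local bounding window only."""
    cr, cc = center
    ur, uc = np.sin(theta_rad), np.cos(theta_rad)
    er = abs(ur) * half_seg_px + radius_px + 1.0
    ec = abs(uc) * half_seg_px + radius_px + 1.0
    r0 = max(int(np.floor(cr - er)), 0)
    r1 = min(int(np.ceil(cr + er)) + 1, grid.shape[0])
    c0 = max(int(np.floor(cc - ec)), 0)
    c1 = min(int(np.ceil(cc + ec)) + 1, grid.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cols = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    # project onto the axis, clamp to the segment, take distance
    t = rows * ur + cols * uc
    t = np.clip(t, -half_seg_px, half_seg_px)
    dr = rows - t * ur
    dc = cols - t * uc
    inside = dr * dr + dc * dc <= radius_px * radius_px
    window = grid[r0:r1, c0:c1]
    window[inside] = value


def generate_patient(
    cfg: GeneratorConfig, patient_index: int, trg: int | None = None
) -> tuple[list[LabelMask], list[LuminalSurface], SyntheticGroundTruth]:
    """Generate one patient's serial slides, surfaces, and ground truth.

    Deterministic given ``(cfg.seed, patient_index)``.  Draws that do not
    fit the maximum raster extent are rejected and redrawn up to
    ``cfg.max_attempts`` times before raising.
    """
    rng = np.random.default_rng((cfg.seed, patient_index))
    px = cfg.pixel_size_mm
    if trg is None:
        trg = 2 if patient_index % 2 == 0 else 3
    patient_id = f"P{patient_index:03d}"

    surf_row = int(round(cfg.background_band_mm / px))
    band_px = max(int(round(cfg.mucosa_band_mm / px)), 1)
    margin_px = cfg.margin_mm / px

    for _attempt in range(cfg.max_attempts):
        fragmentation = rng.random() < cfg.p_fragmentation
        if fragmentation:
            lo, hi = cfg.n_fragments_range
            n_frag = int(rng.integers(lo, hi + 1))
        else:
            n_frag = 1
        widths = np.array([_log_uniform(rng, *cfg.width_range_mm) for _ in range(n_frag)])
        aspects = rng.uniform(*cfg.aspect_range, size=n_frag)
        thetas = np.deg2rad(rng.uniform(-cfg.tilt_max_deg, cfg.tilt_max_deg, size=n_frag))
        depths = np.array([_log_uniform(rng, *cfg.depth_range_mm) for _ in range(n_frag)])
        gaps = rng.uniform(*cfg.separation_range_mm, size=max(n_frag - 1, 0))
        n_slides = int(rng.integers(cfg.n_slides_range[0], cfg.n_slides_range[1] + 1))
        central = n_slides // 2
        left = rng.integers(0, central + 1, size=n_frag)
        right = rng.integers(0, n_slides - central, size=n_frag)
        scales = rng.uniform(*cfg.slide_scale_range, size=(n_frag, n_slides))

        radii = widths / 2.0 / px
        half_segs = (widths * aspects - widths) / 2.0 / px  # >= 0
        ext_r = np.abs(np.sin(thetas)) * half_segs + radii  # vertical half-extent
        ext_c = np.abs(np.cos(thetas)) * half_segs + radii
        depth_px = depths / px

        # lay fragments out left to right; bounding boxes separated by the
        # drawn gaps, which lower-bound the true edge-to-edge distance
        centers_c = np.empty(n_frag)
        cursor = margin_px
        for i in range(n_frag):
            centers_c[i] = cursor + ext_c[i]
            cursor += 2.0 * ext_c[i]
            if i < n_frag - 1:
                cursor += gaps[i] / px
        n_cols = int(np.ceil(cursor + margin_px))
        centers_r = surf_row + depth_px + ext_r  # capsule top at drawn depth
        n_rows = int(np.ceil((centers_r + ext_r).max() + margin_px))
        if n_cols <= cfg.max_raster_px and n_rows <= cfg.max_raster_px:
            break
    else:
        raise RuntimeError(
            f"geometry infeasible for patient {patient_index} after "
            f"{cfg.max_attempts} draws (raster limit {cfg.max_raster_px} px)"
        )

    lm = cfg.label_map
    base = np.full((n_rows, n_cols), lm["other"], dtype=np.uint8)
    base[:surf_row, :] = lm["background"]
    base[surf_row : surf_row + band_px, :] = lm["mucosa"]

    surface_points = np.column_stack(
        [np.full(n_cols, surf_row, dtype=np.int64), np.arange(n_cols, dtype=np.int64)]
    )

    slides: list[LabelMask] = []
    surfaces: list[LuminalSurface] = []
    slide_areas: dict[str, float] = {}
    for k in range(n_slides):
        grid = base.copy()
        for i in range(n_frag):
            if not (central - left[i] <= k <= central + right[i]):
                continue
            lam = 1.0 if k == central else float(scales[i, k])
            _rasterize_capsule(
                grid,
                lm["tumor"],
                (float(centers_r[i]), float(centers_c[i])),
                lam * float(half_segs[i]),
                lam * float(radii[i]),
                float(thetas[i]),
            )
        slide_id = f"S{k:02d}"
        slides.append(
            LabelMask(
                patient_id=patient_id,
                slide_id=slide_id,
                grid=grid,  # uint8 keeps a full cohort small in memory
                pixel_size_mm=px,
                label_map=dict(lm),
            )
        )
        surfaces.append(LuminalSurface(points=surface_points.copy(), source="annotated"))
        slide_areas[slide_id] = float((grid == lm["tumor"]).sum()) * px * px

    volume = float(sum(slide_areas.values())) * cfg.slide_spacing_mm
    fragments = [
        FragmentTruth(
            center_mm=(float(centers_r[i] * px), float(centers_c[i] * px)),
            width_mm=float(widths[i]),
            length_mm=float(widths[i] * aspects[i]),
            orientation_deg=float(np.rad2deg(thetas[i])),
            lumen_dist_mm=float(depths[i]),
            slide_span=(int(central - left[i]), int(central + right[i])),
        )
        for i in range(n_frag)
    ]
    truth = SyntheticGroundTruth(
        patient_id=patient_id,
        trg=trg,
        pattern="fragmentation" if fragmentation else "shrinkage",
        fragments=fragments,
        n_slides=n_slides,
        central_slide=central,
        slide_areas_mm2=slide_areas,
        volume_mm3=volume,
        max_width_mm=float(widths.max()),
        min_depth_mm=float(depths.min()),
        seed_entropy=(cfg.seed, patient_index),
    )
    return slides, surfaces, truth


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[CohortInput, list[SyntheticGroundTruth]]:
    """Generate a full cohort; TRG 2/3 assigned alternately by index."""
    patients: list[PatientRecord] = []
    truths: list[SyntheticGroundTruth] = []
    for idx in range(cfg.n_patients):
        slides, surfaces, truth = generate_patient(cfg, idx)
        patients.append(
            PatientRecord(
                patient_id=truth.patient_id,
                trg=truth.trg,
                slides=slides,
                surfaces=surfaces,
            )
        )
        truths.append(truth)
    return CohortInput(patients=patients), truths


# ---------------------------------------------------------------------------
# truth (de)serialization


def write_truths(truths: list[SyntheticGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([dataclasses.asdict(t) for t in truths], indent=1))
    return path


def read_truths(path: str | Path) -> list[SyntheticGroundTruth]:
    raw = json.loads(Path(path).read_text())
    out = []
    for t in raw:
        frags = [
            FragmentTruth(
                center_mm=tuple(f["center_mm"]),
                width_mm=f["width_mm"],
                length_mm=f["length_mm"],
                orientation_deg=f["orientation_deg"],
                lumen_dist_mm=f["lumen_dist_mm"],
                slide_span=tuple(f["slide_span"]),
            )
            for f in t["fragments"]
        ]
        out.append(
            SyntheticGroundTruth(
                patient_id=t["patient_id"],
                trg=t["trg"],
                pattern=t["pattern"],
                fragments=frags,
                n_slides=t["n_slides"],
                central_slide=t["central_slide"],
                slide_areas_mm2=t["slide_areas_mm2"],
                volume_mm3=t["volume_mm3"],
                max_width_mm=t["max_width_mm"],
                min_depth_mm=t["min_depth_mm"],
                seed_entropy=tuple(t["seed_entropy"]),
            )
        )
    return out
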