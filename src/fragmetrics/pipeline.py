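"""End-to-end orchestration: simulate -> measure -> summarize -> detect.

All stages write plain-text artifacts (PNG masks, GeoJSON surfaces, CSV
tables, JSON summaries) into a directory; re-running with the same config
and seed is byte-identical.  Patients are processed one at a time so a
full cohort never needs to be resident in memory at once.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    PatientSummary,
    build_table2,
    empirical_cdf,
    fraction_below,
    summarize_patient,
)
from .config import PipelineConfig
from .detectability import DetectabilityReport, detection_table
from .mask_io import (
    CohortInput,
    PatientRecord,
    infer_luminal_surface,
    read_mask,
    read_surface_geojson,
    write_mask,
    write_measurements,
    write_surface_geojson,
)
from .morphometry import (
    Fragment,
    classify_pattern,
    extract_fragments,
    slide_tumor_area,
)
from .synthetic import GeneratorConfig, generate_patient, write_truths

__all__ = [
    "simulate_to_dir",
    "iter_cohort_dir",
    "measure_patient",
    "run_pipeline",
]

FRAGMENT_COLUMNS = (
    "patient_id",
    "slide_id",
    "fragment_id",
    "cluster_id",
    "pixel_count",
    "area_mm2",
    "width_mm",
    "min_lumen_dist_mm",
)


def simulate_to_dir(gen_cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write it as a mask directory with manifest.

    Layout: ``masks/<pid>_<sid>.png``, ``surfaces/<pid>_<sid>.json``
    (GeoJSON), ``cohort.json`` (manifest with TRG labels, pixel size and
    slide spacing), ``truth.json`` (generator ground truth).
    """
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "surfaces").mkdir(exist_ok=True)
    manifest: dict = {
        "pixel_size_mm": gen_cfg.pixel_size_mm,
        "slide_spacing_mm": gen_cfg.slide_spacing_mm,
        "label_map": dict(gen_cfg.label_map),
        "patients": [],
    }
    truths = []
    for idx in range(gen_cfg.n_patients):
        slides, surfaces, truth = generate_patient(gen_cfg, idx)
        entry = {"patient_id": truth.patient_id, "trg": truth.trg, "slides": []}
        for mask, surf in zip(slides, surfaces):
            stem = f"{mask.patient_id}_{mask.slide_id}"
            write_mask(mask, out / "masks" / f"{stem}.png")
            write_surface_geojson(surf, out / "surfaces" / f"{stem}.json")
            entry["slides"].append(
                {
                    "slide_id": mask.slide_id,
                    "mask": f"masks/{stem}.png",
                    "surface": f"surfaces/{stem}.json",
                }
            )
        manifest["patients"].append(entry)
        truths.append(truth)
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1))
    write_truths(truths, out / "truth.json")
    return out


def iter_cohort_dir(cohort_dir: str | Path) -> Iterator[PatientRecord]:
    """Lazily read a simulated/curated cohort directory patient by patient."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "cohort.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    px = float(manifest["pixel_size_mm"])
    label_map = {k: int(v) for k, v in manifest["label_map"].items()}
    for entry in manifest["patients"]:
        slides, surfaces = [], []
        for s in entry["slides"]:
            mask = read_mask(
                cohort_dir / s["mask"],
                pixel_size_mm=px,
                label_map=label_map,
                patient_id=entry["patient_id"],
                slide_id=s["slide_id"],
            )
            slides.append(mask)
            surfaces.append(
                read_surface_geojson(cohort_dir / s["surface"])
                if s.get("surface")
                else None
            )
        if any(s is None for s in surfaces):
            surfaces = [
                s if s is not None else infer_luminal_surface(m)
                for s, m in zip(surfaces, slides)
            ]
        yield PatientRecord(
            patient_id=entry["patient_id"],
            trg=int(entry["trg"]),
            slides=slides,
            surfaces=surfaces,
        )


def measure_patient(
    record: PatientRecord, cfg: PipelineConfig
) -> tuple[list[Fragment], PatientSummary]:
    """Run the full per-patient measurement chain on one PatientRecord."""
    fragments: list[Fragment] = []
    slide_areas: dict[str, float] = {}
    surfaces = record.surfaces or [None] * len(record.slides)
    for mask, surface in zip(record.slides, surfaces):
        frs = extract_fragments(
            mask,
            min_area_mm2=cfg.min_area_mm2,
            surface=surface,
            width_method=cfg.width_estimator,  # type: ignore[arg-type]
        )
        fragments.extend(frs)
        slide_areas[mask.slide_id] = slide_tumor_area(mask)
    pattern = classify_pattern(
        fragments,
        pixel_size_mm=record.slides[0].pixel_size_mm,
        linkage_threshold_mm=cfg.linkage_threshold_mm,
    )
    summary = summarize_patient(
        record.patient_id,
        record.trg,
        fragments,
        slide_areas,
        pattern,
        slide_spacing_mm=cfg.slide_spacing_mm,
    )
    return fragments, summary


def _fragment_frame(
    per_patient: dict[str, list[Fragment]]
) -> pd.DataFrame:
    rows = []
    for pid, frags in per_patient.items():
        for f in frags:
            rows.append(
                {
                    "patient_id": pid,
                    "slide_id": f.slide_id,
                    "fragment_id": f.fragment_id,
                    "cluster_id": f.cluster_id,
                    "pixel_count": f.pixel_count,
                    "area_mm2": f.area_mm2,
                    "width_mm": f.width_mm,
                    "min_lumen_dist_mm": f.min_lumen_dist_mm,
                }
            )
    return pd.DataFrame(rows, columns=list(FRAGMENT_COLUMNS))


def _ecdf_frame(summaries: list[PatientSummary], attr: str) -> pd.DataFrame:
    """Stacked ECDF tables (combined + per pattern) for one measure."""
    frames = []
    groups = [("all", summaries)] + [
        (p, [s for s in summaries if s.pattern == p])
        for p in ("fragmentation", "shrinkage")
    ]
    for name, subset in groups:
        if not subset:
            continue
        tab = empirical_cdf([getattr(s, attr) for s in subset])
        tab.insert(0, "group", name)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    cohort_dir: str | Path | None = None,
    cohort: CohortInput | Iterable[PatientRecord] | None = None,
    simulate_n: int | None = None,
    plot: bool = False,
) -> dict:
    """Run measure -> summarize -> detect and write all artifacts.

    Input is one of: an on-disk cohort directory, an in-memory cohort, or
    ``simulate_n`` to generate one first (written next to the outputs so
    the run is fully traceable).  Returns the cohort summary dict.
    """
    out = Path(out_dir)
    if sum(x is not None for x in (cohort_dir, cohort, simulate_n)) != 1:
        raise ValueError("provide exactly one of cohort_dir, cohort, simulate_n")
    if simulate_n is not None:
        gen_cfg = cfg.make_generator_config(n_patients=simulate_n)
        cohort_dir = simulate_to_dir(gen_cfg, out / "cohort")
    if cohort_dir is not None:
        records: Iterable[PatientRecord] = iter_cohort_dir(cohort_dir)
    else:
        records = cohort.patients if isinstance(cohort, CohortInput) else cohort  # type: ignore[union-attr]

    per_patient: dict[str, list[Fragment]] = {}
    summaries: list[PatientSummary] = []
    n_slides = 0
    for record in records:
        fragments, summary = measure_patient(record, cfg)
        per_patient[record.patient_id] = fragments
        summaries.append(summary)
        n_slides += len(record.slides)
    if not summaries:
        raise ValueError("empty cohort: nothing to measure")

    out.mkdir(parents=True, exist_ok=True)
    frag_df = _fragment_frame(per_patient)
    frag_df.to_csv(out / "fragments.csv", index=False)
    write_measurements(summaries, out / "patient_summaries.csv")

    table2 = build_table2(summaries)
    (out / "table2.json").write_text(json.dumps(table2, indent=1))
    _ecdf_frame(summaries, "max_width_mm").to_csv(out / "ecdf_width.csv", index=False)
    _ecdf_frame(summaries, "min_depth_mm").to_csv(out / "ecdf_depth.csv", index=False)

    report: DetectabilityReport = detection_table(
        summaries, cfg.modalities, fragments_by_patient=per_patient
    )
    report.per_modality.to_csv(out / "detectability_modalities.csv", index=False)
    report.per_patient.to_csv(out / "detectability_patients.csv", index=False)

    if plot:
        from .plotting import plot_cohort_cdfs

        plot_cohort_cdfs(summaries, out / "cohort_cdfs.png")

    widths = [s.max_width_mm for s in summaries]
    depths = [s.min_depth_mm for s in summaries]
    summary_json = {
        "n_patients": len(summaries),
        "n_slides": n_slides,
        "n_fragments": int(len(frag_df)),
        "n_fragmentation": sum(s.pattern == "fragmentation" for s in summaries),
        "n_shrinkage": sum(s.pattern == "shrinkage" for s in summaries),
        "required_resolution_mm": report.required_resolution_mm,
        "required_depth_mm": report.required_depth_mm,
        "fraction_width_below_1mm": fraction_below(widths, 1.0),
        "fraction_width_below_0p2mm": fraction_below(widths, 0.2),
        "fraction_depth_within_0p01mm": fraction_below(depths, 0.01, strict=False),
        "fraction_depth_within_0p5mm": fraction_below(depths, 0.5, strict=False),
        "table2": table2,
    }
    (out / "cohort_summary.json").write_text(
        json.dumps(summary_json, indent=1, default=float)
    )

    log_lines = [
        f"fragmetrics {__version__}",
        f"config_hash {cfg.content_hash()}",
        f"seed {cfg.seed}",
        f"patients {len(summaries)} slides {n_slides} fragments {len(frag_df)}",
        "outputs fragments.csv patient_summaries.csv table2.json "
        "ecdf_width.csv ecdf_depth.csv detectability_modalities.csv "
        "detectability_patients.csv cohort_summary.json",
    ]
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary_json
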