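"""Imaging-feasibility analysis.

Translates cohort morphometry into requirements on an imaging technique.
A technique is characterized by two numbers: its in-plane spatial
resolution and the depth below the luminal surface down to which it can
resolve structures.  A patient's residual tumor is considered *detectable*
by a technique when

* **marginal criterion** (default): the patient's widest fragment is at
  least as wide as the resolution AND their shallowest fragment lies
  within the imaging depth — two conditions that may be met by different
  fragments;
* **joint criterion** (stricter): a single fragment is both wide enough
  and shallow enough.

The cohort-level requirement pair — the resolution needed to see every
patient's widest fragment and the depth needed to reach every patient's
shallowest one — is the marginal reading taken over the whole cohort.
Detection is purely geometric; tissue contrast is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import PatientSummary
from .morphometry import Fragment

__all__ = [
    "ModalitySpec",
    "DetectabilityReport",
    "EXAMPLE_MODALITIES",
    "cohort_requirements",
    "patient_detectable",
    "detection_table",
]


@dataclass(frozen=True)
class ModalitySpec:
    """An imaging technique's (resolution, imaging depth) pair, in mm."""

    name: str
    resolution_mm: float
    imaging_depth_mm: float

    def __post_init__(self) -> None:
        if self.resolution_mm <= 0 or self.imaging_depth_mm <= 0:
            raise ValueError("resolution and imaging depth must be positive")


#: Illustrative order-of-magnitude specs for common techniques; the exact
#: numbers depend heavily on the specific setup and are user-configurable.
EXAMPLE_MODALITIES: tuple[ModalitySpec, ...] = (
    ModalitySpec("confocal_microscopy", 0.001, 0.3),
    ModalitySpec("OCT", 0.01, 2.0),
    ModalitySpec("photoacoustic", 0.1, 30.0),
    ModalitySpec("ultrasound", 0.3, 100.0),
    ModalitySpec("MRI", 1.0, 1000.0),
    ModalitySpec("CT", 0.5, 1000.0),
)


@dataclass
class DetectabilityReport:
    """Cohort-level feasibility result."""

    required_resolution_mm: float
    required_depth_mm: float
    per_modality: pd.DataFrame  # name, resolution, depth, fractions
    per_patient: pd.DataFrame  # patient_id x modality flags


def cohort_requirements(
    summaries: Sequence[PatientSummary],
) -> tuple[float, float]:
    """(resolution, imaging depth) needed to detect every patient.

    Resolution must reach the *smallest* of the per-patient widest
    fragments; depth must reach the *largest* of the per-patient
    shallowest lumen distances.
    """
    if not summaries:
        raise ValueError("empty cohort")
    return (
        min(s.max_width_mm for s in summaries),
        max(s.min_depth_mm for s in summaries),
    )


def patient_detectable(
    summary: PatientSummary,
    modality: ModalitySpec,
    joint: bool = False,
    fragments: Iterable[Fragment] | None = None,
) -> bool:
    """Whether a technique would have detected this patient's tumor.

    The joint criterion needs the per-fragment table, since it pairs each
    fragment's width with its own lumen distance.
    """
    if joint:
        if fragments is None:
            raise ValueError("joint criterion needs the per-fragment table")
        return any(
            f.width_mm >= modality.resolution_mm
            and f.min_lumen_dist_mm <= modality.imaging_depth_mm
            for f in fragments
        )
    return (
        summary.max_width_mm >= modality.resolution_mm
        and summary.min_depth_mm <= modality.imaging_depth_mm
    )


def detection_table(
    summaries: Sequence[PatientSummary],
    modalities: Sequence[ModalitySpec] = EXAMPLE_MODALITIES,
    fragments_by_patient: Mapping[str, Sequence[Fragment]] | None = None,
) -> DetectabilityReport:
    """Per-modality detectable fractions under both criteria.

    The joint-criterion columns are emitted only when per-fragment tables
    are supplied.
    """
    if not summaries or not modalities:
        raise ValueError("need at least one patient and one modality")
    req_res, req_depth = cohort_requirements(summaries)
    flags = []
    for s in summaries:
        row: dict = {"patient_id": s.patient_id, "trg": s.trg, "pattern": s.pattern}
        for m in modalities:
            row[f"{m.name}__marginal"] = patient_detectable(s, m)
            if fragments_by_patient is not None:
                row[f"{m.name}__joint"] = patient_detectable(
                    s, m, joint=True, fragments=fragments_by_patient[s.patient_id]
                )
        flags.append(row)
    per_patient = pd.DataFrame(flags)

    rows = []
    for m in modalities:
        row = {
            "modality": m.name,
            "resolution_mm": m.resolution_mm,
            "imaging_depth_mm": m.imaging_depth_mm,
            "fraction_detectable_marginal": float(
                per_patient[f"{m.name}__marginal"].mean()
            ),
        }
        if fragments_by_patient is not None:
            row["fraction_detectable_joint"] = float(
                per_patient[f"{m.name}__joint"].mean()
            )
        rows.append(row)
    return DetectabilityReport(
        required_resolution_mm=req_res,
        required_depth_mm=req_depth,
        per_modality=pd.DataFrame(rows),
        per_patient=per_patient,
    )
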