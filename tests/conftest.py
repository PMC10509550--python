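from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fragmetrics import (
    DEFAULT_LABEL_MAP,
    GeneratorConfig,
    LabelMask,
    PipelineConfig,
    generate_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_mask(
    grid, pixel_size_mm: float = 0.02, patient_id: str = "P", slide_id: str = "S"
) -> LabelMask:
    return LabelMask(
        patient_id=patient_id,
        slide_id=slide_id,
        grid=np.asarray(grid, dtype=np.int64),
        pixel_size_mm=pixel_size_mm,
        label_map=dict(DEFAULT_LABEL_MAP),
    )


def tumor_mask_from_bool(occ, pixel_size_mm: float = 0.02, **kw) -> LabelMask:
    """Boolean fragment raster -> LabelMask (True = tumor, False = other)."""
    occ = np.asarray(occ, dtype=bool)
    grid = np.where(occ, DEFAULT_LABEL_MAP["tumor"], DEFAULT_LABEL_MAP["other"])
    return make_mask(grid, pixel_size_mm=pixel_size_mm, **kw)


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-patient cohort under default study conditions, with truth."""
    cfg = GeneratorConfig(n_patients=8, seed=11)
    cohort, truths = generate_cohort(cfg)
    return cfg, cohort, truths


@pytest.fixture(scope="session")
def measured_small_cohort(small_cohort, pipeline_cfg):
    """(summaries, fragments_by_patient, truths) for the small cohort."""
    from fragmetrics.pipeline import measure_patient

    _, cohort, truths = small_cohort
    summaries, per_patient = [], {}
    for record in cohort.patients:
        fragments, summary = measure_patient(record, pipeline_cfg)
        summaries.append(summary)
        per_patient[record.patient_id] = fragments
    return summaries, per_patient, truths
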