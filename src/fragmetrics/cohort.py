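"""Cohort-level aggregation and TRG group statistics.

Rolls per-slide fragment measurements up to the per-patient summary row
(pattern, widest fragment/bulk, shallowest lumen distance, central-slide
area, volume), builds the per-TRG summary table with medians and ranges,
exports cumulative distributions of widths and depths, and runs the group
comparisons: normality is gated by Shapiro-Wilk on each group (alpha =
0.05); both groups normal -> unpaired two-sided t-test, otherwise
two-sided Mann-Whitney U (exact for min(n) <= 8 without ties, average-rank
normal approximation otherwise).  p <= 0.05 is flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import Fragment, PatternCall

__all__ = [
    "PatientSummary",
    "GroupComparison",
    "summarize_patient",
    "fraction_below",
    "empirical_cdf",
    "compare_groups",
    "build_table2",
]

ALPHA = 0.05  # significance threshold and Shapiro-Wilk gate
EXACT_MWU_MAX_N = 8  # exact Mann-Whitney null up to this group size


@dataclass
class PatientSummary:
    """The per-patient row of the cohort summary table."""

    patient_id: str
    trg: int
    pattern: str
    n_clusters: int
    max_width_mm: float
    min_depth_mm: float
    central_slide_area_mm2: float
    volume_mm3: float


@dataclass
class GroupComparison:
    """Result of one TRG 2 vs TRG 3 comparison."""

    variable: str
    median_a: float
    range_a: tuple[float, float]
    median_b: float
    range_b: tuple[float, float]
    n_a: int
    n_b: int
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool


def summarize_patient(
    patient_id: str,
    trg: int,
    fragments: Sequence[Fragment],
    slide_areas_mm2: Mapping[str, float],
    pattern: PatternCall,
    slide_spacing_mm: float,
) -> PatientSummary:
    """Aggregate a patient's fragments and slide areas into one row.

    * ``max_width_mm``: widest fragment (fragmentation) / bulk (shrinkage);
    * ``min_depth_mm``: shortest lumen distance over all fragments/slides;
    * ``central_slide_area_mm2``: the largest single-slide tumor area;
    * ``volume_mm3``: sum over slides of tumor area x slide spacing.
    """
    frags = list(fragments)
    if not frags:
        raise ValueError("no residual tumor; outside cohort definition")
    depths = [f.min_lumen_dist_mm for f in frags if np.isfinite(f.min_lumen_dist_mm)]
    return PatientSummary(
        patient_id=patient_id,
        trg=trg,
        pattern=pattern.pattern,
        n_clusters=pattern.n_clusters,
        max_width_mm=max(f.width_mm for f in frags),
        min_depth_mm=min(depths) if depths else float("nan"),
        central_slide_area_mm2=max(slide_areas_mm2.values()),
        volume_mm3=float(sum(slide_areas_mm2.values())) * slide_spacing_mm,
    )


def fraction_below(
    values: Sequence[float], threshold: float, strict: bool = True
) -> float:
    """Fraction of values below (``strict``) or at-most the threshold."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    return float((v < threshold).mean() if strict else (v <= threshold).mean())


def empirical_cdf(values: Sequence[float]) -> pd.DataFrame:
    """Right-continuous ECDF as a two-column table (x, cdf).

    Evaluated at the sorted unique data points; F(max) = 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    res = stats.ecdf(v)
    return pd.DataFrame({"x": res.cdf.quantiles, "cdf": res.cdf.probabilities})


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variable: str = "",
    alpha: float = ALPHA,
    force_test: Literal["t_test", "mann_whitney"] | None = None,
) -> GroupComparison:
    """Compare two groups with the Shapiro-Wilk-gated test choice.

    Both groups pass Shapiro-Wilk at ``alpha`` -> pooled-variance unpaired
    two-sided t-test; otherwise two-sided Mann-Whitney U.  ``force_test``
    bypasses the gate (used for worked examples and sensitivity checks).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")

    if force_test is None:
        normal_a = stats.shapiro(a).pvalue > alpha
        normal_b = stats.shapiro(b).pvalue > alpha
        test_used = "t_test" if (normal_a and normal_b) else "mann_whitney"
    else:
        test_used = force_test

    if test_used == "t_test":
        res = stats.ttest_ind(a, b, equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test_used == "mann_whitney":
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(a), len(b)) <= EXACT_MWU_MAX_N and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test_used!r}")

    return GroupComparison(
        variable=variable,
        median_a=float(np.median(a)),
        range_a=(float(a.min()), float(a.max())),
        median_b=float(np.median(b)),
        range_b=(float(b.min()), float(b.max())),
        n_a=len(a),
        n_b=len(b),
        test_used=test_used,
        statistic=statistic,
        p_value=p,
        significant=bool(p <= alpha),
    )


#: measure name -> (attribute, subset of patients it applies to)
_TABLE2_ROWS: tuple[tuple[str, str, str | None], ...] = (
    ("fragmentation_max_width_mm", "max_width_mm", "fragmentation"),
    ("shrinkage_max_width_mm", "max_width_mm", "shrinkage"),
    ("min_lumen_distance_mm", "min_depth_mm", None),
    ("central_slide_area_mm2", "central_slide_area_mm2", None),
    ("volume_mm3", "volume_mm3", None),
)


def build_table2(
    summaries: Iterable[PatientSummary], alpha: float = ALPHA
) -> dict:
    """Per-TRG summary: counts, median (range) of each measure, p-values.

    The fragmentation-width row uses fragmentation patients only and the
    shrinkage-width row shrinkage patients only; the depth, area and
    volume rows use all patients.  A subgroup that is empty (or too small
    for the tests, n < 3) yields missing markers and no p-value.
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        {
            "trg": [s.trg for s in rows],
            "pattern": [s.pattern for s in rows],
            "max_width_mm": [s.max_width_mm for s in rows],
            "min_depth_mm": [s.min_depth_mm for s in rows],
            "central_slide_area_mm2": [s.central_slide_area_mm2 for s in rows],
            "volume_mm3": [s.volume_mm3 for s in rows],
        }
    )
    out: dict = {"groups": sorted(df["trg"].unique().tolist()), "counts": {}, "measures": {}}
    for trg, sub in df.groupby("trg"):
        out["counts"][str(trg)] = {
            "n": int(len(sub)),
            "fragmentation": int((sub["pattern"] == "fragmentation").sum()),
            "shrinkage": int((sub["pattern"] == "shrinkage").sum()),
        }
    for name, attr, subset in _TABLE2_ROWS:
        sel = df if subset is None else df[df["pattern"] == subset]
        entry: dict = {}
        groups = {}
        for trg in out["groups"]:
            vals = sel.loc[sel["trg"] == trg, attr].dropna().to_numpy()
            if len(vals) == 0:
                groups[str(trg)] = None
            else:
                groups[str(trg)] = {
                    "n": int(len(vals)),
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
        entry["by_trg"] = groups
        gvals = [
            sel.loc[sel["trg"] == trg, attr].dropna().to_numpy()
            for trg in out["groups"]
        ]
        if len(gvals) == 2 and all(len(g) >= 3 for g in gvals):
            cmp_res = compare_groups(gvals[0], gvals[1], variable=name, alpha=alpha)
            entry["test_used"] = cmp_res.test_used
            entry["statistic"] = cmp_res.statistic
            entry["p_value"] = cmp_res.p_value
            entry["significant"] = cmp_res.significant
        else:
            entry["test_used"] = None
            entry["p_value"] = None
        out["measures"][name] = entry
    return out
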