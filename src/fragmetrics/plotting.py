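"""Cumulative-distribution plots of cohort morphometry.

One figure with two panels: the ECDF of the per-patient maximum fragment
width (what an imaging technique's resolution must reach) and of the
per-patient minimum depth below the luminal surface (what its imaging
depth must reach), each split by regression pattern.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cohort import PatientSummary, empirical_cdf

__all__ = ["plot_cohort_cdfs"]

_COLORS = {"all": "black", "fragmentation": "tab:blue", "shrinkage": "tab:red"}


def _panel(ax, summaries: Sequence[PatientSummary], attr: str, xlabel: str) -> None:
    groups = {"all": list(summaries)}
    for p in ("fragmentation", "shrinkage"):
        groups[p] = [s for s in summaries if s.pattern == p]
    for name, subset in groups.items():
        if not subset:
            continue
        tab = empirical_cdf([getattr(s, attr) for s in subset])
        ax.step(
            tab["x"],
            tab["cdf"],
            where="post",
            color=_COLORS[name],
            label=f"{name} (n={len(subset)})",
        )
    ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction of patients")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)


def plot_cohort_cdfs(
    summaries: Sequence[PatientSummary], path: str | Path
) -> Path:
    """Write the two-panel ECDF figure (widths, depths) to ``path``."""
    fig, (ax_w, ax_d) = plt.subplots(1, 2, figsize=(9, 3.6), constrained_layout=True)
    _panel(ax_w, summaries, "max_width_mm", "max fragment width (mm)")
    _panel(ax_d, summaries, "min_depth_mm", "min depth below surface (mm)")
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
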