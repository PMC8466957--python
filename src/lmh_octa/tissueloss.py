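"""Longitudinal foveal tissue-loss quantification and TL/ST classification.

Tissue loss (TL) for one B-scan section is the algebraic change of the
manually contoured retinal gap area between two visits.  We orient the
difference as follow-up minus baseline so that loss of tissue (an enlarged
gap) is positive, which matches the sign of every reported TL value;
shrinkage therefore comes out negative and is flagged.  A patient's
quantitative TL is the sum of the three most involved sections (the three
largest per-section changes), the TL/ST split uses an inclusive cutoff of
0.02 mm^2, and the speed of loss is the top-3 sum divided by the
between-visit interval in years (exact day difference / 365.25).
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import stats as _stats

__all__ = [
    "BScanGap",
    "TissueLossResult",
    "section_tissue_loss",
    "quantify_patient_tl",
    "grader_agreement",
    "interval_years",
    "patient_tl_table",
    "TL_CUTOFF_MM2",
]

#: enrollment cutoff: at least this much summed loss defines the TL group
TL_CUTOFF_MM2 = 0.02
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class BScanGap:
    """Contoured retinal gap for one B-scan section at one visit."""

    patient_id: str
    section_id: int
    visit: str  # "baseline" | "followup"
    gap_area_mm2: float | None = None
    gap_polygon: np.ndarray | None = None
    visit_date: _dt.date | None = None

    def __post_init__(self):
        if self.visit not in ("baseline", "followup"):
            raise ValueError("visit must be 'baseline' or 'followup'")
        if self.gap_area_mm2 is None and self.gap_polygon is None:
            raise ValueError("either gap_area_mm2 or gap_polygon is required")
        if self.gap_area_mm2 is None:
            object.__setattr__(
                self, "gap_area_mm2", _metrics.polygon_area(self.gap_polygon)
            )
        if self.gap_area_mm2 < 0:
            raise ValueError("gap area must be nonnegative")


@dataclass(frozen=True)
class TissueLossResult:
    patient_id: str
    per_section_tl_mm2: dict[int, float]
    top3_sum_mm2: float
    group: str  # "TL" | "ST"
    interval_years: float
    speed_mm2_per_year: float
    cutoff_mm2: float = TL_CUTOFF_MM2


def interval_years(baseline_date: _dt.date, followup_date: _dt.date) -> float:
    """Between-visit interval as exact day difference / 365.25."""
    return (followup_date - baseline_date).days / DAYS_PER_YEAR


def section_tissue_loss(baseline: BScanGap, followup: BScanGap) -> float:
    """Per-section TL in mm^2: follow-up gap area minus baseline gap area.

    Positive means tissue was lost (the gap enlarged).  Negative values are
    retained (the subtraction is algebraic) but flagged with a warning.
    """
    if baseline.patient_id != followup.patient_id:
        raise ValueError("gaps belong to different patients")
    if baseline.section_id != followup.section_id:
        raise ValueError("gaps belong to different sections")
    if baseline.visit != "baseline" or followup.visit != "followup":
        raise ValueError("pass (baseline, followup) in that order")
    tl = followup.gap_area_mm2 - baseline.gap_area_mm2
    if tl < 0:
        warnings.warn(
            f"section {baseline.section_id} of patient {baseline.patient_id}: "
            f"gap shrank by {-tl:.4f} mm^2",
            stacklevel=2,
        )
    return tl


def quantify_patient_tl(
    per_section: dict[int, float] | list[tuple[int, float]],
    interval_years: float,
    patient_id: str = "",
    cutoff_mm2: float = TL_CUTOFF_MM2,
) -> TissueLossResult:
    """Summarize one patient's section TLs.

    The quantitative TL is the sum of the 3 largest per-section values
    (all of them when fewer than 3 sections exist); ties at the third place
    are broken by ascending section id.  Group is TL iff the sum reaches
    the cutoff (inclusive); speed is the sum over the follow-up interval.
    """
    if interval_years <= 0:
        raise ValueError("interval must be positive")
    items = dict(per_section)
    if not items:
        raise ValueError("need at least one section")
    ordered = sorted(items.items(), key=lambda kv: (-kv[1], kv[0]))
    top3 = float(sum(v for _, v in ordered[:3]))
    group = "TL" if top3 >= cutoff_mm2 else "ST"
    return TissueLossResult(
        patient_id=patient_id,
        per_section_tl_mm2=items,
        top3_sum_mm2=top3,
        group=group,
        interval_years=float(interval_years),
        speed_mm2_per_year=top3 / interval_years,
        cutoff_mm2=cutoff_mm2,
    )


def grader_agreement(areas_g1, areas_g2) -> tuple[_stats.StatReport, np.ndarray]:
    """Inter-grader agreement on TL areas.

    ICC(2,1) (two-way random, single measure, absolute agreement) plus the
    consensus areas (per-item mean of the two graders) used downstream.
    """
    g1 = np.asarray(areas_g1, dtype=float)
    g2 = np.asarray(areas_g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("graders must supply equal-length 1-d lists")
    if g1.size < 2:
        raise ValueError("agreement needs at least 2 rated items")
    report = _stats.icc_two_way(np.column_stack([g1, g2]))
    return report, (g1 + g2) / 2.0


def patient_tl_table(sections: pd.DataFrame, followup_years: pd.Series | dict) -> pd.DataFrame:
    """Per-patient TL summary from a long-format section table.

    ``sections`` columns: patient_id, section_id, visit, gap_area_mm2.
    ``followup_years`` maps patient_id -> interval in years.
    """
    need = {"patient_id", "section_id", "visit", "gap_area_mm2"}
    if not need <= set(sections.columns):
        raise ValueError(f"sections table needs columns {sorted(need)}")
    fu = dict(followup_years)
    rows = []
    for pid, g in sections.groupby("patient_id", sort=True):
        wide = g.pivot_table(
            index="section_id", columns="visit", values="gap_area_mm2", aggfunc="first"
        )
        if not {"baseline", "followup"} <= set(wide.columns) or wide.isna().any().any():
            raise ValueError(f"patient {pid}: unmatched baseline/followup sections")
        per_section = (wide["followup"] - wide["baseline"]).to_dict()
        res = quantify_patient_tl(per_section, fu[pid], patient_id=str(pid))
        rows.append(
            {
                "patient_id": str(pid),
                "n_sections": len(per_section),
                "top3_sum_mm2": res.top3_sum_mm2,
                "group": res.group,
                "interval_years": res.interval_years,
                "speed_mm2_per_year": res.speed_mm2_per_year,
            }
        )
    return pd.DataFrame(rows)
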