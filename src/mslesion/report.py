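"""Per-study report rows and the longitudinal series table.

The report is the file-based analogue of a radiology "live report": one row
per study with lesion counts per McDonald location, per condensed key area,
change counts (new / progressing), enhancing-lesion count and total lesion
volume. A series table stacks the rows for baseline + follow-ups and adds a
running total of new lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .change import ChangeResult
from .enhance import EnhanceResult
from .locate import MCDONALD_REGIONS

__all__ = ["StudyReportRow", "ReportConsistencyError", "build_report", "build_series_report"]

#: columns required of a per-component location table
LOCATION_COLUMNS = ("component_id", "voxel_count", "volume_ml", "region")


class ReportConsistencyError(ValueError):
    """Report inputs disagree (e.g. more changed lesions than lesions)."""


@dataclass
class StudyReportRow:
    """One timepoint's report record.

    ``region_counts`` has one entry per McDonald location and sums to
    ``total_lesions`` (each lesion counted once, under the localization
    precedence); baseline rows have ``n_new == total_lesions``.
    """

    study_id: str
    timepoint: int
    region_counts: dict[str, int]
    total_lesions: int
    n_new: int
    n_progressing: int
    n_enhancing: int
    total_volume_ml: float
    key_area_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {"study_id": self.study_id, "timepoint": self.timepoint}
        for r in MCDONALD_REGIONS:
            d[f"n_{r}"] = self.region_counts.get(r, 0)
        d["total_lesions"] = self.total_lesions
        d["n_new"] = self.n_new
        d["n_progressing"] = self.n_progressing
        d["n_enhancing"] = self.n_enhancing
        d["total_volume_ml"] = self.total_volume_ml
        for name in sorted(self.key_area_counts):
            d[f"area_{name.replace(' ', '_')}"] = self.key_area_counts[name]
        return d


def build_report(
    change: ChangeResult | None,
    locations: pd.DataFrame,
    enhance: EnhanceResult | None,
    study_id: str = "study",
    timepoint: int = 0,
) -> StudyReportRow:
    """Assemble one study's report row.

    ``locations`` is the per-component table for this study's lesion map:
    columns ``component_id, voxel_count, volume_ml, region`` and optionally
    ``key_area``. A baseline study passes ``change=None`` and every lesion
    counts as new (all are first seen).
    """
    missing = [c for c in LOCATION_COLUMNS if c not in locations.columns]
    if missing and len(locations):
        raise ReportConsistencyError(f"location table lacks columns {missing}")
    total = int(len(locations))
    region_counts = {r: 0 for r in MCDONALD_REGIONS}
    if total:
        if locations["component_id"].duplicated().any():
            raise ReportConsistencyError("duplicate component ids in location table")
        for r, n in locations["region"].value_counts().items():
            if r not in region_counts:
                raise ReportConsistencyError(f"unknown region label {r!r}")
            region_counts[r] = int(n)
    if change is None:
        n_new, n_progressing = total, 0
    else:
        n_new, n_progressing = change.n_new, change.n_progressing
        if n_new + n_progressing > total:
            raise ReportConsistencyError(
                f"{n_new} new + {n_progressing} progressing exceeds {total} lesions; "
                "change and location inputs are inconsistent"
            )
    key_area_counts: dict[str, int] = {}
    if "key_area" in locations.columns and total:
        for a, n in locations["key_area"].value_counts().items():
            key_area_counts[str(a)] = int(n)
    return StudyReportRow(
        study_id=study_id,
        timepoint=timepoint,
        region_counts=region_counts,
        total_lesions=total,
        n_new=n_new,
        n_progressing=n_progressing,
        n_enhancing=0 if enhance is None else len(enhance.components),
        total_volume_ml=float(locations["volume_ml"].sum()) if total else 0.0,
        key_area_counts=key_area_counts,
    )


def build_series_report(rows: list[StudyReportRow], sort: bool = False) -> pd.DataFrame:
    """Stack report rows into one longitudinal table.

    One row per timepoint in stable column order, with a
    ``cumulative_new`` running sum. Duplicate timepoints are an error;
    out-of-order rows are an error unless ``sort=True``.
    """
    if not rows:
        raise ValueError("no report rows")
    tps = [r.timepoint for r in rows]
    if len(set(tps)) != len(tps):
        raise ValueError(f"duplicate timepoints in series: {tps}")
    if sort:
        rows = sorted(rows, key=lambda r: r.timepoint)
    elif tps != sorted(tps):
        raise ValueError(f"timepoints out of order: {tps} (pass sort=True to sort)")
    df = pd.DataFrame([r.to_dict() for r in rows])
    df = df.fillna(0)
    for c in df.columns:
        if c.startswith("area_"):
            df[c] = df[c].astype(int)
    df["cumulative_new"] = df["n_new"].cumsum()
    return df
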