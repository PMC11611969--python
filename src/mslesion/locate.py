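"""Lesion localization: McDonald-criteria regions and condensed-atlas areas.

A lesion's location drives both MS diagnosis (dissemination in space requires
periventricular, juxtacortical/cortical and infratentorial involvement) and
the per-study report. Anatomical inputs — ventricle, cortical-ribbon and
infratentorial masks plus a subregion label map — are produced upstream by
anatomical segmentation and arrive here as masks on the common grid. The
subregion atlas (95 Hammers-style labels) is condensed into 23 named key
areas through a shipped, editable two-column table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_volumes import BinaryMask, LabelMap, VolumeGrid, check_same_grid

__all__ = [
    "RegionSet",
    "AtlasCondensation",
    "LocationParams",
    "MappingCoverageError",
    "MCDONALD_REGIONS",
    "load_condensation_table",
    "default_condensation",
    "assign_mcdonald_region",
    "locate_components",
    "condense_atlas",
    "locate_component_atlas",
]

#: McDonald-criteria location labels, in default precedence order.
MCDONALD_REGIONS = ("infratentorial", "periventricular", "cortical", "juxtacortical", "other")


class MappingCoverageError(KeyError):
    """An atlas label has no entry in the condensation table."""


@dataclass
class RegionSet:
    """Anatomical region masks and atlas on one voxel grid.

    The juxtacortical band is derived on demand: voxels within
    ``juxtacortical_distance_mm`` of the cortical ribbon, excluding the
    ribbon itself.
    """

    ventricles: BinaryMask
    cortical_ribbon: BinaryMask
    infratentorial: BinaryMask
    atlas: LabelMap | None = None

    def __post_init__(self) -> None:
        check_same_grid(self.ventricles, self.cortical_ribbon)
        check_same_grid(self.ventricles, self.infratentorial)
        if self.atlas is not None:
            check_same_grid(self.ventricles, self.atlas)
        if np.any(self.ventricles.as_bool() & self.cortical_ribbon.as_bool()):
            raise ValueError("ventricle and cortical-ribbon masks overlap")

    def juxtacortical_band(self, distance_mm: float) -> BinaryMask:
        """Voxels within ``distance_mm`` of the cortical ribbon, ribbon excluded."""
        ribbon = self.cortical_ribbon.as_bool()
        dist = ndimage.distance_transform_edt(
            ~ribbon, sampling=self.cortical_ribbon.spacing
        )
        band = (dist <= distance_mm) & ~ribbon
        g = self.cortical_ribbon.grid
        return BinaryMask(VolumeGrid(band.astype(np.uint8), g.spacing, g.origin))


@dataclass
class LocationParams:
    """Tunable definitions behind the four McDonald location classes.

    periventricular_distance_mm : float
        0 (default) means the lesion must share voxels with the ventricle
        mask; positive values admit lesions within that Euclidean distance.
    juxtacortical_distance_mm : float
        Width of the band around the cortical ribbon (default 1.0, i.e. one
        voxel at 1 mm isotropic resolution).
    precedence : tuple of str
        Total order over the five labels; the first passing test wins.
    """

    periventricular_distance_mm: float = 0.0
    juxtacortical_distance_mm: float = 1.0
    precedence: tuple[str, ...] = ("infratentorial", "periventricular", "cortical", "juxtacortical", "other")

    def __post_init__(self) -> None:
        if self.periventricular_distance_mm < 0 or self.juxtacortical_distance_mm < 0:
            raise ValueError("distances must be >= 0")
        if sorted(self.precedence) != sorted(MCDONALD_REGIONS):
            raise ValueError(
                f"precedence must be a total order over {MCDONALD_REGIONS}, got {self.precedence}"
            )


@dataclass
class AtlasCondensation:
    """Mapping from atlas subregion labels to condensed key-area labels.

    ``mapping`` sends every subregion label to a key-area id (1-based);
    ``key_area_names`` gives the area name for each id, in id order.
    """

    mapping: dict[int, int]
    key_area_names: list[str]

    def __post_init__(self) -> None:
        used = set(self.mapping.values())
        n = len(self.key_area_names)
        if used - set(range(1, n + 1)):
            raise ValueError("mapping targets a key-area id with no name")
        if set(range(1, n + 1)) - used:
            raise ValueError("every key area must have at least one source label")

    @property
    def n_key_areas(self) -> int:
        return len(self.key_area_names)

    def area_name(self, area_id: int) -> str:
        if area_id == 0:
            return "background"
        return self.key_area_names[area_id - 1]


def load_condensation_table(path) -> AtlasCondensation:
    """Load a two-column (subregion_label, key_area_name) CSV condensation table.

    Key-area ids are assigned 1, 2, ... in order of first appearance of each
    area name in the file.
    """
    mapping: dict[int, int] = {}
    names: list[str] = []
    ids: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[0].strip().lower() != "subregion_label":
            raise ValueError(f"unexpected condensation table header: {header}")
        for row in reader:
            if not row or not row[0].strip():
                continue
            label = int(row[0])
            name = row[1].strip()
            if name not in ids:
                names.append(name)
                ids[name] = len(names)
            if label in mapping:
                raise ValueError(f"duplicate subregion label {label} in table")
            mapping[label] = ids[name]
    return AtlasCondensation(mapping, names)


def default_condensation() -> AtlasCondensation:
    """The shipped 95-subregion -> 23-key-area table."""
    ref = resources.files("mslesion.data") / "hammers_condensation_23.csv"
    with resources.as_file(ref) as path:
        return load_condensation_table(path)


def condense_atlas(atlas: LabelMap, condensation: AtlasCondensation) -> LabelMap:
    """Relabel an atlas voxelwise through the condensation mapping.

    Background (0) stays 0. Raises :class:`MappingCoverageError` naming the
    first atlas label absent from the table.
    """
    labels = atlas.labels()
    missing = [int(l) for l in labels if int(l) not in condensation.mapping]
    if missing:
        raise MappingCoverageError(
            f"atlas label {missing[0]} has no condensation-table entry "
            f"({len(missing)} unmapped labels total)"
        )
    max_label = int(labels.max()) if labels.size else 0
    lut = np.zeros(max_label + 1, dtype=np.int32)
    for src, dst in condensation.mapping.items():
        if src <= max_label:
            lut[src] = dst
    g = atlas.grid
    return LabelMap(VolumeGrid(lut[atlas.data], g.spacing, g.origin))


def assign_mcdonald_region(
    component_mask: BinaryMask,
    regions: RegionSet,
    params: LocationParams | None = None,
) -> str:
    """Assign one McDonald location label to a lesion component.

    The five class tests run in precedence order and the first pass wins:

    - infratentorial: any voxel overlaps the infratentorial mask;
    - periventricular: overlaps the ventricle mask, or lies within
      ``periventricular_distance_mm`` of it when that distance is positive;
    - cortical: a strict majority of voxels lies inside the cortical ribbon;
    - juxtacortical: any voxel overlaps the juxtacortical band;
    - other: none of the above ("white matter, unspecified").
    """
    if params is None:
        params = LocationParams()
    check_same_grid(component_mask, regions.ventricles)
    comp = component_mask.as_bool()
    n = int(comp.sum())
    if n == 0:
        raise ValueError("cannot localize an empty component")

    def _test(label: str) -> bool:
        if label == "infratentorial":
            return bool(np.any(comp & regions.infratentorial.as_bool()))
        if label == "periventricular":
            vent = regions.ventricles.as_bool()
            if np.any(comp & vent):
                return True
            d = params.periventricular_distance_mm
            if d > 0:
                dist = ndimage.distance_transform_edt(
                    ~vent, sampling=regions.ventricles.spacing
                )
                return bool(np.any(dist[comp] <= d))
            return False
        if label == "cortical":
            inside = int(np.sum(comp & regions.cortical_ribbon.as_bool()))
            return inside * 2 > n
        if label == "juxtacortical":
            band = regions.juxtacortical_band(params.juxtacortical_distance_mm)
            return bool(np.any(comp & band.as_bool()))
        return True  # "other" always passes

    for label in params.precedence:
        if _test(label):
            return label
    return "other"


def locate_components(
    labels: "LabelMap",
    regions: RegionSet,
    params: LocationParams | None = None,
    condensation: AtlasCondensation | None = None,
):
    """Localize every component of a label map at once.

    Returns a pandas DataFrame with one row per component: ``component_id,
    voxel_count, volume_ml, region`` plus ``key_area`` and
    ``key_area_fraction`` when the region set carries an atlas and a
    condensation table is given. Equivalent to calling
    :func:`assign_mcdonald_region` / :func:`locate_component_atlas` per
    component; region tests are precomputed once for speed.
    """
    import pandas as pd

    if params is None:
        params = LocationParams()
    check_same_grid(labels, regions.ventricles)
    condensed = None
    if condensation is not None and regions.atlas is not None:
        condensed = condense_atlas(regions.atlas, condensation)
    band = regions.juxtacortical_band(params.juxtacortical_distance_mm)
    vent_dist = None
    if params.periventricular_distance_mm > 0:
        vent_dist = ndimage.distance_transform_edt(
            ~regions.ventricles.as_bool(), sampling=regions.ventricles.spacing
        )
    g = labels.grid
    rows = []
    for lab in labels.labels():
        comp = labels.data == lab
        n = int(comp.sum())
        infra = bool(np.any(comp & regions.infratentorial.as_bool()))
        if np.any(comp & regions.ventricles.as_bool()):
            peri = True
        elif vent_dist is not None:
            peri = bool(np.any(vent_dist[comp] <= params.periventricular_distance_mm))
        else:
            peri = False
        cort = int(np.sum(comp & regions.cortical_ribbon.as_bool())) * 2 > n
        juxta = bool(np.any(comp & band.as_bool()))
        passes = {
            "infratentorial": infra,
            "periventricular": peri,
            "cortical": cort,
            "juxtacortical": juxta,
            "other": True,
        }
        region = next(l for l in params.precedence if passes[l])
        row = {
            "component_id": int(lab),
            "voxel_count": n,
            "volume_ml": n * g.voxel_volume_ml,
            "region": region,
        }
        if condensed is not None:
            comp_mask = BinaryMask(VolumeGrid(comp.astype(np.uint8), g.spacing, g.origin))
            area, frac = locate_component_atlas(comp_mask, condensed)
            row["key_area"] = condensation.area_name(area)
            row["key_area_fraction"] = frac
        rows.append(row)
    cols = ["component_id", "voxel_count", "volume_ml", "region"]
    if condensed is not None:
        cols += ["key_area", "key_area_fraction"]
    return pd.DataFrame(rows, columns=cols)


def locate_component_atlas(
    component_mask: BinaryMask, condensed: LabelMap
) -> tuple[int, float]:
    """Condensed key area with maximal voxel overlap, and the fraction overlapped.

    Ties break toward the smaller area id. A component entirely outside the
    labeled voxels returns (0, 0.0).
    """
    check_same_grid(component_mask, condensed)
    comp = component_mask.as_bool()
    n = int(comp.sum())
    if n == 0:
        raise ValueError("cannot localize an empty component")
    vals = condensed.data[comp]
    counts = np.bincount(vals[vals > 0])
    if counts.size == 0 or counts.max() == 0:
        return 0, 0.0
    best = int(np.argmax(counts))  # argmax returns the first (smallest) maximal id
    return best, float(counts[best]) / n
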