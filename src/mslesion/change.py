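"""Longitudinal lesion-change classification.

Given a baseline and a follow-up binary lesion map on one grid, the
follow-up-only voxels (follow-up minus baseline) are split into connected
components. A standalone component — one with no voxel overlapping or
adjacent to the baseline lesion map — is a *new* lesion; a component
attached to an existing lesion is *progression* (enlargement). Follow-up
components fully contained in the baseline are *stable*. Lesion regression
(shrinkage) is deliberately not a class of its own: vanished voxels simply
do not appear in the subtraction.

One connectivity parameter (6, 18 or 26; default 26) governs both the
component labeling and the "attached" adjacency test, keeping the two
semantics coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import BinaryMask, LabelMap, VolumeGrid, check_same_grid

__all__ = [
    "LesionComponent",
    "ChangeResult",
    "connectivity_structure",
    "label_components",
    "components_from_labels",
    "subtract_maps",
    "classify_changes",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """The 3x3x3 binary adjacency structure for 6-, 18- or 26-connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    return ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])


@dataclass
class LesionComponent:
    """One connected lesion component.

    ``volume_ml`` is ``voxel_count`` times the voxel volume in ml; the
    centroid is in world mm; ``bbox`` is the (start, stop) voxel index range
    per axis. ``status`` is filled by change classification, ``location`` by
    localization and ``enhancing`` by contrast-enhancement detection.
    """

    id: int
    voxel_count: int
    volume_ml: float
    centroid_mm: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    status: str | None = None
    location: str | None = None
    enhancing: bool = False

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("a component has at least one voxel")


@dataclass
class ChangeResult:
    """Outcome of one baseline/follow-up comparison.

    Components are the follow-up lesions (``fu_labels``), so counts are
    per lesion: a grown lesion is one progressing lesion even when its
    added shell rasterizes into several disconnected pieces. Every voxel of
    ``added_mask`` belongs to exactly one new or progressing component; new
    components have zero overlap and zero adjacency with the baseline mask.
    New and progressing components report their *added* voxels (count,
    volume, centroid, bbox) — for a new lesion that is the whole lesion.
    """

    added_mask: BinaryMask
    fu_labels: LabelMap
    new: list[LesionComponent]
    progressing: list[LesionComponent]
    stable: list[LesionComponent]
    connectivity: int

    @property
    def n_new(self) -> int:
        return len(self.new)

    @property
    def n_progressing(self) -> int:
        return len(self.progressing)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Label the connected components of a binary mask.

    Labels 1..K partition the foreground; two voxels share a label iff they
    are connected under the chosen adjacency.
    """
    structure = connectivity_structure(connectivity)
    labels, _ = ndimage.label(mask.as_bool(), structure=structure)
    g = mask.grid
    return LabelMap(VolumeGrid(labels.astype(np.int32), g.spacing, g.origin))


def components_from_labels(labels: LabelMap, status: str | None = None) -> list[LesionComponent]:
    """Measure every labeled component (voxel count, volume, centroid, bbox)."""
    data = labels.data
    ids = labels.labels()
    if ids.size == 0:
        return []
    spacing = np.asarray(labels.spacing)
    origin = np.asarray(labels.origin)
    counts = ndimage.sum_labels(np.ones_like(data), data, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(data), data, index=ids)
    slices = ndimage.find_objects(data)
    vox_ml = labels.grid.voxel_volume_ml
    out = []
    for lab, n, com in zip(ids, counts, centroids):
        sl = slices[int(lab) - 1]
        out.append(
            LesionComponent(
                id=int(lab),
                voxel_count=int(n),
                volume_ml=float(n) * vox_ml,
                centroid_mm=tuple(origin + np.asarray(com) * spacing),
                bbox=tuple((s.start, s.stop) for s in sl),
                status=status,
            )
        )
    return out


def subtract_maps(baseline: BinaryMask, followup: BinaryMask) -> BinaryMask:
    """Voxels present at follow-up but not at baseline (regression ignored)."""
    check_same_grid(baseline, followup)
    added = followup.as_bool() & ~baseline.as_bool()
    g = followup.grid
    return BinaryMask(VolumeGrid(added.astype(np.uint8), g.spacing, g.origin))


def classify_changes(
    baseline: BinaryMask,
    followup: BinaryMask,
    connectivity: int = 26,
    min_new_voxels: int = 1,
) -> ChangeResult:
    """Classify follow-up lesion change into new / progressing / stable.

    Each follow-up component is classified by its subtraction voxels: with
    no added voxel it is *stable*; with added voxels it is *progressing*
    when it overlaps the baseline mask or any of its voxels lies within the
    connectivity neighborhood of a baseline lesion voxel ("attached"), and
    *new* (standalone) otherwise. New components smaller than
    ``min_new_voxels`` are dropped (default 1: no size policy).
    """
    check_same_grid(baseline, followup)
    structure = connectivity_structure(connectivity)
    bl = baseline.as_bool()
    added_mask = subtract_maps(baseline, followup)
    added = added_mask.as_bool()
    fu_labels = label_components(followup, connectivity)
    fu = fu_labels.data

    # a voxel is "attached" iff the dilated baseline covers it
    attached = ndimage.binary_dilation(bl, structure=structure)
    changed_ids = set(np.unique(fu[added & (fu > 0)]).tolist())
    attached_ids = set(np.unique(fu[attached & (fu > 0)]).tolist())

    # measure the added portion of each changed follow-up component,
    # keeping the follow-up component id
    g = followup.grid
    added_portion = np.where(np.isin(fu, sorted(changed_ids)) & added, fu, 0)
    added_by_id = {
        c.id: c
        for c in components_from_labels(
            LabelMap(VolumeGrid(added_portion.astype(np.int32), g.spacing, g.origin))
        )
    }

    new_comps: list[LesionComponent] = []
    prog_comps: list[LesionComponent] = []
    for cid in sorted(changed_ids):
        comp = added_by_id[cid]
        if cid in attached_ids:
            comp.status = "progressing"
            prog_comps.append(comp)
        else:
            comp.status = "new"
            if comp.voxel_count >= min_new_voxels:
                new_comps.append(comp)

    stable = [
        c
        for c in components_from_labels(fu_labels, status="stable")
        if c.id not in changed_ids
    ]
    return ChangeResult(
        added_mask=added_mask,
        fu_labels=fu_labels,
        new=new_comps,
        progressing=prog_comps,
        stable=stable,
        connectivity=connectivity,
    )
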