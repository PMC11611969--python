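"""Contrast-enhancing lesion detection on post-contrast T1.

Enhancing lesions mark active inflammation (typically younger than eight
weeks) and are detected with a deliberately simple rule-based chain:
median filter -> brain mask -> intensity threshold -> connected components
-> size filter -> vessel exclusion -> optional restriction to the FLAIR
lesion mask. Vessels are also gadolinium-bright, so any voxel whose raw
intensity strictly exceeds the vessel cutoff (default 600, on the
calibrated intensity scale) is marked as vessel, and any candidate
component sharing at least one voxel with the vessel mask is removed
entirely.

The detection threshold itself is ``median + k * MAD`` over the brain mask
(MAD unscaled), a robust rule that is insensitive to the enhancing voxels
it is meant to find; the value actually used is recorded in the result for
auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .change import components_from_labels, connectivity_structure, label_components, LesionComponent
from .io_volumes import BinaryMask, LabelMap, VolumeGrid, check_same_grid

__all__ = [
    "EnhanceParams",
    "EnhanceResult",
    "median_filter3d",
    "compute_brain_mask",
    "compute_enhance_threshold",
    "detect_vessels",
    "detect_ce_lesions",
]


@dataclass
class EnhanceParams:
    """Parameters of the enhancement-detection chain.

    median_kernel : odd ints per axis (default 3^3) for the smoothing filter.
    brain_mask_method : "otsu" (bimodal histogram split) or "fixed".
    fixed_mask_threshold : cutoff used when ``brain_mask_method="fixed"``.
    threshold_k : multiplier on the MAD in ``median + k * MAD`` (default 3.0);
        set ``threshold_rule="mean_sd"`` for ``mean + k * SD`` instead.
    vessel_threshold : absolute intensity above which a voxel is vessel
        (default 600, strict ">"); scanner/sequence dependent — review per
        intensity calibration.
    min_component_voxels : smallest surviving candidate (default 3, a
        noise-suppression policy; set 1 to disable).
    restrict_to_lesions : drop candidates with no FLAIR-lesion overlap when a
        lesion mask is supplied (default True).
    """

    median_kernel: tuple[int, int, int] = (3, 3, 3)
    brain_mask_method: str = "otsu"
    fixed_mask_threshold: float = 1.0
    threshold_k: float = 3.0
    threshold_rule: str = "median_mad"
    vessel_threshold: float = 600.0
    min_component_voxels: int = 3
    restrict_to_lesions: bool = True
    connectivity: int = 26

    def __post_init__(self) -> None:
        if any(k < 1 or k % 2 == 0 for k in self.median_kernel):
            raise ValueError(f"median kernel must be odd and >= 1 per axis, got {self.median_kernel}")
        if not np.isfinite(self.vessel_threshold):
            raise ValueError("vessel_threshold must be finite")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.brain_mask_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown brain_mask_method {self.brain_mask_method!r}")
        if self.threshold_rule not in ("median_mad", "mean_sd"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")


@dataclass
class EnhanceResult:
    """Detected enhancing-lesion candidates and the audit trail.

    ``candidate_mask`` and ``vessel_mask`` are disjoint by construction;
    ``n_excluded_by_vessel`` counts the candidate components removed for
    vessel overlap; ``threshold_used`` records the computed cutoff.
    """

    candidate_mask: BinaryMask
    components: list[LesionComponent]
    vessel_mask: BinaryMask
    threshold_used: float
    n_excluded_by_vessel: int
    n_excluded_by_size: int = 0
    n_excluded_by_lesion_mask: int = 0


def median_filter3d(v: VolumeGrid, kernel=(3, 3, 3)) -> VolumeGrid:
    """Median filter with per-axis odd kernel; borders use edge replication."""
    if any(k < 1 or k % 2 == 0 for k in kernel):
        raise ValueError(f"kernel must be odd and >= 1 per axis, got {kernel}")
    out = ndimage.median_filter(v.data, size=tuple(kernel), mode="nearest")
    return v.same_geometry(out)


def compute_brain_mask(v: VolumeGrid, method: str = "otsu", fixed_threshold: float = 1.0) -> BinaryMask:
    """Foreground (brain) mask by Otsu's bimodal split or a fixed cutoff.

    Otsu on a constant image has no histogram to split and raises.
    """
    data = v.data
    if method == "otsu":
        if np.all(data == data.flat[0]):
            raise ValueError("degenerate histogram: constant image has no Otsu threshold")
        thr = float(threshold_otsu(data))
    elif method == "fixed":
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown brain mask method {method!r}")
    return BinaryMask(v.same_geometry((data >= thr).astype(np.uint8)))


def compute_enhance_threshold(v: VolumeGrid, brain: BinaryMask, params: EnhanceParams) -> float:
    """Detection cutoff over the brain voxels: ``median + k * MAD`` (MAD
    unscaled) or ``mean + k * SD`` under the alternative rule."""
    check_same_grid(v, brain)
    vals = v.data[brain.as_bool()]
    if vals.size == 0:
        raise ValueError("empty brain mask: cannot compute enhancement threshold")
    if params.threshold_rule == "mean_sd":
        return float(vals.mean() + params.threshold_k * vals.std())
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med + params.threshold_k * mad


def detect_vessels(v: VolumeGrid, params: EnhanceParams | None = None) -> BinaryMask:
    """Voxels whose raw intensity strictly exceeds the vessel threshold."""
    if params is None:
        params = EnhanceParams()
    return BinaryMask(v.same_geometry((v.data > params.vessel_threshold).astype(np.uint8)))


def detect_ce_lesions(
    t1post: VolumeGrid,
    params: EnhanceParams | None = None,
    lesion_mask: BinaryMask | None = None,
) -> EnhanceResult:
    """Run the full enhancement-detection chain on a post-contrast T1.

    Stage order: median filter; brain mask; threshold (median + k*MAD within
    brain); supra-threshold voxels inside the brain; connected components;
    drop components below ``min_component_voxels``; drop components with any
    vessel overlap (vessels from the *unfiltered* volume, so thin vessels
    the filter would erode still veto); optionally drop components with no
    FLAIR-lesion overlap.
    """
    if params is None:
        params = EnhanceParams()
    if lesion_mask is not None:
        check_same_grid(t1post, lesion_mask)
    filtered = median_filter3d(t1post, params.median_kernel)
    brain = compute_brain_mask(filtered, params.brain_mask_method, params.fixed_mask_threshold)
    threshold = compute_enhance_threshold(filtered, brain, params)
    supra = (filtered.data > threshold) & brain.as_bool()
    g = t1post
    supra_mask = BinaryMask(g.same_geometry(supra.astype(np.uint8)))
    labels = label_components(supra_mask, params.connectivity)
    vessel_mask = detect_vessels(t1post, params)
    vessel = vessel_mask.as_bool()
    lesion = lesion_mask.as_bool() if lesion_mask is not None else None

    lab = labels.data
    keep = np.zeros(g.shape, dtype=bool)
    kept_ids: list[int] = []
    n_size = n_vessel = n_lesion = 0
    for comp in components_from_labels(labels):
        comp_vox = lab == comp.id
        if comp.voxel_count < params.min_component_voxels:
            n_size += 1
            continue
        if np.any(comp_vox & vessel):
            n_vessel += 1
            continue
        if params.restrict_to_lesions and lesion is not None and not np.any(comp_vox & lesion):
            n_lesion += 1
            continue
        keep |= comp_vox
        kept_ids.append(comp.id)

    candidate = BinaryMask(g.same_geometry(keep.astype(np.uint8)))
    cand_labels = label_components(candidate, params.connectivity)
    components = components_from_labels(cand_labels)
    for c in components:
        c.enhancing = True
    assert not np.any(candidate.as_bool() & vessel), "vessel-exclusion postcondition violated"
    return EnhanceResult(
        candidate_mask=candidate,
        components=components,
        vessel_mask=vessel_mask,
        threshold_used=threshold,
        n_excluded_by_vessel=n_vessel,
        n_excluded_by_size=n_size,
        n_excluded_by_lesion_mask=n_lesion,
    )
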