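"""Synthetic 3D brain phantoms with full ground truth.

The phantom stands in for the clinical inputs of a longitudinal MS study:
co-registered 3D FLAIR and pre/post-contrast T1 volumes, binary lesion maps
for a baseline plus follow-up series, anatomical region masks and a
subregion atlas. Anatomy is a nested-ellipsoid brain (outer brain, central
ventricles, outer cortical ribbon, inferior infratentorial slab); lesions
are ellipsoids that may appear de novo at a later timepoint or grow between
timepoints; vessels are bright tubes along a polyline; enhancing lesions
appear hyperintense on the post-contrast T1. Every structure's exact
rasterization is returned as ground truth, so each downstream stage can be
scored against construction.

All randomness (additive Gaussian noise, randomized lesion layouts) derives
from the spec seed; equal (spec, seed) gives bitwise-equal output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import BinaryMask, LabelMap, VolumeGrid
from .locate import RegionSet

__all__ = [
    "PhantomSpecError",
    "RoiGeometry",
    "LesionSpec",
    "VesselSpec",
    "PhantomSpec",
    "ChangeTruth",
    "rasterize_ellipsoid",
    "rasterize_tube",
    "generate_anatomy",
    "generate_lesion_series",
    "generate_postcontrast",
    "random_phantom_spec",
    "synthetic_full_atlas",
]


class PhantomSpecError(ValueError):
    """The phantom specification is inconsistent (lesion outside the brain,
    merging lesions, invalid geometry)."""


@dataclass
class RoiGeometry:
    """Placement of the nested anatomy, in voxel coordinates / mm.

    The brain is an ellipsoid; the ventricles a smaller central ellipsoid;
    the cortical ribbon the outer shell of the brain within
    ``ribbon_thickness_mm`` of the brain surface; the infratentorial
    compartment the brain voxels with axis-2 index below
    ``infratentorial_z_max`` (axis 2 is inferior -> superior).
    """

    brain_center: tuple[float, float, float] = (32.0, 32.0, 34.0)
    brain_radii_mm: tuple[float, float, float] = (28.0, 28.0, 27.0)
    ventricle_center: tuple[float, float, float] = (32.0, 32.0, 38.0)
    ventricle_radii_mm: tuple[float, float, float] = (9.0, 6.0, 6.0)
    ribbon_thickness_mm: float = 3.0
    infratentorial_z_max: int = 16


@dataclass
class LesionSpec:
    """One ellipsoidal lesion across the longitudinal series.

    ``appears_at`` is the timepoint index at which the lesion first exists;
    ``growth_per_timepoint_mm`` is added to every radius at each timepoint
    after appearance. Enhancing lesions additionally light up on the
    post-contrast T1 at ``enhancement_intensity``.
    """

    center: tuple[float, float, float]
    radii_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    flair_intensity: float = 80.0
    appears_at: int = 0
    growth_per_timepoint_mm: float = 0.0
    enhancing: bool = False
    enhancement_intensity: float = 500.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise PhantomSpecError(f"lesion radii must be > 0, got {self.radii_mm}")
        if self.appears_at < 0:
            raise PhantomSpecError("appears_at must be >= 0")

    def radii_at(self, timepoint: int) -> tuple[float, float, float]:
        """Radii at a timepoint (undefined before appearance)."""
        dt = timepoint - self.appears_at
        g = self.growth_per_timepoint_mm * max(dt, 0)
        return tuple(r + g for r in self.radii_mm)


@dataclass
class VesselSpec:
    """A bright tubular vessel along a voxel-coordinate polyline.

    Default intensity 650 sits above the 600 vessel-identification cutoff so
    the exclusion rule fires on the phantom.
    """

    polyline: list[tuple[float, float, float]]
    radius_mm: float = 1.5
    intensity: float = 650.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomSpecError("vessel radius must be > 0")
        if len(self.polyline) < 2:
            raise PhantomSpecError("vessel polyline needs at least 2 points")


@dataclass
class PhantomSpec:
    """Full phantom description; with a fixed seed, output is bitwise reproducible.

    Intensity calibration (all configurable): FLAIR background tissue 100
    with lesions ``flair_intensity`` above it; T1 brain tissue 300 with
    darker ventricles; post-contrast T1 brain tissue 300, enhancing lesions
    500, vessels 650 — an arbitrary scale chosen so that the absolute vessel
    cutoff of 600 is meaningful.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    tissue_noise_sd: float = 2.0
    flair_background: float = 100.0
    flair_csf: float = 40.0
    t1_background: float = 300.0
    t1_csf: float = 150.0
    t1post_background: float = 300.0
    lesions: list[LesionSpec] = field(default_factory=list)
    vessels: list[VesselSpec] = field(default_factory=list)
    roi_geometry: RoiGeometry = field(default_factory=RoiGeometry)

    def __post_init__(self) -> None:
        if self.tissue_noise_sd < 0:
            raise PhantomSpecError("noise sd must be >= 0")
        if any(n <= 0 for n in self.shape):
            raise PhantomSpecError("shape must be positive")
        brain = rasterize_ellipsoid(
            self.shape,
            self.spacing,
            self.roi_geometry.brain_center,
            self.roi_geometry.brain_radii_mm,
        )
        for i, les in enumerate(self.lesions):
            c = tuple(int(round(x)) for x in les.center)
            if not all(0 <= ci < si for ci, si in zip(c, self.shape)):
                raise PhantomSpecError(f"lesion {i} center {les.center} outside volume")
            if not brain[c]:
                raise PhantomSpecError(f"lesion {i} center {les.center} outside brain")

    def grid(self, data: np.ndarray) -> VolumeGrid:
        return VolumeGrid(data, self.spacing, (0.0, 0.0, 0.0))

    def mask(self, data: np.ndarray) -> BinaryMask:
        return BinaryMask(self.grid(data.astype(np.uint8)))


def rasterize_ellipsoid(shape, spacing, center_vox, radii_mm) -> np.ndarray:
    """Boolean rasterization of an ellipsoid by the voxel-center test.

    A voxel is included iff its center satisfies
    ``sum(((i - c) * spacing / r)**2) <= 1``.
    """
    idx = np.indices(shape, dtype=np.float64)
    q = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        q += ((idx[ax] - center_vox[ax]) * spacing[ax] / radii_mm[ax]) ** 2
    return q <= 1.0


def rasterize_tube(shape, spacing, polyline, radius_mm) -> np.ndarray:
    """Boolean rasterization of a tube: voxel centers within ``radius_mm``
    (mm, Euclidean) of any polyline segment."""
    idx = np.indices(shape, dtype=np.float64)
    pts_mm = [np.asarray(p, dtype=np.float64) * np.asarray(spacing) for p in polyline]
    coords = np.stack(
        [idx[ax] * spacing[ax] for ax in range(3)], axis=-1
    )  # (nx,ny,nz,3), mm
    out = np.zeros(shape, dtype=bool)
    for a, b in zip(pts_mm[:-1], pts_mm[1:]):
        ab = b - a
        denom = float(ab @ ab)
        rel = coords - a
        if denom == 0:
            d2 = np.sum(rel**2, axis=-1)
        else:
            t = np.clip(np.tensordot(rel, ab, axes=([-1], [0])) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = np.sum((coords - proj) ** 2, axis=-1)
        out |= d2 <= radius_mm**2
    return out


def _anatomy_masks(spec: PhantomSpec):
    g = spec.roi_geometry
    brain = rasterize_ellipsoid(spec.shape, spec.spacing, g.brain_center, g.brain_radii_mm)
    ventricles = (
        rasterize_ellipsoid(
            spec.shape, spec.spacing, g.ventricle_center, g.ventricle_radii_mm
        )
        & brain
    )
    dist_to_surface = ndimage.distance_transform_edt(brain, sampling=spec.spacing)
    ribbon = brain & (dist_to_surface <= g.ribbon_thickness_mm) & ~ventricles
    zidx = np.arange(spec.shape[2])
    infra = brain & (zidx[None, None, :] < g.infratentorial_z_max)
    if np.any(ventricles & ribbon):
        raise PhantomSpecError("ventricles intersect the cortical ribbon; shrink the ventricles")
    return brain, ventricles, ribbon, infra


def _phantom_atlas(spec: PhantomSpec, brain: np.ndarray, n_labels: int = 95) -> np.ndarray:
    """Partition the brain into up to ``n_labels`` contiguous blocks.

    Blocks come from binning the brain bounding box on a 5x5x4 grid and are
    only meant to exercise overlap/argmax mechanics, not anatomy.
    """
    atlas = np.zeros(spec.shape, dtype=np.int32)
    ii = np.argwhere(brain)
    lo, hi = ii.min(axis=0), ii.max(axis=0) + 1
    bins = (5, 5, 4)
    block = np.zeros(len(ii), dtype=np.int64)
    for ax, nb in enumerate(bins):
        frac = (ii[:, ax] - lo[ax]) / max(hi[ax] - lo[ax], 1)
        b = np.minimum((frac * nb).astype(np.int64), nb - 1)
        block = block * nb + b
    labels = (block % n_labels) + 1
    atlas[tuple(ii.T)] = labels
    return atlas


def _rng(spec: PhantomSpec, stream: int, timepoint: int = 0) -> np.random.Generator:
    # independent, reproducible substream per (seed, stage, timepoint)
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stream, timepoint)))


def generate_anatomy(spec: PhantomSpec):
    """Generate the FLAIR and pre-contrast T1 volumes plus the region set.

    Returns
    -------
    flair, t1 : VolumeGrid
        Piecewise-constant tissue intensities (air 0, tissue, darker CSF,
        FLAIR lesions at baseline radii) plus additive Gaussian noise of
        sd ``tissue_noise_sd`` inside the brain.
    regions : RegionSet
        Ventricles, cortical ribbon, infratentorial slab and a 95-label
        block atlas, mutually consistent by construction.
    """
    brain, ventricles, ribbon, infra = _anatomy_masks(spec)
    flair = np.zeros(spec.shape, dtype=np.float64)
    t1 = np.zeros(spec.shape, dtype=np.float64)
    flair[brain] = spec.flair_background
    flair[ventricles] = spec.flair_csf
    t1[brain] = spec.t1_background
    t1[ventricles] = spec.t1_csf
    for les in spec.lesions:
        if les.appears_at == 0:
            ras = rasterize_ellipsoid(spec.shape, spec.spacing, les.center, les.radii_mm)
            flair[ras] = spec.flair_background + les.flair_intensity
    if spec.tissue_noise_sd > 0:
        rng = _rng(spec, stream=0)
        flair[brain] += rng.normal(0, spec.tissue_noise_sd, int(brain.sum()))
        t1[brain] += rng.normal(0, spec.tissue_noise_sd, int(brain.sum()))
    regions = RegionSet(
        ventricles=spec.mask(ventricles),
        cortical_ribbon=spec.mask(ribbon),
        infratentorial=spec.mask(infra),
        atlas=LabelMap(spec.grid(_phantom_atlas(spec, brain))),
    )
    return spec.grid(flair), spec.grid(t1), regions


@dataclass
class ChangeTruth:
    """Per-lesion, per-timepoint ground-truth change status.

    ``status[i][t]`` is one of {"absent", "new", "progressing", "stable"}:
    absent before ``appears_at``, new at ``appears_at``, progressing at any
    later timepoint where the rasterized voxel count grew, stable otherwise.
    """

    status: list[list[str]]
    voxel_counts: list[list[int]]

    @property
    def n_lesions(self) -> int:
        return len(self.status)

    @property
    def n_timepoints(self) -> int:
        return len(self.status[0]) if self.status else 0

    def counts_at(self, t: int) -> dict[str, int]:
        col = [s[t] for s in self.status]
        return {
            "n_new": col.count("new"),
            "n_progressing": col.count("progressing"),
            "n_stable": col.count("stable"),
            "n_present": sum(s != "absent" for s in col),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lesion": i,
                "timepoint": t,
                "status": self.status[i][t],
                "voxel_count": self.voxel_counts[i][t],
            }
            for i in range(self.n_lesions)
            for t in range(self.n_timepoints)
        ]
        return pd.DataFrame(rows, columns=["lesion", "timepoint", "status", "voxel_count"])


def generate_lesion_series(
    spec: PhantomSpec, n_timepoints: int, connectivity: int = 26
):
    """Rasterize the longitudinal lesion masks and their change truth.

    The mask at timepoint ``t`` is the union of the rasterizations of all
    lesions with ``appears_at <= t`` at their grown radii. Two lesions whose
    rasterizations merge into one connected component (under
    ``connectivity``) make the ground truth ambiguous and raise
    :class:`PhantomSpecError`.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    from .change import connectivity_structure  # local import avoids a cycle

    structure = connectivity_structure(connectivity)
    masks: list[BinaryMask] = []
    status = [["absent"] * n_timepoints for _ in spec.lesions]
    counts = [[0] * n_timepoints for _ in spec.lesions]
    for t in range(n_timepoints):
        union = np.zeros(spec.shape, dtype=bool)
        n_present = 0
        for i, les in enumerate(spec.lesions):
            if t < les.appears_at:
                continue
            ras = rasterize_ellipsoid(
                spec.shape, spec.spacing, les.center, les.radii_at(t)
            )
            n_vox = int(ras.sum())
            if n_vox == 0:
                raise PhantomSpecError(f"lesion {i} rasterizes to zero voxels at t={t}")
            if np.any(union & ras):
                raise PhantomSpecError(
                    f"lesion {i} overlaps another lesion at t={t}; ground truth ambiguous"
                )
            union |= ras
            n_present += 1
            counts[i][t] = n_vox
            if t == les.appears_at:
                status[i][t] = "new"
            elif n_vox > counts[i][t - 1]:
                status[i][t] = "progressing"
            else:
                status[i][t] = "stable"
        _, n_comp = ndimage.label(union, structure=structure)
        if n_comp != n_present:
            raise PhantomSpecError(
                f"lesions merge at t={t}: {n_present} lesions but {n_comp} components"
            )
        masks.append(spec.mask(union))
    return masks, ChangeTruth(status, counts)


def generate_postcontrast(spec: PhantomSpec, timepoint: int = 0):
    """Generate the post-contrast T1 at a timepoint plus exact truths.

    Enhancing lesions that exist at ``timepoint`` appear at their
    ``enhancement_intensity``; vessels at their spec intensity; both on a
    uniform brain background with additive Gaussian noise. The returned
    vessel and enhancing-lesion masks are the exact rasterizations.
    """
    brain, ventricles, _, _ = _anatomy_masks(spec)
    t1post = np.zeros(spec.shape, dtype=np.float64)
    t1post[brain] = spec.t1post_background
    t1post[ventricles] = spec.t1_csf
    enhancing = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesions:
        if les.enhancing and les.appears_at <= timepoint:
            ras = rasterize_ellipsoid(
                spec.shape, spec.spacing, les.center, les.radii_at(timepoint)
            )
            t1post[ras] = les.enhancement_intensity
            enhancing |= ras
    vessels = np.zeros(spec.shape, dtype=bool)
    for ves in spec.vessels:
        ras = rasterize_tube(spec.shape, spec.spacing, ves.polyline, ves.radius_mm)
        t1post[ras] = ves.intensity
        vessels |= ras
    if np.any(vessels & enhancing):
        raise PhantomSpecError("a vessel overlaps an enhancing lesion; truths ambiguous")
    if spec.tissue_noise_sd > 0:
        rng = _rng(spec, stream=1, timepoint=timepoint)
        t1post[brain] += rng.normal(0, spec.tissue_noise_sd, int(brain.sum()))
    return spec.grid(t1post), spec.mask(vessels), spec.mask(enhancing)


def _default_vessel() -> VesselSpec:
    # a superior-sagittal-sinus-like arc over the top of the brain
    return VesselSpec(
        polyline=[(32.0, 10.0, 50.0), (32.0, 32.0, 56.0), (32.0, 54.0, 50.0)],
        radius_mm=1.5,
        intensity=650.0,
    )


def random_phantom_spec(
    seed: int,
    n_lesions: int | None = None,
    n_timepoints: int = 4,
    noise_sd: float = 2.0,
    enhancing_fraction: float = 0.5,
) -> PhantomSpec:
    """A randomized phantom with 3-8 well-separated lesions of mixed behavior.

    Lesion centers are rejection-sampled deep inside the brain with pairwise
    clearance that accounts for growth over ``n_timepoints``, so lesions
    never merge or touch and every change status is unambiguous. Roughly a
    third of lesions appear de novo after baseline and half of the rest grow.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    if n_lesions is None:
        n_lesions = int(rng.integers(3, 9))
    geom = RoiGeometry()
    vessel = _default_vessel()
    centers: list[np.ndarray] = []
    specs: list[LesionSpec] = []
    max_radii: list[float] = []
    brain_c = np.array(geom.brain_center)
    brain_r = np.array(geom.brain_radii_mm)
    vessel_pts = np.array(vessel.polyline, dtype=float)
    attempts = 0
    while len(specs) < n_lesions:
        attempts += 1
        if attempts > 5000:
            raise PhantomSpecError("could not place well-separated lesions; reduce n_lesions")
        radius = float(rng.uniform(2.0, 4.0))
        appears_at = int(rng.integers(0, 3)) if len(specs) > 0 else 0
        growth = float(rng.choice([0.0, 0.5]))
        r_final = radius + growth * (n_timepoints - 1 - appears_at)
        # stay well inside the brain and clear of the infratentorial boundary noise
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rho = rng.uniform(0, 0.6)
        center = brain_c + u * rho * (brain_r - r_final - 4.0)
        if center[2] - r_final < geom.infratentorial_z_max + 2 and rng.uniform() < 0.5:
            continue
        ok = True
        for c_prev, r_prev in zip(centers, max_radii):
            if np.linalg.norm(center - c_prev) < r_final + r_prev + 4.0:
                ok = False
                break
        if ok and np.min(np.linalg.norm(vessel_pts - center, axis=1)) < r_final + 8.0:
            ok = False
        if not ok:
            continue
        centers.append(center)
        max_radii.append(r_final)
        specs.append(
            LesionSpec(
                center=tuple(np.round(center, 1)),
                radii_mm=(radius, radius, radius),
                appears_at=appears_at,
                growth_per_timepoint_mm=growth,
                enhancing=bool(rng.uniform() < enhancing_fraction),
            )
        )
    return PhantomSpec(
        seed=seed, tissue_noise_sd=noise_sd, lesions=specs, vessels=[vessel]
    )


def synthetic_full_atlas(
    shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0), n_labels: int = 95
) -> LabelMap:
    """A label map guaranteed to contain every label 1..n_labels (cycled over
    the flattened voxel order); used to exercise condensation coverage."""
    n = int(np.prod(shape))
    if n < n_labels:
        raise ValueError("volume too small to hold all labels")
    data = (np.arange(n, dtype=np.int32) % n_labels + 1).reshape(shape)
    return LabelMap(VolumeGrid(data, spacing, (0.0, 0.0, 0.0)))
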