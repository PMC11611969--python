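# Methods notes

This note records the models and procedures behind `mslesion`, the defaults
chosen where the problem is genuinely under-determined, what the synthetic
phantom does and does not emulate, and the package's known limitations.

## Scope and input contract

The package operates strictly downstream of image preprocessing. All inputs
— FLAIR and pre/post-contrast T1 volumes, binary lesion maps, anatomical
region masks (ventricles, cortical ribbon, infratentorial compartment), a
subregion atlas — must already live on one voxel grid. `check_same_grid`
enforces this (shape exact; spacing and origin within 1e-3 mm) and nothing
in the package resamples, reorients or intensity-corrects. Voxel indices
are 0-based; world coordinates are `origin + index · spacing`; a single
orientation is assumed throughout. Binary masks read from disk are
binarized by `value > 0` (logged when values other than {0, 1} occur), so
probabilistic lesion maps saved as floats are tolerated; negative voxels
are rejected as a corrupt mask.

## Longitudinal change classification

Given baseline `B` and follow-up `F` lesion maps, subtraction keeps only
voxels present at follow-up (`A = F ∧ ¬B`); lesion regression is visible as
absence, never as a class of its own. Classification is *per follow-up
lesion*, not per added fragment: the subtraction shell of a smoothly
growing lesion can rasterize into several disconnected pieces (isolated
corner voxels), and counting those as separate events would inflate
progression counts. Each connected follow-up component is therefore
classified once by its added voxels — stable (none), progressing (some, and
the component overlaps or is adjacent to `B`), or new (standalone). New and
progressing components report the measurements of their added portion
(voxel count, volume, centroid), which for a new lesion is the whole
lesion; the added voxels are exactly partitioned by the new and progressing
components.

One connectivity parameter (default 26, the most inclusive standard 3D
adjacency) governs both component labeling and the "attached" test, so the
two notions cannot disagree. "Attached" means: at least one component voxel
lies within the connectivity neighborhood of a baseline lesion voxel
(overlap included). No minimum added volume is imposed on progression, and
new lesions have no size floor by default (`min_new_voxels = 1`); both are
policy knobs, not science. Follow-ups are compared to the immediately
preceding study by default, with baseline comparison available.

## Contrast-enhancement detection

The chain is deliberately simple and fully auditable: median filter
(default 3×3×3, borders edge-replicated) → brain mask (Otsu's threshold on
the filtered volume; a fixed cutoff is available for non-bimodal data) →
detection threshold → supra-threshold voxels inside the brain → connected
components → size filter → vessel exclusion → optional restriction to the
FLAIR lesion map.

The detection threshold is `median + k·MAD` computed over brain voxels of
the filtered volume, with `k = 3` and the MAD left unscaled (no 1.4826
normal-consistency factor). A robust location/scale rule is used because
the enhancing voxels being sought are exactly the outliers that would
corrupt a mean/SD estimate; `mean + k·SD` is available as an alternative.
Under Gaussian noise this default sits near 2 filtered-noise standard
deviations, which favors recall over precision: on noisy data some small
false candidates survive (and are then curtailed by the 3-voxel size floor
and the lesion-map restriction), while enhancing lesions of realistic
contrast are reliably found. The threshold actually used is recorded in
every result (`threshold_used`) and in the pipeline provenance block.

Vessels are gadolinium-bright and would otherwise dominate the candidates.
A voxel is vessel iff its **raw** (unfiltered) intensity strictly exceeds
`vessel_threshold` (default 600) — unfiltered so that thin vessels the
median filter erodes still veto; strict so that a voxel at exactly 600 is
not vessel. Exclusion is component-level: a candidate sharing even one
voxel with the vessel mask is removed entirely. The 600 default is an
absolute intensity and therefore scanner- and sequence-dependent; it is a
required-review configuration value on any new intensity calibration.

A note on monotonicity: the threshold value and the supra-threshold voxel
set are monotone in `k`, but the *number* of candidate components is not —
lowering the cutoff can merge neighboring components into one, so the count
can rise as `k` increases. The tests assert the monotone forms.

## McDonald localization and atlas condensation

The four location classes are named in the diagnostic criteria but have no
single operational definition, so each test is explicit and parameterized:
infratentorial = any overlap with the infratentorial mask; periventricular
= voxel contact with the ventricle mask (a positive `mm` tolerance via
Euclidean distance transform is available, default 0); cortical = strict
majority of voxels inside the cortical ribbon; juxtacortical = overlap with
a band of configurable width (default 1 mm ≈ 1 voxel) around the ribbon;
otherwise "other" (unspecified white matter). A lesion touching several
regions gets exactly one label via a configurable, logged precedence order
(default infratentorial ≻ periventricular ≻ cortical ≻ juxtacortical ≻
other), which keeps the report's row-sum invariant (region counts sum to
total lesions) exact.

The 95-subregion atlas is condensed to 23 named key areas through
`src/mslesion/data/hammers_condensation_23.csv`, a two-column
(subregion_label, key_area_name) table shipped as editable, versioned data.
Only three of the 23 area names are fixed by convention (temporal lobe,
cingulum, basal ganglia); the remaining grouping is this package's
construction and should be replaced by a site's own table where one exists.
Condensation is total: an atlas label absent from the table raises a named
coverage error rather than silently passing through. Per-lesion area
assignment is by maximal voxel overlap, ties broken toward the smaller area
id.

## Lesion-wise evaluation

Automated and reference maps are compared at the component level because
that is the unit a reader corrects. Matching is one-to-one and greedy by
descending overlap (ties toward smaller predicted, then reference, id) with
a minimum overlap of 1 voxel; per-pair Dice is reported but is not the
headline metric. Split/merge cases resolve conservatively: one reference
lesion covered by two predictions yields one true positive and one false
positive. `misclassifications = FP + FN`.

## The phantom generator

The phantom stands in for a longitudinal MS study: a two-tissue ellipsoidal
brain with darker CSF ventricles, a cortical ribbon (outer 3 mm shell), an
inferior infratentorial slab, a 95-label block atlas, ellipsoidal lesions
that may appear de novo at any timepoint and/or grow by a fixed radius
increment per interval, tubular vessels along polylines, and post-contrast
T1 volumes where enhancing lesions and vessels are hyperintense. The
default grid is 64³ at 1 mm isotropic — small enough that every test and
the acceptance script run in seconds on one CPU, large enough that lesions,
shells and bands are well resolved.

Rasterization is a pure voxel-center test (a voxel belongs to an ellipsoid
iff its center satisfies the closed ellipsoid inequality; tubes use
center-to-segment distance ≤ radius), which makes brute-force counting
oracles exact. Noise is additive Gaussian, applied inside the brain after
structure placement; every random draw derives from the spec seed through
named substreams, so equal (spec, seed) gives bitwise-equal volumes. The
intensity scale is calibrated so the absolute vessel cutoff is meaningful:
post-contrast background ≈ 300, enhancing lesions ≈ 500, vessels ≈ 650,
all configurable. Randomized study layouts (`random_phantom_spec`) place
3–8 spherical lesions (radius 2–4 mm) with pairwise clearance that accounts
for growth, so no two lesions ever merge or touch and every change status
is unambiguous by construction; about a third appear after baseline and
half of the rest grow by 0.5 mm per interval.

What the phantom does **not** emulate: MRI physics (partial volume, bias
fields, Rician noise), anatomical realism, scanner and sequence intensity
variation, registration error, or segmentation error in the input lesion
maps. Passing the phantom-based tests therefore demonstrates that the
*rules* are implemented exactly as specified — not that the defaults are
clinically optimal on real scanners, where the intensity-dependent
parameters (vessel threshold above all) must be re-validated.

## Numerical and degenerate-input choices

- Grid agreement tolerance 1e-3 mm; shapes must match exactly.
- Otsu brain masking on a constant image raises (no histogram to split)
  rather than returning an arbitrary mask; an empty brain mask makes the
  detection threshold undefined and raises.
- Empty components cannot be localized (error); a component outside all
  atlas labels returns background with fraction 0.
- All tie-breaks are deterministic and documented (smaller label/area id);
  report JSON is written with sorted keys so runs are byte-comparable.
- End-to-end ground-truth recovery is verified on noiseless phantoms: the
  lesion masks are exact by construction, and the enhancement chain's
  recall-over-precision default means noisy runs may add small false
  candidates (bounded and measured separately) without invalidating the
  change, localization or report logic.

## Limitations

- The enhancement threshold formula and the 23-area condensation table are
  reconstructions of practice, exposed as configuration, not facts of any
  scanner or atlas release.
- Lesions are not tracked by identity across more than two studies; the
  series report aggregates pairwise comparisons.
- One orientation, one grid: no resampling means misregistered inputs fail
  fast rather than being corrected.
- Reading-time modeling of human readers is out of scope; the evaluation
  module only produces the lesion-wise FP/FN counts such analyses consume.
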