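# mslesion

Automated assessment of longitudinal brain MRI in multiple sclerosis (MS).

Monitoring MS means answering, for every follow-up scan, a small set of
questions that are tedious and error-prone to answer by eye: which FLAIR
lesions are **new**, which existing lesions have **progressed** (enlarged),
which lesions **enhance** after gadolinium (active inflammation), and where
each lesion sits with respect to the **McDonald criteria** locations
(periventricular, juxtacortical, cortical, infratentorial). `mslesion`
implements these steps as a tested library and CLI for co-registered NIfTI
volumes, and ships a synthetic 3D phantom generator so the whole chain can
be exercised — and scored — against exact ground truth without any patient
data. Upstream steps (bias-field correction, registration, lesion and
anatomy segmentation) are deliberately out of scope: their outputs are this
tool's inputs.

## Methods at a glance

- **Change classification.** With baseline and follow-up lesion maps
  `B, F ∈ {0,1}^(nx×ny×nz)` on one grid, the added map is `A = F ∧ ¬B`.
  Each connected follow-up lesion (6/18/26-connectivity, default 26) is
  classified by its added voxels: none → *stable*; some, and the lesion
  overlaps or is adjacent to `B` ("attached") → *progressing*; standalone →
  *new*.
- **Contrast-enhancement detection.** On post-contrast T1: median filter →
  brain mask (Otsu) → threshold `median + k·MAD` over the brain (k = 3,
  MAD unscaled) → connected components → drop components < 3 voxels → drop
  any component overlapping the vessel mask (voxels with raw intensity
  > 600) → optionally keep only components overlapping the FLAIR lesion
  map.
- **Localization.** Precedence-ordered tests per lesion: infratentorial
  (any overlap) ≻ periventricular (ventricle contact) ≻ cortical (majority
  in the cortical ribbon) ≻ juxtacortical (touching a 1-voxel band around
  the ribbon) ≻ other. A 95-subregion Hammers-style atlas is condensed to
  23 named key areas via a shipped, editable table, and each lesion gets
  the area of maximal overlap.
- **Evaluation.** Automated vs. reference lesion maps are compared
  lesion-wise: one-to-one greedy matching by overlap; unmatched predictions
  are false positives, unmatched reference lesions false negatives;
  `misclassifications = FP + FN`.
- **Reporting.** One row per study: counts per McDonald region and key
  area, totals, new/progressing/enhancing counts, total lesion volume (ml),
  and a cumulative new-lesion column across the series.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a 4-timepoint synthetic study and run the full pipeline:

```sh
cat > demo.yaml <<EOF
study_id: demo
phantom:
  enabled: true
  seed: 7
  noise_sd: 0.0
  write_volumes: false
output_dir: demo-out
EOF
mslesion run-all --config demo.yaml
```

prints (key-area columns elided):

```
study_id  timepoint  n_infratentorial  n_periventricular  n_cortical  n_juxtacortical  n_other  total_lesions  n_new  n_progressing  n_enhancing  total_volume_ml  cumulative_new
    demo          0                 0                  1           0                0        2              3      3              0            1            0.217               3
    demo          1                 0                  1           0                0        2              3      0              1            1            0.291               3
    demo          2                 0                  2           0                0        4              6      3              1            2            0.718               6
    demo          3                 0                  3           0                0        3              6      0              3            2            0.982               6
```

Reading the table: the baseline (t0) has 3 lesions, all counted as new
(first seen), one of them enhancing; at t2 three lesions appear de novo and
one existing lesion has enlarged; by t3 three lesions are enlarging and the
total lesion volume has grown to 0.982 ml. Every count here equals the
phantom's construction ground truth (`demo-out/phantom_truth.csv`), and
`demo-out/report.json` carries a provenance block with every default the
run used (threshold rule and value, connectivity, precedence, condensation
table).

Each stage is also available standalone on NIfTI files:

```sh
mslesion phantom  --seed 7 --out-dir study/
mslesion change   --baseline study/lesions_t0.nii.gz --followup study/lesions_t1.nii.gz --out-prefix ch
mslesion enhance  --t1post study/t1post_t3.nii.gz --lesions study/lesions_t3.nii.gz --out-prefix en
mslesion evaluate --pred en_candidates.nii.gz --ref study/enhancing_truth_t3.nii.gz --out-prefix ev
```

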