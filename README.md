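# spineannot

Automated annotation of lumbar spine MRI: given a mid-sagittal
T2-weighted slice and a six-region segmentation label map, `spineannot`
locates and names each intervertebral disc (IVD), measures its height
geometrically, and predicts its Pfirrmann degeneration grade.  It is
aimed at researchers building radiology decision-support pipelines who
have a segmentation backend (any model emitting the six-region label
convention) and need the downstream anatomy, morphometry, and grading
steps.

## What it computes

**Regions.** Label maps partition the slice into Anterior, PosteriorA,
PosteriorB, Vertebrae, IVD, and Sacrum (codes 1-6).  Inferred maps are
repaired by connected-component post-processing (hole closing,
largest-component selection, dissolving fragments under 20 px) until
they satisfy the same topological requirements as expert-drawn maps.

**Naming.** The merged Sacrum+Vertebrae+IVD region is thinned to a
one-pixel centerline; A* pathfinding orders it from the sacral (lowest)
endpoint upward and prunes thinning branches.  Walking the path, the
1st, 2nd, ... disc runs are named L5/S1, L4/L5, ..., vertebrae L5, L4,
... likewise.

**Height.** On a 4x-upscaled frame, the middle 30% of each disc's
superior and inferior boundary point sets are fitted with orthogonal
regression lines.  With centres C_T, C_B and perpendiculars v_T, v_B,
projections C'_T, C'_B onto the opposite lines give the first estimate
M_T = (C_T + C'_B)/2, M_B = (C_B + C'_T)/2.  Each endpoint then slides
along its perpendicular (range k) to the pixel maximizing the directed
Prewitt gradient b_p = cos(beta_p - alpha) * m_p, and

    height = ||M'_T - M'_B|| * ps' / 4   (mm),

where ps' = ps * dm / 384 is the pixel spacing rescaled to the 384 px
working frame.

**Grade.** A disc measured strictly below 3.0 mm is grade 5
(collapsed).  Otherwise a classifier (default: Random Forest with 15
trees, min leaf 1, max 114 splits, 20 sampled variables, samples
weighted by tw_c = median(f)/f_c) predicts grades 1-4 from the
*self-similar color correlogram* of the disc's nucleus: intensities are
offset so the vertebrae mean matches a cohort reference (gl = gl_orig -
(gl_vert - 69)), quantized into N = 30 bins capped at 150, and the
probability table C_ij of bin pairs at chessboard distance d = 4 is
restricted to the band |i - j| <= w, giving a feature of length
N(2w+1) - w(w+1) (default w = 2: 144 values).

**Phantoms.** A seeded generator renders synthetic studies (image +
valid label map + ground-truth heights/grades) with curvature, per-disc
tilt, skeleton-branch bumps, grade-dependent nucleus intensity/texture,
exposure offsets, and noise, so the whole pipeline is testable without
clinical data.

## Worked example

```bash
python examples/03_measure_disc_heights.py
```

```
disc      measured   truth   error
L5/S1       8.24mm  8.49mm  -0.25mm
L4/L5       6.42mm  6.26mm  +0.16mm
L3/L4       2.37mm  2.19mm  +0.18mm
```

Three discs of a noise-free phantom (grades 1, 3, 5): measured heights
recover the rendered geometry within a quarter millimetre, and the
collapsed 2.4 mm disc falls under the 3.0 mm rule, so it is graded 5
without consulting the classifier.  The grading experiment
(`examples/04_grade_prediction_experiment.py`, 120 balanced discs)
prints a stratified 10-fold CV accuracy of 95.8% for the grade 1-4
classifier and a diagonal 5x5 confusion matrix for the combined
rule+classifier pipeline.

The `spineannot` CLI wraps the same library calls for shell use:
`spineannot annotate mri.png labels.png`, `spineannot phantom`,
`spineannot experiment`.

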