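# Methods

`annostream` implements a human-in-the-loop pipeline for producing
voxel-level lesion annotations of volumetric scans at a fraction of the cost
of manual delineation. A pre-trained few-shot patch segmenter (pluggable;
this package ships deterministic mocks behind the same interface) produces
initial labels for a pool of unlabeled query scans, conditioned on a small
support set of labeled slice patches; the scans whose labels are cheapest
and most informative to fix are prioritized for manual correction; and the
remaining effort is quantified in mouse clicks. The corrected scans plus the
support scans are exported as a supervised training dataset (nnU-Net raw
layout supported).

## Pipeline model and assumptions

1. **Pre-processing.** Scan intensities are clipped to a preset window
   `[clip_lo, clip_hi]` (default −100 to 200, a CT soft-tissue-like window;
   the window is a config value, not a code constant) and min–max scaled to
   [0, 1]. A constant volume maps to all zeros. Each axial slice is
   decomposed into `P × P` patches (default `P = 128`) on a half-stride grid
   (stride 64). If the regular grid stops short of the slice edge, one
   extra edge-aligned origin is appended per axis so that every pixel is
   covered; slices smaller than `P` are zero-padded bottom/right. The
   segmenter is assumed 2D-only, so there are no 3D patches.
2. **Support-set selection.** Candidate patches are those whose label
   window holds strictly more than `positivity_threshold` (30) positive
   pixels. The clustering policy flattens each candidate's binary label
   window row-major, runs seeded k-means (`k = 100`, 10 restarts) on those
   vectors, removes the single largest cluster (ties broken toward the
   lowest cluster id; the dominant cluster tends to hold the most frequent,
   least informative pattern), and apportions the patch budget
   (`support_budget = 450`) over the remaining clusters proportionally to
   their size using the largest-remainder rule, drawing uniformly without
   replacement inside each cluster. Largest-remainder apportionment was
   chosen because it is deterministic, conserves the budget exactly, and
   needs no rounding convention beyond the id tie-break. A uniform random
   policy is provided as the baseline. If fewer candidates exist than the
   budget, all are returned with a warning. Clustering operates on label
   vectors only, not on image intensities.
3. **Inference and stitching.** The segmenter returns a `P × P`
   foreground-score grid in [0, 1] per query patch. Overlapping scores are
   combined per pixel by their *mean* and thresholded at 0.5, with ties
   counted as foreground. The mean rule is symmetric in the overlapping
   patches and makes decomposition + stitching an exact round trip whenever
   the segmenter reproduces its inputs, which gives the pipeline a strong
   internal consistency check. A logical-OR mode exists for binary-only
   segmenters (off by default). Stitched slices are stacked into a 3D
   volume; lesions are its 26-connected components (connectivity
   configurable: 6/18/26).
4. **Post-processing.** Background cavities fully enclosed in 3D are
   filled (a 2D per-slice mode is available), then components with at most
   `min_lesion_voxels` (30) voxels are removed. Filling runs first because
   it can only grow components, so removal is decided on final sizes. The
   operation is idempotent.
5. **Prioritization.** Scans are ranked for manual correction in three
   tiers using the *computed* labels only: (1) scans with lesions whose
   diameter is ≥ `diameter_threshold_mm` (10 mm), ordered by descending
   count of such lesions; (2) scans with lesions but none large; (3)
   lesion-free scans. All remaining ties break lexicographically by scan id
   for reproducibility. The first `n_correct` scans (default 10; 10–30 is
   typical practice) are flagged.
6. **Correction and export.** In simulation mode the flagged scans'
   computed labels are replaced voxel-for-voxel by ground truth and the
   avoided/remaining effort is reported; in interactive mode the user
   supplies corrected label files. Corrected + support scans are exported
   in the nnU-Net raw-dataset convention (`imagesTr/`, `labelsTr/`,
   `dataset.json`) or as flat pairs with a CSV manifest; training is always
   external and is never invoked by this package. The stopping rule
   ("performance is satisfactory") is a user decision; the default is a
   single iteration.

## Lesion geometry

- **Diameter.** Two definitions are provided, selectable in config. The
  default `equivalent_sphere` is volume-derived:
  `d = 2 · (3V / 4π)^(1/3)` with `V = voxel_count ×` voxel volume, which is
  consistent with treating a ~30-voxel lesion as ~3 mm at 1 mm isotropic
  spacing. `max_inplane` returns the largest physical distance between two
  same-slice contour pixels (a RECIST-style long axis). Neither is asserted
  as canonical; the threshold test `d ≥ 10 mm` is inclusive in both.
- **Contour.** Defined per axial slice (corrections happen slice-wise): a
  lesion pixel with at least one 4-neighbor outside the lesion in that
  slice; out-of-bounds neighbors count as background.

## Evaluation metrics

Matching is lesion-level with the one-voxel-overlap rule: any overlap makes
a computed component a true positive; a computed component with no GT
overlap is a false positive; an untouched GT lesion is a false negative. A
computed component overlapping several GT lesions is assigned to the one
with the largest overlap (ties: larger GT lesion, then lower id). Several
computed components may overlap one GT lesion: the lesion counts as
detected once, the extra components are not false positives, and the
components are merged into the pair's mask for segmentation scoring.

- Detection: precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 their
  harmonic mean. With neither computed nor GT lesions everything is 1;
  precision with zero computed lesions is reported missing (NaN/null).
- Segmentation: per-pair Dice `2|A∩B|/(|A|+|B|)` averaged over pairs
  within a scan and then over scans; `Dice_with_FN` averages over
  TP ∪ FN ∪ FP with unmatched lesions scoring 0, so it degrades when
  detection is poor.
- Effort (click model): one click per FP lesion (discard), one per FN
  lesion (mark), one per erroneous pixel on a matched lesion's contour.
  `FNR = FN / GT lesions`, `FPR = FP / GT lesions` (FPR may exceed 1;
  both are undefined when a scan has no GT lesions and are reported
  missing). Erroneous contour pixels of a matched pair are the per-slice
  symmetric difference between the computed and GT contours, covering both
  added and deleted pixels; `CCS` is that count divided by the pair's GT
  contour pixels, averaged over pairs. CCS can exceed 1: shifting an entire
  boundary by one voxel makes both the old and the new contour erroneous.
  The clicks needed to delineate FN lesions from scratch are reported
  separately (`fn_delineation_clicks`) rather than folded into
  `contour_clicks`, since whether published contour-pixel counts include
  them is ambiguous; keeping the totals separate loses no information.

## Synthetic data

`PhantomSpec` generates scans with pairwise-disjoint ellipsoidal lesions on
a noisy uniform background: default 96 × 96 × 40 voxels at 1 mm isotropic,
20 lesions per scan (a typical metastatic-liver lesion load), diameters
4–14 mm with 30% at or above 10 mm, +60 intensity units of lesion contrast
over a background of 40 with Gaussian noise σ = 10 — enough contrast that
clipping/normalization is exercised nontrivially, and every lesion above
the 30-voxel removal threshold unless small lesions are requested
explicitly. Ellipsoid semi-axes preserve the requested equivalent-sphere
diameter (geometric mean equals the radius). Placement is rejection
sampling with a 2-voxel margin so components stay disjoint.

`PerturbationSpec` corrupts ground truth to mock an imperfect segmenter:
each lesion dropped with probability `p_fn`; Poisson(`fp_rate`) spurious
blobs per scan, placed away from true lesions and sized above the removal
threshold (a sub-threshold variant exercises the removal rule); and a
per-lesion signed morphological jitter radius (positive dilates, negative
erodes). Injected rates are recoverable end to end: measured FNR matches
`p_fn` and mean spurious components per scan matches `fp_rate` within
3 standard errors in the seeded tests, and contour error grows
monotonically with jitter radius.

What the phantoms do **not** emulate: organ anatomy and texture, intensity
inhomogeneity, partial-volume effects, anisotropic spacing artifacts,
spatially correlated segmenter errors (real few-shot models fail more on
small/low-contrast lesions — which is exactly the behavior the
prioritization tiers exploit), and inter-reader variability. Passing tests
therefore validate the pipeline's mechanics, determinism, and metric
arithmetic, not clinical segmentation quality.

## Numerical and design choices

- Axis convention `(slice, row, col)`; NIfTI axes are reversed on read and
  restored on write, spacing follows the array axes.
- Label binarization: any value > 0 is foreground (with a warning for
  non-binary inputs).
- Lesion ordering: descending voxel count, ties by first voxel in scan
  order; ids assigned after sorting.
- All boundary rules are asserted at their exact thresholds: patch
  positivity is strict (`> 30` pixels), small-component removal is
  inclusive (`≤ 30` voxels), the large-lesion rule is inclusive
  (`≥ 10 mm`).
- Every stochastic step (k-means, sampling, phantoms, perturbations) is
  driven by explicit integer seeds; repeated runs are bit-identical.
- Problem sizes in the test suite and acceptance script (volumes ≤ 64³,
  tens of scans, hundreds of lesions) were chosen as the smallest sizes at
  which the statistical checks (binomial/Poisson recovery at 3 SE) are
  meaningful.

## Known limitations

- The click model ignores viewing/scrolling time and advanced editing
  tools; it is a comparative effort measure, not a time estimate.
- No resampling, registration, or DICOM ingestion: inputs are NIfTI
  volumes on a common grid.
- The support-selection heuristic (drop the largest cluster) is exactly
  that — a heuristic; on degenerate pools where all patches fall in one
  cluster the policy falls back to sampling that cluster with a warning.
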