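# annostream

Streamlined annotation of lesions in volumetric medical scans.

Manual voxel-level annotation of small lesions (liver, lung, or brain
metastases in CT/MRI) is the main bottleneck for training supervised
segmentation models. `annostream` implements a correct-instead-of-draw
pipeline: a pre-trained few-shot patch segmenter produces initial 3D labels
for a pool of unlabeled scans from a small labeled support set, the scans
whose labels are most worth fixing are prioritized for manual correction,
and the remaining effort is quantified in mouse clicks. The corrected scans
are exported for supervised training (nnU-Net raw layout supported).

The core pieces:

- **Support-set selection** — positive 128 × 128 slice patches (strictly
  more than 30 lesion pixels) are clustered by k-means (k = 100) on their
  flattened binary label windows; the largest cluster is dropped and a
  450-patch budget is sampled proportionally from the rest
  (largest-remainder apportionment), giving a pattern-diverse support set.
- **Inference + stitching** — a pluggable segmenter scores half-stride
  overlapping patches; per-pixel mean of scores thresholded at 0.5 gives
  slice masks, stacked into 3D, holes filled, components of ≤ 30 voxels
  removed. Lesions are 3D connected components (26-connectivity).
- **Prioritization** — scans ranked by count of lesions with diameter
  ≥ 10 mm (equivalent-sphere `d = 2·(3V/4π)^{1/3}` by default), then scans
  with only small lesions, then lesion-free scans; the top *M* go to the
  reader.
- **Effort metrics** — lesion-level matching by the one-voxel-overlap
  rule; precision/recall/F1, per-lesion Dice and Dice_with_FN;
  FNR = FN/GT, FPR = FP/GT, and the contour correction score
  CCS = erroneous contour pixels / GT contour pixels, plus raw click
  counts (one click per FP/FN lesion, one per erroneous contour pixel).
- **Synthetic fixtures** — seeded phantoms with ellipsoidal lesions and a
  perturbed mock segmenter (controllable FN probability, FP rate, boundary
  jitter), so the whole pipeline is testable without any dataset.

The actual few-shot model is *not* bundled: any callable mapping
`(query patch, support set) → P×P score grid` plugs in via the segmenter
registry.

## Worked example

```python
import numpy as np
from annostream import (
    PhantomSpec, PipelineConfig, generate_phantom, make_perturbed_segmenter,
    run_inference, match_lesions, effort_metrics, prioritize_scans, SupportSet,
)

# a synthetic scan with 12 lesions, and a mock segmenter that misses 30%
spec = PhantomSpec(shape=(24, 64, 64), n_lesions=12, seed=100)
scan, gt, manifest = generate_phantom(spec, scan_id="demo")
seg = make_perturbed_segmenter(gt, p_fn=0.3, fp_rate=2.0, seed=500)

cfg = PipelineConfig()
computed = run_inference(scan, SupportSet(patches=[], policy="clustering"), seg, cfg)

report = effort_metrics(match_lesions(computed, gt))
print(f"FNR={report.fnr:.3f} FPR={report.fpr:.3f} CCS={report.ccs:.3f}")
print(f"clicks: {report.detection_clicks_fp} FP, {report.detection_clicks_fn} FN, "
      f"{report.contour_clicks} contour")
```

prints

```
FNR=0.083 FPR=0.167 CCS=0.000
clicks: 2 FP, 1 FN, 0 contour
```

— of the 12 true lesions, 1 was missed on this seed (FNR 0.083, one click
to mark it), 2 spurious lesions must be discarded (FPR 0.167, one click
each), and the lesions that were found have exact contours (CCS 0, no
contour clicks), so correcting this scan costs 3 clicks instead of
delineating 12 lesions from scratch.

A full simulated iteration (support selection → inference → prioritization
→ simulated correction → export) is one call, `annostream.run_iteration`,
or from the shell:

```bash
annostream synth --out data --n-scans 5 --seed 0
annostream run --support-scans data/scans --support-labels data/labels \
    --query-scans data/scans --query-gt data/labels --out results/run
```

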