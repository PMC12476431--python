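"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (BFS flood fill, per-pixel neighbor
enumeration, dict-of-sets arithmetic) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np

OFFSETS_6 = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
]
OFFSETS_26 = [
    (ds, dr, dc)
    for ds in (-1, 0, 1)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (ds, dr, dc) != (0, 0, 0)
]
OFFSETS_18 = [o for o in OFFSETS_26 if sum(abs(x) for x in o) <= 2]


def flood_fill_components(volume: np.ndarray, connectivity: int = 26):
    """BFS connected components; returns a list of voxel-coordinate sets."""
    offsets = {6: OFFSETS_6, 18: OFFSETS_18, 26: OFFSETS_26}[connectivity]
    vol = np.asarray(volume) > 0
    seen = np.zeros(vol.shape, dtype=bool)
    components = []
    for start in zip(*np.nonzero(vol)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = set()
        while queue:
            s, r, c = queue.popleft()
            comp.add((int(s), int(r), int(c)))
            for ds, dr, dc in offsets:
                n = (s + ds, r + dr, c + dc)
                if (
                    0 <= n[0] < vol.shape[0]
                    and 0 <= n[1] < vol.shape[1]
                    and 0 <= n[2] < vol.shape[2]
                    and vol[n]
                    and not seen[n]
                ):
                    seen[n] = True
                    queue.append(n)
        components.append(comp)
    return components


def brute_contour(pixels: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """4-neighbor contour of an in-slice pixel set by direct enumeration."""
    return {
        (r, c)
        for (r, c) in pixels
        if any(
            (r + dr, c + dc) not in pixels
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
        )
    }


def contours_by_slice(component: set[tuple[int, int, int]]):
    per_slice: dict[int, set[tuple[int, int]]] = {}
    for s, r, c in component:
        per_slice.setdefault(s, set()).add((r, c))
    return {s: brute_contour(p) for s, p in per_slice.items()}


def brute_metrics(computed: np.ndarray, gt: np.ndarray, connectivity: int = 26):
    """Full detection/effort metric bundle by direct enumeration.

    Matching follows the one-voxel-overlap rule; a GT lesion overlapped by
    any computed component counts as detected once, and every computed
    component overlapping it contributes to the pair's merged mask.
    """
    comp = flood_fill_components(computed, connectivity)
    gtc = flood_fill_components(gt, connectivity)
    fp = [c for c in comp if all(not (c & g) for g in gtc)]
    detected = [g for g in gtc if any(c & g for c in comp)]
    fn = [g for g in gtc if all(not (c & g) for c in comp)]
    n_tp, n_fp, n_fn = len(detected), len(fp), len(fn)
    out = {
        "n_tp": n_tp,
        "n_fp": n_fp,
        "n_fn": n_fn,
        "n_gt": len(gtc),
        "n_computed": len(comp),
    }
    out["precision"] = n_tp / (n_tp + n_fp) if n_tp + n_fp else None
    out["recall"] = n_tp / (n_tp + n_fn) if n_tp + n_fn else None
    out["fnr"] = n_fn / len(gtc) if gtc else None
    out["fpr"] = n_fp / len(gtc) if gtc else None
    dices = []
    ccs_terms = []
    contour_clicks = 0
    for g in detected:
        merged = set().union(*(c for c in comp if c & g))
        dices.append(2 * len(merged & g) / (len(merged) + len(g)))
        cc = contours_by_slice(merged)
        gc = contours_by_slice(g)
        errors = sum(
            len(cc.get(s, set()) ^ gc.get(s, set())) for s in set(cc) | set(gc)
        )
        gt_pix = sum(len(p) for p in gc.values())
        contour_clicks += errors
        if gt_pix:
            ccs_terms.append(errors / gt_pix)
    out["dice"] = float(np.mean(dices)) if dices else None
    all_d = dices + [0.0] * (n_fn + n_fp)
    out["dice_with_fn"] = float(np.mean(all_d)) if all_d else None
    out["ccs"] = float(np.mean(ccs_terms)) if ccs_terms else None
    out["contour_clicks"] = contour_clicks
    out["fn_delineation_clicks"] = sum(
        sum(len(p) for p in contours_by_slice(g).values()) for g in fn
    )
    return out


def random_blob_volume(rng: np.random.Generator, shape, density: float = 0.5):
    """Random binary volume: thresholded smoothed noise gives blobby masks."""
    noise = rng.random(shape)
    # cheap smoothing via local averaging to create connected structure
    from scipy import ndimage as ndi

    smooth = ndi.uniform_filter(noise, size=3)
    return (smooth > np.quantile(smooth, 1 - density)).astype(np.uint8)
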