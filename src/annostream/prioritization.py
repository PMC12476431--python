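"""Ranking of computed scan labels for manual correction.

Scans are tiered: (1) scans with at least one lesion whose diameter is at
least the threshold (default 10 mm), sorted by descending count of such
large lesions; (2) scans with lesions but none large; (3) scans without
lesions. Large lesions are both the most clinically informative and the ones
few-shot segmenters get most nearly right, so their scans are corrected
first. Ranking consults the computed labels only, never the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .volume_model import DiameterMode, LabelVolume, find_lesions


@dataclass
class PrioritizedList:
    """Total ordering of scans with the flagged top-M subset.

    ``entries`` rows carry scan_id, tier, n_large (count of lesions >= the
    diameter threshold), n_lesions, rank (1-based) and a flagged marker for
    the first M scans.
    """

    entries: pd.DataFrame

    @property
    def scan_ids(self) -> list[str]:
        return list(self.entries["scan_id"])

    @property
    def flagged(self) -> list[str]:
        return list(self.entries.loc[self.entries["flagged"], "scan_id"])


def count_large_lesions(
    labels: LabelVolume,
    diameter_threshold_mm: float = 10.0,
    connectivity: int = 26,
    diameter_mode: DiameterMode = "equivalent_sphere",
) -> int:
    """Number of lesions with diameter >= the threshold (inclusive)."""
    lesions = find_lesions(labels, connectivity=connectivity, diameter_mode=diameter_mode)
    return sum(1 for l in lesions if l.diameter_mm >= diameter_threshold_mm)


def prioritize_scans(
    labels_by_scan: dict[str, LabelVolume],
    n_correct: int,
    diameter_threshold_mm: float = 10.0,
    connectivity: int = 26,
    diameter_mode: DiameterMode = "equivalent_sphere",
) -> PrioritizedList:
    """Rank scans by the tier rules and flag the first ``n_correct``.

    Within tier 1 scans sort by descending large-lesion count; all remaining
    ties (and tiers 2-3, where the ranking is indifferent) break
    lexicographically by scan_id for reproducibility.
    """
    if n_correct < 1:
        raise ValueError("n_correct must be >= 1")
    rows = []
    for scan_id, labels in labels_by_scan.items():
        lesions = find_lesions(
            labels, connectivity=connectivity, diameter_mode=diameter_mode
        )
        n_large = sum(1 for l in lesions if l.diameter_mm >= diameter_threshold_mm)
        if n_large > 0:
            tier = 1
        elif lesions:
            tier = 2
        else:
            tier = 3
        rows.append(
            {"scan_id": scan_id, "tier": tier, "n_large": n_large, "n_lesions": len(lesions)}
        )
    df = pd.DataFrame(rows, columns=["scan_id", "tier", "n_large", "n_lesions"])
    df = df.sort_values(
        by=["tier", "n_large", "scan_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if n_correct > len(df):
        warnings.warn(
            f"n_correct={n_correct} exceeds the {len(df)} available scans; "
            "flagging all of them",
            stacklevel=2,
        )
    df["rank"] = df.index + 1
    df["flagged"] = df["rank"] <= n_correct
    return PrioritizedList(entries=df)
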