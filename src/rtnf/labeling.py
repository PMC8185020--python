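"""Functional and structural labeling of statistic maps.

Functional labeling scores a (by default unthresholded) group z map
against each map of a template network set by Pearson spatial
correlation over the shared mask and ranks the templates by r.
Structural labeling parcellates a thresholded map with a
probabilistic atlas binarized at a probability threshold (0.25 by
default), and a tri-color overlap map partitions the union of two
thresholded paradigm maps into paradigm-specific and shared voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapglm import StatMap
from .synthetic import TemplateSet

__all__ = [
    "LabelReport",
    "spatial_correlation",
    "parcellate",
    "overlap_map",
    "OVERLAP_LABELS",
]

OVERLAP_LABELS = {0: "none", 1: "parallel_only", 2: "serial_only", 3: "both"}


@dataclass
class LabelReport:
    table: pd.DataFrame  # columns: label, r; sorted by descending r
    mask: np.ndarray

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["label"])

    def r_of(self, label: str) -> float:
        return float(self.table.set_index("label").loc[label, "r"])


def spatial_correlation(
    stat_map: StatMap, templates: TemplateSet, min_overlap: int = 10
) -> LabelReport:
    """Pearson r between the statistic map and each template weight map.

    Computed over the intersection of the map mask and template mask;
    positive affine transforms of the map leave every r unchanged.
    """
    if stat_map.values.shape != templates.mask.shape:
        raise ValueError("map and templates must share the grid")
    mask = stat_map.mask & templates.mask
    n = int(mask.sum())
    if n < min_overlap:
        raise ValueError(f"mask overlap {n} below minimum {min_overlap}")
    x = stat_map.values[mask]
    if x.std() == 0:
        raise ValueError("statistic map has zero variance within mask")
    rows = []
    for label, tmpl in zip(templates.labels, templates.maps):
        y = tmpl[mask]
        if y.std() == 0:
            raise ValueError(f"template {label!r} has zero variance within mask")
        rows.append({"label": label, "r": float(np.corrcoef(x, y)[0, 1])})
    table = (
        pd.DataFrame(rows)
        .sort_values("r", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return LabelReport(table, mask)


def parcellate(
    stat_map: StatMap,
    atlas: list[np.ndarray],
    labels: list[str] | None = None,
    p_thresh: float = 0.25,
) -> pd.DataFrame:
    """Count supra-threshold map voxels per atlas region.

    Each probabilistic region map is binarized at probability >=
    ``p_thresh``; the table reports, per region, the number of nonzero
    map voxels inside it and the peak statistic there.
    """
    labels = labels or [f"region_{i:02d}" for i in range(len(atlas))]
    active = stat_map.values != 0
    any_region = False
    rows = []
    for label, prob in zip(labels, atlas):
        if prob.shape != stat_map.values.shape:
            raise ValueError(f"atlas region {label!r} grid mismatch")
        region = prob >= p_thresh
        if region.any():
            any_region = True
        overlap = active & region & stat_map.mask
        count = int(overlap.sum())
        peak = float(stat_map.values[overlap].max()) if count else np.nan
        rows.append({"region": label, "n_voxels": count, "peak_stat": peak})
    if not any_region:
        raise ValueError(f"atlas empty after thresholding at {p_thresh}")
    return pd.DataFrame(rows)


def overlap_map(
    parallel_thr: StatMap, serial_thr: StatMap, conjunction_thr: StatMap
) -> np.ndarray:
    """Tri-color overlap labels on the union of two thresholded maps.

    Conjunction voxels are "both" (3); remaining voxels of each input
    are paradigm-specific (1 parallel, 2 serial); everything else 0.
    """
    for other in (serial_thr, conjunction_thr):
        if parallel_thr.values.shape != other.values.shape:
            raise ValueError("grid mismatch between overlap inputs")
    par = parallel_thr.values != 0
    ser = serial_thr.values != 0
    both = conjunction_thr.values != 0
    out = np.zeros(par.shape, dtype=np.int8)
    out[par | ser | both] = 0  # explicit: labels partition the union
    out[par & ~both] = 1
    out[ser & ~both & ~par] = 2
    out[both] = 3
    return out
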