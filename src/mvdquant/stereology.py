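"""Tumour-stroma percentage (TSP) by systematic point counting.

A square lattice of ~``n_points`` sample points (400 by default,
matching a 20x-objective stereology grid) is laid over the annotated
tumour area with a uniformly random sub-cell offset.  Each point is
scored epithelium / stroma / other, and

    TSP = 100 * stromal hits / (stromal + epithelial hits).

Points on "other" tissue (lumen, mucus, vessels, background) count
toward neither the numerator nor the denominator.  With a random grid
offset the hit fractions are unbiased estimators of the corresponding
area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CLASS_EPITHELIUM, CLASS_STROMA

__all__ = [
    "PointGrid",
    "PointClassification",
    "TSPResult",
    "generate_grid",
    "classify_points",
    "compute_tsp",
    "LABEL_EPITHELIUM",
    "LABEL_STROMA",
    "LABEL_OTHER",
]

LABEL_EPITHELIUM = "epithelium"
LABEL_STROMA = "stroma"
LABEL_OTHER = "other"
_VALID_LABELS = {LABEL_EPITHELIUM, LABEL_STROMA, LABEL_OTHER}


@dataclass
class PointGrid:
    """Systematic sample points inside an analysis mask."""

    points: np.ndarray  # (n, 2) of (x, y) pixel coordinates, float
    n_requested: int
    offset_seed: int
    spacing: float

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PointClassification:
    """Per-point tissue labels aligned with a :class:`PointGrid`."""

    labels: list[str]
    source: str  # "auto_from_class_map" or "manual_table"


@dataclass
class TSPResult:
    tsp_percent: float
    n_stroma: int
    n_epithelium: int
    n_other: int

    def to_dict(self) -> dict:
        return {
            "tsp_percent": self.tsp_percent,
            "n_stroma": self.n_stroma,
            "n_epithelium": self.n_epithelium,
            "n_other": self.n_other,
        }


def generate_grid(
    mask: np.ndarray,
    n_points: int = 400,
    offset_seed: int = 0,
    fixed_origin: bool = False,
) -> PointGrid:
    """Square lattice with random sub-cell offset, restricted to the mask.

    The lattice spacing is chosen so the *expected* number of in-mask
    nodes equals ``n_points``; only nodes whose pixel lies in the mask
    are returned.  ``fixed_origin`` pins the offset to the cell centre
    for reproducing a specific count.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if area == 0:
        raise ValueError("empty analysis mask")
    if area < n_points:
        raise ValueError(
            f"mask has only {area} pixels; cannot support a {n_points}-point grid"
        )
    h, w = mask.shape
    spacing = float(np.sqrt(area / n_points))
    rng = np.random.default_rng(offset_seed)
    if fixed_origin:
        ox = oy = spacing / 2.0
    else:
        ox, oy = rng.uniform(0.0, spacing, size=2)
    xs = np.arange(ox, w, spacing)
    ys = np.arange(oy, h, spacing)
    xx, yy = np.meshgrid(xs, ys)
    cols = np.floor(xx).astype(int).ravel()
    rows = np.floor(yy).astype(int).ravel()
    inside = mask[rows, cols]
    points = np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])
    return PointGrid(points=points, n_requested=n_points, offset_seed=offset_seed, spacing=spacing)


def classify_points(
    grid: PointGrid,
    class_map: np.ndarray | None = None,
    manual_table: pd.DataFrame | None = None,
) -> PointClassification:
    """Score each grid point as epithelium / stroma / other.

    Auto mode reads a class map raster (generator ground truth or any
    supplied segmentation, integer-coded or string-valued); manual mode
    ingests a scored table with a ``label`` column, one row per point in
    grid order.
    """
    if (class_map is None) == (manual_table is None):
        raise ValueError("provide exactly one of class_map or manual_table")
    if manual_table is not None:
        if len(manual_table) != len(grid):
            raise ValueError(
                f"manual table has {len(manual_table)} rows for a {len(grid)}-point grid"
            )
        labels = [str(v) for v in manual_table["label"]]
        bad = [i for i, v in enumerate(labels) if v not in _VALID_LABELS]
        if bad:
            raise ValueError(f"invalid or missing labels at row indices {bad}")
        return PointClassification(labels=labels, source="manual_table")

    class_map = np.asarray(class_map)
    cols = np.floor(grid.points[:, 0]).astype(int)
    rows = np.floor(grid.points[:, 1]).astype(int)
    out_of_bounds = [
        int(i)
        for i in range(len(grid))
        if not (0 <= rows[i] < class_map.shape[0] and 0 <= cols[i] < class_map.shape[1])
    ]
    if out_of_bounds:
        raise ValueError(f"class_map does not cover grid point indices {out_of_bounds}")
    values = class_map[rows, cols]
    if values.dtype.kind in "iu":
        code_to_label = {CLASS_EPITHELIUM: LABEL_EPITHELIUM, CLASS_STROMA: LABEL_STROMA}
        labels = [code_to_label.get(int(v), LABEL_OTHER) for v in values]
    else:
        labels = [str(v) for v in values]
        bad = [i for i, v in enumerate(labels) if v not in _VALID_LABELS]
        if bad:
            raise ValueError(f"class_map yields invalid labels at point indices {bad}")
    return PointClassification(labels=labels, source="auto_from_class_map")


def compute_tsp(classification: PointClassification) -> TSPResult:
    """Stromal hits over epithelial-plus-stromal hits, as a percent."""
    n_str = classification.labels.count(LABEL_STROMA)
    n_epi = classification.labels.count(LABEL_EPITHELIUM)
    n_oth = classification.labels.count(LABEL_OTHER)
    if n_str + n_epi == 0:
        raise ValueError("no informative (epithelium or stroma) hits on the grid")
    return TSPResult(
        tsp_percent=100.0 * n_str / (n_str + n_epi),
        n_stroma=n_str,
        n_epithelium=n_epi,
        n_other=n_oth,
    )
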