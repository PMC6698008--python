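"""Microvessel density (MVD) by positive-pixel morphometry.

Quantifies CD31-stained whole-section images as the percentage of
chromogen-positive *clustered* pixels over the analysed tumour tissue
area.  The pipeline mirrors the particle-analysis style of raster
morphometry:

1. rasterize the tumour delineation (include polygons minus
   damage/exclusion polygons) into a boolean analysis mask;
2. classify DAB-brown positive pixels inside the mask, either by an RGB
   rule or by optical-density projection onto a DAB stain vector;
3. label connected components of the positive mask;
4. discard components below a minimum pixel size (microvessel size
   threshold, default 100 px);
5. report 100 * retained positive pixels / analysed pixels.

Sub-threshold positive pixels are excluded from the numerator but stay
in the denominator: the denominator is *all* analysed tissue pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "AnnotatedSlide",
    "StainClassifierConfig",
    "ComponentSet",
    "MVDResult",
    "rasterize_annotation",
    "polygons_to_mask",
    "classify_positive_pixels",
    "label_components",
    "filter_components",
    "compute_mvd",
    "quantify_image",
    "quantify_slide",
    "DEFAULT_MIN_COMPONENT_PX",
]

#: Minimum microvessel size in pixels ("minimal hundred CD31-positive pixels").
DEFAULT_MIN_COMPONENT_PX = 100


@dataclass
class AnnotatedSlide:
    """An RGB section image with tumour delineation annotations.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 RGB pixel array.
    include_polygons
        Tumour delineations, each an ``(n, 2)`` array of ``(x, y)``
        vertices in 0-based pixel coordinates.
    exclude_polygons
        Damaged / tissue-absent regions to subtract from the analysis
        area.
    pixel_size_um
        Physical pixel edge length in micrometres (0.23 um at a typical
        20x scan).  Carried through for provenance; the MVD statistic is
        an area fraction and does not use it.
    """

    image: np.ndarray
    include_polygons: Sequence[np.ndarray]
    exclude_polygons: Sequence[np.ndarray] = field(default_factory=list)
    pixel_size_um: float = 0.23

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be an (H, W, 3) RGB array")
        if self.image.shape[0] == 0 or self.image.shape[1] == 0:
            raise ValueError("image must be non-empty")
        self.include_polygons = [np.asarray(p, dtype=float) for p in self.include_polygons]
        self.exclude_polygons = [np.asarray(p, dtype=float) for p in self.exclude_polygons]
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class StainClassifierConfig:
    """Positive-pixel (DAB brown) classifier configuration.

    ``rgb_rule`` mode flags a pixel positive when all of

    * ``R >= min_red``
    * ``R - B >= min_red_minus_blue``
    * ``R - G >= min_red_minus_green``

    hold; this captures the brown chromogen against the blue-purple
    hematoxylin counterstain and pink eosin-like stroma.

    ``stain_deconvolution`` mode converts pixels to optical density and
    projects onto a unit DAB stain vector; pixels with projected OD at or
    above ``od_threshold`` are positive.
    """

    mode: Literal["rgb_rule", "stain_deconvolution"] = "rgb_rule"
    min_red: int = 100
    min_red_minus_blue: int = 60
    min_red_minus_green: int = 20
    # Ruifrok-Johnston style DAB optical-density direction.
    dab_vector: tuple[float, float, float] = (0.268, 0.570, 0.776)
    od_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.mode not in ("rgb_rule", "stain_deconvolution"):
            raise ValueError(f"unknown classifier mode {self.mode!r}")
        for name in ("min_red", "min_red_minus_blue", "min_red_minus_green"):
            v = getattr(self, name)
            if not -255 <= v <= 255:
                raise ValueError(f"{name}={v} outside valid channel-difference range")
        if self.od_threshold <= 0:
            raise ValueError("od_threshold must be positive")
        if not np.any(self.dab_vector):
            raise ValueError("dab_vector must be non-zero")


@dataclass
class ComponentSet:
    """Connected components of a positive-pixel mask."""

    label_map: np.ndarray  # int array, 0 = background, labels 1..n contiguous
    sizes: dict[int, int]
    connectivity: int  # 4 or 8

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    @property
    def total_pixels(self) -> int:
        return int(sum(self.sizes.values()))


@dataclass
class MVDResult:
    """Percent positive clustered pixels over analysed tissue area."""

    mvd_percent: float
    n_components: int
    positive_pixels: int
    analysed_pixels: int
    min_component_px: int

    def to_dict(self) -> dict:
        return {
            "mvd_percent": self.mvd_percent,
            "n_components": self.n_components,
            "positive_pixels": self.positive_pixels,
            "analysed_pixels": self.analysed_pixels,
            "min_component_px": self.min_component_px,
        }


def polygons_to_mask(
    polygons: Sequence[np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a union of polygons onto a pixel grid.

    A pixel (row r, col c) is inside if its centre ``(c + 0.5, r + 0.5)``
    lies inside the (even-odd filled) polygon union.  Polygons extending
    past the image bounds are effectively clipped by the grid.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    geoms = []
    for p in polygons:
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise ValueError("each polygon must be an (n>=3, 2) array of (x, y)")
        poly = Polygon(p)
        if not poly.is_valid:
            poly = poly.buffer(0)  # even-odd style repair of self-touching rings
        if not poly.is_empty:
            geoms.append(poly)
    if not geoms:
        return mask
    union = unary_union(geoms)
    minx, miny, maxx, maxy = union.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), w)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), h)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xx, yy = np.meshgrid(cols + 0.5, rows + 0.5)
    inside = shapely.contains_xy(union, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def rasterize_annotation(slide: AnnotatedSlide) -> np.ndarray:
    """Boolean analysis mask: union(include) minus union(exclude).

    Raises
    ------
    ValueError
        If no include polygon is given or the resulting mask is empty
        ("no analysable tissue").
    """
    if len(slide.include_polygons) == 0:
        raise ValueError("at least one include polygon is required")
    shape = slide.image.shape[:2]
    mask = polygons_to_mask(slide.include_polygons, shape)
    if slide.exclude_polygons:
        mask &= ~polygons_to_mask(slide.exclude_polygons, shape)
    if not mask.any():
        raise ValueError("no analysable tissue: analysis mask is empty")
    return mask


def classify_positive_pixels(
    image: np.ndarray,
    mask: np.ndarray,
    config: StainClassifierConfig | None = None,
) -> np.ndarray:
    """Flag chromogen-positive (DAB brown) pixels inside the analysis mask.

    Pure function of pixel values and config; the returned mask is a
    subset of ``mask``.  An all-negative result is valid (no chromogen).
    """
    config = config or StainClassifierConfig()
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image")
    if config.mode == "rgb_rule":
        rgb = image.astype(np.int16)
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        positive = (
            (r >= config.min_red)
            & (r - b >= config.min_red_minus_blue)
            & (r - g >= config.min_red_minus_green)
        )
    else:  # stain_deconvolution
        od = -np.log10((image.astype(np.float64) + 1.0) / 256.0)
        v = np.asarray(config.dab_vector, dtype=np.float64)
        v = v / np.linalg.norm(v)
        positive = od @ v >= config.od_threshold
    return positive & mask


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def label_components(positive_mask: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """Label maximal connected clusters of positive pixels.

    ``connectivity`` 4 uses edge adjacency only; 8 (default) also joins
    diagonal neighbours, matching common particle-analysis behaviour.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    label_map, n = ndimage.label(np.asarray(positive_mask, dtype=bool), structure=structure)
    counts = np.bincount(label_map.ravel(), minlength=n + 1)
    sizes = {int(k): int(counts[k]) for k in range(1, n + 1)}
    return ComponentSet(label_map=label_map, sizes=sizes, connectivity=connectivity)


def filter_components(
    components: ComponentSet, min_pixels: int = DEFAULT_MIN_COMPONENT_PX
) -> ComponentSet:
    """Drop components smaller than ``min_pixels``; relabel 1..k.

    Components with size >= ``min_pixels`` are retained ("minimal
    hundred" read as an inclusive bound); removed components vanish from
    the label map entirely.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    keep = sorted(k for k, s in components.sizes.items() if s >= min_pixels)
    if len(keep) == len(components.sizes):
        return ComponentSet(
            label_map=components.label_map.copy(),
            sizes=dict(components.sizes),
            connectivity=components.connectivity,
        )
    n_old = len(components.sizes)
    remap = np.zeros(n_old + 1, dtype=components.label_map.dtype)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    label_map = remap[components.label_map]
    sizes = {new: components.sizes[old] for new, old in enumerate(keep, start=1)}
    return ComponentSet(label_map=label_map, sizes=sizes, connectivity=components.connectivity)


def compute_mvd(
    filtered: ComponentSet,
    analysed_pixels: int,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> MVDResult:
    """MVD percent = 100 * retained positive pixels / analysed pixels."""
    if analysed_pixels < 1:
        raise ValueError("analysed_pixels must be >= 1")
    positive = filtered.total_pixels
    if positive > analysed_pixels:
        raise ValueError("positive pixels exceed analysed pixels")
    return MVDResult(
        mvd_percent=100.0 * positive / analysed_pixels,
        n_components=filtered.n_components,
        positive_pixels=positive,
        analysed_pixels=int(analysed_pixels),
        min_component_px=min_component_px,
    )


def quantify_image(
    image: np.ndarray,
    analysis_mask: np.ndarray,
    config: StainClassifierConfig | None = None,
    min_pixels: int = DEFAULT_MIN_COMPONENT_PX,
    connectivity: int = 8,
) -> MVDResult:
    """Run classify -> label -> size-filter -> percent on a masked image."""
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    analysed = int(analysis_mask.sum())
    if analysed == 0:
        raise ValueError("no analysable tissue: analysis mask is empty")
    positive = classify_positive_pixels(image, analysis_mask, config)
    components = label_components(positive, connectivity=connectivity)
    filtered = filter_components(components, min_pixels=min_pixels)
    return compute_mvd(filtered, analysed, min_component_px=min_pixels)


def quantify_slide(
    slide: AnnotatedSlide,
    config: StainClassifierConfig | None = None,
    min_pixels: int = DEFAULT_MIN_COMPONENT_PX,
    connectivity: int = 8,
) -> MVDResult:
    """Full pipeline on an annotated slide: rasterize then quantify."""
    mask = rasterize_annotation(slide)
    return quantify_image(
        slide.image, mask, config=config, min_pixels=min_pixels, connectivity=connectivity
    )
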