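"""Disk formats: TIFF/PNG rasters, GeoJSON annotations, CSV/JSON tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import SyntheticSlide, SyntheticTruth

__all__ = [
    "write_slide",
    "read_image",
    "read_mask_png",
    "write_mask_png",
    "read_annotations",
    "write_annotations",
    "write_cohort",
    "read_cohort",
    "write_json",
]


def write_json(obj: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_mask_png(mask: np.ndarray, path: Path | str) -> None:
    """Boolean or small-integer mask as single-channel 8-bit PNG."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.max(initial=0) > 255:
        raise ValueError("mask values exceed 8-bit range")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_mask_png(path: Path | str, boolean: bool = True) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0 if boolean else arr


def read_image(path: Path | str) -> np.ndarray:
    """RGB image from TIFF or PNG as (H, W, 3) uint8."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path} is not an RGB image")
    return np.ascontiguousarray(arr[..., :3])


def write_annotations(
    include_polygons, exclude_polygons, path: Path | str
) -> None:
    """GeoJSON FeatureCollection of pixel-coordinate polygons.

    Each feature carries a ``role`` property, ``include`` or ``exclude``.
    """
    features = []
    for role, polys in (("include", include_polygons), ("exclude", exclude_polygons)):
        for p in polys:
            ring = [[float(x), float(y)] for x, y in np.asarray(p)]
            if ring[0] != ring[-1]:
                ring.append(ring[0])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"role": role},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    write_json({"type": "FeatureCollection", "features": features}, path)


def read_annotations(path: Path | str) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Include/exclude polygon lists from a GeoJSON annotation file."""
    data = json.loads(Path(path).read_text())
    include, exclude = [], []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        role = feat.get("properties", {}).get("role", "include")
        (include if role == "include" else exclude).append(ring)
    return include, exclude


def write_slide(slide: SyntheticSlide, outdir: Path | str) -> Path:
    """Slide image plus sidecar ground truth.

    Layout: ``image.tif`` (deflate-compressed RGB), ``tissue_mask.png``,
    ``excluded_mask.png``, ``class_map.png``, ``vessel_labels.png``
    (16-bit), ``annotations.geojson``, ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "image.tif", slide.image, compression="deflate")
    write_mask_png(slide.tissue_mask, outdir / "tissue_mask.png")
    write_mask_png(slide.excluded_mask, outdir / "excluded_mask.png")
    write_mask_png(slide.class_map, outdir / "class_map.png")
    labels = slide.vessel_label_map
    if labels.max(initial=0) > 65535:
        raise ValueError("too many vessels for 16-bit label PNG")
    Image.fromarray(labels.astype(np.uint16)).save(outdir / "vessel_labels.png")
    if slide.spec is not None:
        write_annotations([slide.spec.tissue_polygon], [], outdir / "annotations.geojson")
    t = slide.truth
    write_json(
        {
            "positive_fraction": t.positive_fraction,
            "vessel_pixel_counts": t.vessel_pixel_counts,
            "stroma_fraction": t.stroma_fraction,
        },
        outdir / "truth.json",
    )
    return outdir


def load_truth(slide_dir: Path | str) -> SyntheticTruth:
    d = json.loads((Path(slide_dir) / "truth.json").read_text())
    return SyntheticTruth(
        positive_fraction=d["positive_fraction"],
        vessel_pixel_counts=d["vessel_pixel_counts"],
        stroma_fraction=d["stroma_fraction"],
    )


def write_cohort(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)
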