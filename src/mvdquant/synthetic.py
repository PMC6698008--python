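"""Synthetic slides and cohorts with exact ground truth.

Two simulators back the validation of the whole pipeline:

* :func:`generate_slide` paints chromogen-brown vessel objects (ellipses
  and lumen-bearing annuli with jittered boundaries) of a controlled
  total area fraction onto a tissue-coloured background, and returns the
  image together with pixel-exact ground-truth masks (tissue, exclusion,
  per-vessel labels, epithelium/stroma class map).

* :func:`generate_cohort` draws two-stage patient cohorts with binary
  clinicopathological covariates at configurable prevalences and
  disease-free survival from an exponential proportional-hazards model
  with configurable log hazard ratios and censoring.

The generators are deterministic given their seed, and every derived
truth quantity (positive-pixel fraction, stroma fraction, per-vessel
pixel counts) is recomputed from the emitted arrays, never from the
nominal parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .morphometry import polygons_to_mask

__all__ = [
    "CLASS_OTHER",
    "CLASS_EPITHELIUM",
    "CLASS_STROMA",
    "SlideSpec",
    "SyntheticTruth",
    "SyntheticSlide",
    "CohortSpec",
    "generate_slide",
    "inject_excluded_regions",
    "generate_cohort",
    "COHORT_COLUMNS",
]

# class_map codes
CLASS_OTHER = 0
CLASS_EPITHELIUM = 1
CLASS_STROMA = 2

#: cohort CSV schema, in column order
COHORT_COLUMNS = [
    "patient_id",
    "stage",
    "age",
    "sex",
    "right_sided",
    "diameter_mm",
    "grade",
    "ulceration",
    "angioinvasion",
    "mucinous",
    "mvd_percent",
    "tsp_percent",
    "hif1a_score",
    "vegfa_score",
    "dfs_months",
    "dfs_event",
]


def _default_background_colors() -> dict:
    # hematoxylin-purple epithelium, eosin-pink stroma, near-white lumen
    return {
        "epithelium": (150, 120, 190),
        "stroma": (235, 195, 215),
        "lumen": (245, 245, 245),
    }


@dataclass
class SlideSpec:
    """Parameters of a synthetic CD31-stained section.

    The default pixel size (0.23 um) matches a 20x whole-slide scan.
    ``target_positive_fraction`` is the fraction of analysed tissue
    pixels to be covered by vessel (DAB-brown) objects; the generator
    hits it to within 0.5 percentage points by resizing the last vessel.
    """

    width_px: int = 1000
    height_px: int = 1000
    pixel_size_um: float = 0.23
    tissue_polygon: np.ndarray | None = None  # (n, 2) of (x, y); default = inset frame
    target_positive_fraction: float = 0.05
    vessel_count: int = 30
    vessel_size_range_px: tuple[int, int] = (100, 2000)
    positive_color: tuple[int, int, int] = (150, 90, 40)
    background_colors: dict = field(default_factory=_default_background_colors)
    noise_sd: float = 8.0
    excluded_fraction: float = 0.0
    stroma_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.vessel_size_range_px
        if not (0 < lo <= hi):
            raise ValueError("vessel_size_range_px must satisfy 0 < min <= max")
        if not 0.0 <= self.target_positive_fraction <= 1.0:
            raise ValueError("target_positive_fraction must be in [0, 1]")
        if not 0.0 <= self.excluded_fraction < 1.0:
            raise ValueError("excluded_fraction must be in [0, 1)")
        if not 0.0 <= self.stroma_fraction <= 1.0:
            raise ValueError("stroma_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be non-negative")
        colors = [self.positive_color, *self.background_colors.values()]
        for c in colors:
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"RGB components must lie in [0, 255]: {c}")
        if self.tissue_polygon is None:
            m = 0.02
            w, h = self.width_px, self.height_px
            self.tissue_polygon = np.array(
                [
                    (m * w, m * h),
                    ((1 - m) * w, m * h),
                    ((1 - m) * w, (1 - m) * h),
                    (m * w, (1 - m) * h),
                ]
            )
        else:
            self.tissue_polygon = np.asarray(self.tissue_polygon, dtype=float)
        # achievability of the target, from polygon area.  Sampled vessel
        # sizes are scaled toward the target (the size range is a shape
        # prior, and the last vessel is resized to close any gap), so only
        # clearly impossible configurations are rejected.
        x, y = self.tissue_polygon[:, 0], self.tissue_polygon[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        target_px = self.target_positive_fraction * area
        if self.vessel_count == 0 and target_px >= 1.0:
            raise ValueError("target_positive_fraction > 0 requires vessel_count > 0")
        if self.target_positive_fraction > 0.35:
            raise ValueError(
                "target_positive_fraction > 0.35 violates the non-contact "
                "vessel packing bound"
            )
        if self.vessel_count > 0:
            mean_area = target_px / self.vessel_count
            if mean_area > 50 * hi:
                raise ValueError(
                    f"target of ~{target_px:.0f} positive px needs a mean vessel "
                    f"area of {mean_area:.0f} px, more than 50x the configured "
                    f"max size {hi}; raise vessel_count or max size"
                )


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for recovery tests."""

    positive_fraction: float = 0.0
    vessel_pixel_counts: list[int] = field(default_factory=list)
    stroma_fraction: float = 0.0
    cohort_log_hrs: dict = field(default_factory=dict)
    censor_rate: float = 0.0
    mvd_true_cutoffs: dict = field(default_factory=dict)


@dataclass
class SyntheticSlide:
    """A generated slide image plus its pixel-exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    tissue_mask: np.ndarray  # bool
    excluded_mask: np.ndarray  # bool, subset of tissue_mask
    vessel_label_map: np.ndarray  # int32, 0 = background
    class_map: np.ndarray  # uint8, CLASS_* codes
    truth: SyntheticTruth
    spec: SlideSpec | None = None

    @property
    def analysis_mask(self) -> np.ndarray:
        """Tissue minus exclusions: the morphometry denominator."""
        return self.tissue_mask & ~self.excluded_mask


def _vessel_pixels(
    cy: float,
    cx: float,
    area: float,
    kind: str,
    theta: float,
    aspect: float,
    jitter_amp: float,
    jitter_phase: float,
    shape: tuple[int, int],
    inner_scale: float = 0.55,
    lobes: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) of one jittered ellipse or annulus, clipped to bounds."""
    h, w = shape
    if kind == "annulus":
        fill = 1.0 - inner_scale**2
    else:
        fill = 1.0
    a = np.sqrt(max(area, 1.0) / (np.pi * aspect * fill))
    b = aspect * a
    ext = a * (1.0 + jitter_amp) + 1.5
    r0 = max(int(np.floor(cy - ext)), 0)
    r1 = min(int(np.ceil(cy + ext)) + 1, h)
    c0 = max(int(np.floor(cx - ext)), 0)
    c1 = min(int(np.ceil(cx + ext)) + 1, w)
    if r1 <= r0 or c1 <= c0:
        return np.array([], dtype=int), np.array([], dtype=int)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    un, vn = u / a, v / b
    rho = np.hypot(un, vn)
    if jitter_amp > 0:
        phi = np.arctan2(vn, un)
        m = 1.0 + jitter_amp * np.sin(lobes * phi + jitter_phase)
    else:
        m = 1.0
    if kind == "annulus":
        inside = (rho <= m) & (rho > inner_scale * m)
    else:
        inside = rho <= m
    rr, cc = np.nonzero(inside)
    return rr + r0, cc + c0


def _sample_vessel_areas(
    rng: np.random.Generator, count: int, lo: int, hi: int, target_px: int
) -> np.ndarray:
    """Per-vessel nominal areas, scaled toward summing to the target."""
    areas = rng.uniform(lo, hi, size=count)
    total = areas.sum()
    if total > 0 and target_px > 0:
        # scale toward the target; the range acts as a shape prior on the
        # relative size mix, not a hard bound on the scaled areas
        areas *= target_px / total
        np.maximum(areas, 4.0, out=areas)
    return areas


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Render a synthetic CD31 slide with exact pixel bookkeeping.

    Vessels are placed without mutual contact (so each remains a
    distinct 8-connected component); the last vessel's size is chosen by
    bisection so the realized positive fraction lands within 0.5
    percentage points of ``spec.target_positive_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    tissue = polygons_to_mask([spec.tissue_polygon], (h, w))
    tissue_px = int(tissue.sum())
    if tissue_px == 0:
        raise ValueError("tissue polygon rasterizes to an empty mask")
    target_px = int(round(spec.target_positive_fraction * tissue_px))

    label_map = np.zeros((h, w), dtype=np.int32)
    # occupied ∪ its 8-neighbourhood: placements must avoid this to keep
    # separate vessels in separate connected components
    blocked = np.zeros((h, w), dtype=bool)
    tissue_rows, tissue_cols = np.nonzero(tissue)
    counts: list[int] = []

    def _placeable(rr, cc):
        if rr.size == 0:
            return False
        return bool(tissue[rr, cc].all() and not blocked[rr, cc].any())

    def _commit(rr, cc, label):
        label_map[rr, cc] = label
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        r0b, r1b = max(r0 - 1, 0), min(r1 + 1, h)
        c0b, c1b = max(c0 - 1, 0), min(c1 + 1, w)
        local = label_map[r0b:r1b, c0b:c1b] > 0
        blocked[r0b:r1b, c0b:c1b] |= ndimage.binary_dilation(
            local, structure=np.ones((3, 3), dtype=bool)
        )

    n_vessels = spec.vessel_count if target_px > 0 else 0
    lo, hi = spec.vessel_size_range_px
    areas = _sample_vessel_areas(rng, n_vessels, lo, hi, target_px)

    placed_total = 0
    label = 0
    for k in range(max(n_vessels - 1, 0)):
        kind = "annulus" if rng.random() < 0.4 else "ellipse"
        theta = rng.uniform(0, np.pi)
        aspect = rng.uniform(0.5, 1.0)
        jamp = rng.uniform(0.05, 0.15)
        jphase = rng.uniform(0, 2 * np.pi)
        for _ in range(150):
            i = rng.integers(tissue_rows.size)
            rr, cc = _vessel_pixels(
                float(tissue_rows[i]),
                float(tissue_cols[i]),
                areas[k],
                kind,
                theta,
                aspect,
                jamp,
                jphase,
                (h, w),
            )
            if _placeable(rr, cc):
                label += 1
                _commit(rr, cc, label)
                placed_total += rr.size
                counts.append(int(rr.size))
                break
        # a vessel that cannot be placed collision-free is skipped; the
        # final adjustment vessel absorbs the missing area

    remaining = target_px - placed_total
    if n_vessels > 0 and remaining > 0:
        # adjustment vessel: plain disk, pixels clipped to placeable space,
        # area chosen by bisection so the total lands on the target
        i = rng.integers(tissue_rows.size)
        cy, cx = float(tissue_rows[i]), float(tissue_cols[i])

        def _disk_count(area: float) -> tuple[int, np.ndarray, np.ndarray]:
            rr, cc = _vessel_pixels(cy, cx, area, "ellipse", 0.0, 1.0, 0.0, 0.0, (h, w))
            ok = tissue[rr, cc] & ~blocked[rr, cc]
            return int(ok.sum()), rr[ok], cc[ok]

        lo_a, hi_a = 1.0, float(max(remaining * 2, 16))
        while _disk_count(hi_a)[0] < remaining and hi_a < 64 * remaining + 1e6:
            hi_a *= 2.0
        for _ in range(40):
            mid = 0.5 * (lo_a + hi_a)
            if _disk_count(mid)[0] < remaining:
                lo_a = mid
            else:
                hi_a = mid
        n_fit, rr, cc = _disk_count(hi_a)
        if rr.size:
            label += 1
            _commit(rr, cc, label)
            placed_total += rr.size
            counts.append(int(rr.size))

    # epithelium/stroma class map from a smoothed random field thresholded
    # at the requested stroma quantile within tissue
    class_map = np.full((h, w), CLASS_OTHER, dtype=np.uint8)
    if tissue_px:
        noise_field = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), sigma=max(min(h, w) / 25.0, 2.0)
        )
        thresh = np.quantile(noise_field[tissue], spec.stroma_fraction)
        stroma = tissue & (noise_field <= thresh)
        class_map[tissue] = CLASS_EPITHELIUM
        class_map[stroma] = CLASS_STROMA
    class_map[label_map > 0] = CLASS_OTHER  # vessels are neither epithelium nor stroma

    # render
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_colors["lumen"]
    img[class_map == CLASS_EPITHELIUM] = spec.background_colors["epithelium"]
    img[class_map == CLASS_STROMA] = spec.background_colors["stroma"]
    img[label_map > 0] = spec.positive_color
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    excluded = np.zeros((h, w), dtype=bool)
    truth = _recompute_truth(label_map, tissue, excluded, class_map)
    slide = SyntheticSlide(
        image=image,
        tissue_mask=tissue,
        excluded_mask=excluded,
        vessel_label_map=label_map,
        class_map=class_map,
        truth=truth,
        spec=spec,
    )
    if spec.excluded_fraction > 0:
        slide = inject_excluded_regions(
            slide, spec.excluded_fraction, seed=int(rng.integers(2**31 - 1))
        )
    return slide


def _recompute_truth(
    label_map: np.ndarray,
    tissue: np.ndarray,
    excluded: np.ndarray,
    class_map: np.ndarray,
) -> SyntheticTruth:
    """Exact truth from the emitted arrays over tissue minus exclusions."""
    analysed = tissue & ~excluded
    n_analysed = int(analysed.sum())
    labels = label_map[analysed]
    n_pos = int((labels > 0).sum())
    counts = np.bincount(labels[labels > 0]) if n_pos else np.array([], dtype=int)
    vessel_counts = [int(c) for c in counts if c > 0]
    cls = class_map[analysed]
    n_str = int((cls == CLASS_STROMA).sum())
    n_epi = int((cls == CLASS_EPITHELIUM).sum())
    informative = n_str + n_epi
    return SyntheticTruth(
        positive_fraction=(n_pos / n_analysed) if n_analysed else 0.0,
        vessel_pixel_counts=vessel_counts,
        stroma_fraction=(n_str / informative) if informative else 0.0,
    )


def inject_excluded_regions(
    slide: SyntheticSlide, fraction: float, seed: int = 0
) -> SyntheticSlide:
    """Blank out ~``fraction`` of tissue as damaged/excluded regions.

    Random disks are stamped onto the exclusion mask until the excluded
    share of tissue reaches the requested fraction; the last disk is
    sized to the remaining deficit.  Ground truth is recomputed over the
    reduced denominator.  ``fraction == 0`` returns the slide unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("excluded fraction must be in [0, 1)")
    if fraction == 0.0:
        return slide
    rng = np.random.default_rng(seed)
    h, w = slide.tissue_mask.shape
    tissue_px = int(slide.tissue_mask.sum())
    target = int(round(fraction * tissue_px))
    excluded = slide.excluded_mask.copy()
    rows, cols = np.nonzero(slide.tissue_mask)
    yy, xx = np.mgrid[0:h, 0:w]
    max_r = max(min(h, w) / 12.0, 3.0)
    for _ in range(10_000):
        deficit = target - int((excluded & slide.tissue_mask).sum())
        if deficit <= 0:
            break
        r = min(np.sqrt(deficit / np.pi), max_r)
        i = rng.integers(rows.size)
        disk = (yy - rows[i]) ** 2 + (xx - cols[i]) ** 2 <= r * r
        excluded |= disk & slide.tissue_mask
    truth = _recompute_truth(
        slide.vessel_label_map, slide.tissue_mask, excluded, slide.class_map
    )
    return dataclasses.replace(slide, excluded_mask=excluded, truth=truth)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _default_prevalences() -> dict:
    return {
        "sex": 0.62,
        "right_sided": 0.40,
        "ulceration": 0.80,
        "angioinvasion": 0.25,
        "mucinous": 0.16,
    }


def _default_mvd_distribution() -> dict:
    # log-normal marker distributions; medians follow the stage II / III
    # medians of 5.6% and 11.1% positive tissue area
    return {
        "II": ("lognormal", {"median": 5.6, "sigma": 0.6}),
        "III": ("lognormal", {"median": 11.1, "sigma": 0.5}),
    }


@dataclass
class CohortSpec:
    """Parameters of a simulated two-stage colon-cancer cohort.

    Disease-free survival follows an exponential proportional-hazards
    model: subject hazard = ``baseline_hazard * exp(sum beta_j x_j)``
    per month, with independent exponential censoring tuned so the
    expected censored fraction equals ``censor_rate``, plus an
    administrative cutoff at ``admin_censor_months``.

    ``true_log_hrs`` keys name covariate columns; two special keys are
    understood: ``"mvd_high"`` (indicator of marker above its true
    stage-specific median) and ``"mvd_high:<stage>"`` for a
    stage-restricted effect (e.g. opposite-direction effects by stage).
    """

    n_stage2: int = 53
    n_stage3: int = 54
    covariate_prevalences: dict = field(default_factory=_default_prevalences)
    mvd_distribution: dict = field(default_factory=_default_mvd_distribution)
    true_log_hrs: dict = field(default_factory=dict)
    baseline_hazard: float = 0.007
    admin_censor_months: float = 120.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stage2 < 0 or self.n_stage3 < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must lie in [0, 1]")


def _draw_marker(rng, family: str, params: dict, n: int) -> tuple[np.ndarray, float]:
    """Continuous marker draw; returns values and the true median."""
    if family == "lognormal":
        med, sigma = params["median"], params["sigma"]
        return med * np.exp(rng.normal(0.0, sigma, n)), float(med)
    if family == "normal":
        mean, sd = params["mean"], params["sd"]
        return np.maximum(rng.normal(mean, sd, n), 0.0), float(mean)
    raise ValueError(f"unknown marker distribution family {family!r}")


def _tma_scores(rng, n: int, missing_core_p: float = 0.05) -> np.ndarray:
    """Patient-level mean of up to six ordinal (0-3) core intensities."""
    latent = rng.uniform(0.0, 3.0, n)
    cores = np.clip(
        np.rint(latent[:, None] + rng.normal(0.0, 0.6, (n, 6))), 0, 3
    )
    missing = rng.random((n, 6)) < missing_core_p
    cores = np.where(missing, np.nan, cores)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(cores, axis=1)
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a two-stage cohort with proportional-hazards DFS.

    Returns the cohort table (schema :data:`COHORT_COLUMNS`) and the
    ground truth (log hazard ratios, target censor rate).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stage2 + spec.n_stage3
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
        return empty, SyntheticTruth(
            cohort_log_hrs=dict(spec.true_log_hrs), censor_rate=spec.censor_rate
        )

    stage = np.array(["II"] * spec.n_stage2 + ["III"] * spec.n_stage3)
    df = pd.DataFrame({"patient_id": np.arange(1, n + 1), "stage": stage})
    age_mean = np.where(stage == "II", 72.7, 65.5)
    age_sd = np.where(stage == "II", 12.3, 10.0)
    df["age"] = np.round(rng.normal(age_mean, age_sd), 1)
    for name, p in spec.covariate_prevalences.items():
        df[name] = (rng.random(n) < p).astype(int)
    df["diameter_mm"] = np.round(np.clip(rng.normal(37.0, 16.0, n), 5.0, 150.0), 1)
    df["grade"] = rng.choice(["good", "average", "poor"], size=n, p=[0.07, 0.86, 0.07])

    mvd = np.empty(n)
    cutoffs: dict[str, float] = {}
    for s in ("II", "III"):
        idx = stage == s
        family, params = spec.mvd_distribution[s]
        vals, med = _draw_marker(rng, family, params, int(idx.sum()))
        mvd[idx] = vals
        cutoffs[s] = med
    df["mvd_percent"] = np.round(mvd, 2)
    df["tsp_percent"] = np.round(np.clip(rng.normal(46.0, 16.0, n), 2.0, 95.0), 1)
    df["hif1a_score"] = np.round(_tma_scores(rng, n), 3)
    df["vegfa_score"] = np.round(_tma_scores(rng, n), 3)

    mvd_high = (mvd > np.array([cutoffs[s] for s in stage])).astype(float)
    lp = np.zeros(n)
    for name, beta in spec.true_log_hrs.items():
        if name == "mvd_high":
            x = mvd_high
        elif name.startswith("mvd_high:"):
            s = name.split(":", 1)[1]
            x = mvd_high * (stage == s)
        elif name == "stage_iii":
            x = (stage == "III").astype(float)
        elif name in df.columns:
            x = df[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"true_log_hrs names unknown covariate {name!r}")
        lp += beta * x

    rates = spec.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        # exponential censor rate c with mean(c / (c + rate_i)) = censor_rate
        def deficit(c: float) -> float:
            return float(np.mean(c / (c + rates))) - spec.censor_rate

        c = brentq(deficit, 1e-12, 1e6)
        censor_time = np.minimum(rng.exponential(1.0 / c, n), spec.admin_censor_months)
    else:
        censor_time = np.full(n, spec.admin_censor_months)
    dfs = np.minimum(event_time, censor_time)
    df["dfs_months"] = np.round(dfs, 2)
    df["dfs_event"] = (event_time <= censor_time).astype(int)

    df = df[[c for c in COHORT_COLUMNS]]
    truth = SyntheticTruth(
        cohort_log_hrs=dict(spec.true_log_hrs),
        censor_rate=spec.censor_rate,
        mvd_true_cutoffs=cutoffs,
    )
    return df, truth
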