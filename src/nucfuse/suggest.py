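"""Bootstrapped nucleus suggestions from an H&E FOV and a region mask.

Pipeline: (i) Macenko stain unmixing into hematoxylin/eosin optical-density
maps; (ii) Gaussian smoothing + global Otsu per region class (sigma 2 px in
lymphocyte-rich regions, 5 px elsewhere); (iii) 8-connected components;
(iv) Euclidean distance transform with peak local maxima at min distance 10
as markers; (v) marker-controlled watershed to split touching nuclei;
(vi) removal of objects under 300 px^2.  Each surviving object inherits a
noisy class from the region it sits in, with a spindle-shape rule telling
fibroblasts apart from sTILs inside stroma.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, regionprops
from skimage.segmentation import watershed

from .core import BoundingBox, ClassTaxonomy, RegionMask

logger = logging.getLogger(__name__)

__all__ = [
    "SuggestConfig",
    "StainDensities",
    "macenko_unmix",
    "segment_nuclei",
    "shape_features",
    "assign_bootstrap_class",
    "is_spindle",
    "suggest_nuclei",
    "stratified_fov_sample",
]

#: region classes whose nuclei are small and densely packed
LYMPH_RICH_REGIONS = frozenset({"lymphocytic_infiltrate", "plasmacytic_infiltrate"})

#: predominant cell type per region class
REGION_TO_CLASS = {
    "tumor": "tumor",
    "stroma": "fibroblast",            # subject to the spindle-shape rule
    "lymphocytic_infiltrate": "lymphocyte",
    "plasmacytic_infiltrate": "plasma_cell",
    "necrosis_debris": "other",
    "other": "other",
}


@dataclass(frozen=True)
class SuggestConfig:
    smooth_sigma_lymph: float = 2.0
    smooth_sigma_other: float = 5.0
    peak_min_distance: int = 10
    min_area: int = 300
    fibroblast_ar_low: float = 0.4
    fibroblast_ar_high: float = 0.55
    fibroblast_circ_low: float = 0.7
    fibroblast_circ_high: float = 0.8
    stromal_fallback_class: str = "lymphocyte"
    #: if True, the smoothing parameters are variances and converted to sigma
    sigma_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.fibroblast_ar_low >= self.fibroblast_ar_high:
            raise ValueError("fibroblast aspect-ratio band is empty")
        if self.fibroblast_circ_low >= self.fibroblast_circ_high:
            raise ValueError("fibroblast circularity band is empty")
        for name in ("smooth_sigma_lymph", "smooth_sigma_other",
                     "peak_min_distance", "min_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def sigma(self, lymph_rich: bool) -> float:
        s = self.smooth_sigma_lymph if lymph_rich else self.smooth_sigma_other
        return math.sqrt(s) if self.sigma_is_variance else float(s)


@dataclass
class StainDensities:
    hematoxylin: np.ndarray
    eosin: np.ndarray
    stain_matrix: np.ndarray  # 3x2, unit columns in OD space


def _rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    return -np.log((rgb.astype(float) + 1.0) / 256.0)


def macenko_unmix(
    rgb_image: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
) -> StainDensities:
    """Macenko stain unmixing of an 8-bit RGB H&E image.

    Tissue pixels (OD magnitude above ``od_threshold``) are projected onto
    the top-2 singular plane of their OD vectors; the robust extreme angles
    (``angle_percentile`` and its complement) define the two stain vectors.
    Hematoxylin is the column with the lower blue/red OD ratio.  Pixel
    concentrations come from least squares on the full image, clipped >= 0.
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    od = _rgb_to_od(rgb).reshape(-1, 3)
    tissue = od[np.linalg.norm(od, axis=1) > od_threshold]
    if tissue.shape[0] < 100:
        raise ValueError("insufficient tissue: image is nearly all background")
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    plane = vt[:2]  # (2, 3)
    # orient basis vectors to make projections predominantly positive
    proj = tissue @ plane.T
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[k] = -plane[k]
            proj[:, k] = -proj[:, k]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    v1 = np.array([math.cos(lo), math.sin(lo)]) @ plane
    v2 = np.array([math.cos(hi), math.sin(hi)]) @ plane
    v1 = np.clip(v1, 0, None)
    v2 = np.clip(v2, 0, None)
    v1 /= np.linalg.norm(v1) or 1.0
    v2 /= np.linalg.norm(v2) or 1.0
    # hematoxylin absorbs strongly in red/green -> low blue/red OD ratio
    r1 = v1[2] / max(v1[0], 1e-12)
    r2 = v2[2] / max(v2[0], 1e-12)
    h_vec, e_vec = (v1, v2) if r1 <= r2 else (v2, v1)
    M = np.column_stack([h_vec, e_vec])
    conc, *_ = np.linalg.lstsq(M, od.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    h, w = rgb.shape[:2]
    return StainDensities(
        hematoxylin=conc[0].reshape(h, w),
        eosin=conc[1].reshape(h, w),
        stain_matrix=M,
    )


def segment_nuclei(
    hematoxylin: np.ndarray,
    region_mask: RegionMask,
    config: SuggestConfig | None = None,
) -> np.ndarray:
    """Watershed nucleus segmentation of a hematoxylin density map.

    Per region class: Gaussian smoothing (sigma 2 px for lymphocyte-rich
    regions, 5 px elsewhere) then a global Otsu threshold computed within
    that region's pixels only.  The pooled foreground is split by
    8-connected labeling, then by marker-controlled watershed on the
    negative distance transform with peak local maxima (min distance 10) as
    markers.  Objects under ``min_area`` are removed and labels compacted to
    consecutive positive integers.
    """
    config = config or SuggestConfig()
    hema = np.asarray(hematoxylin, dtype=float)
    if hema.shape != region_mask.shape:
        raise ValueError("hematoxylin map and region mask shapes differ")

    smoothed_lymph = gaussian(hema, sigma=config.sigma(True), preserve_range=True)
    smoothed_other = gaussian(hema, sigma=config.sigma(False), preserve_range=True)

    foreground = np.zeros(hema.shape, dtype=bool)
    for code, region_name in region_mask.legend.items():
        region = region_mask.labels == code
        if not region.any():
            continue
        lymph_rich = region_name in LYMPH_RICH_REGIONS
        sm = smoothed_lymph if lymph_rich else smoothed_other
        vals = sm[region]
        if np.unique(vals).size < 2:
            logger.info(
                "region %r has <2 distinct intensities; no foreground there",
                region_name,
            )
            continue
        thr = threshold_otsu(vals)
        foreground |= region & (sm > thr)

    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    components, n_comp = ndi.label(foreground, structure=structure)
    if n_comp == 0:
        return np.zeros(hema.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(
        distance,
        min_distance=config.peak_min_distance,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(hema.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    # a flat/small component may yield no peak: seed it at its distance argmax
    has_marker = set(np.unique(components[markers > 0]))
    next_marker = len(peaks) + 1
    for comp in range(1, n_comp + 1):
        if comp in has_marker:
            continue
        comp_mask = components == comp
        flat = np.argmax(np.where(comp_mask, distance, -1.0))
        markers[np.unravel_index(flat, hema.shape)] = next_marker
        next_marker += 1

    labels = watershed(-distance, markers=markers, mask=foreground)

    # area filter + consecutive relabeling
    out = np.zeros(hema.shape, dtype=np.int32)
    next_label = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        if int(m.sum()) < config.min_area:
            continue
        out[m] = next_label
        next_label += 1
    return out


def _boundary_polygon(obj_mask: np.ndarray, offset: tuple[int, int]) -> Polygon:
    padded = np.pad(obj_mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) in padded frame -> (x, y) in image frame
    y = contour[:, 0] - 1 + offset[0]
    x = contour[:, 1] - 1 + offset[1]
    poly = Polygon(zip(x, y))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def shape_features(label_image: np.ndarray) -> pd.DataFrame:
    """Per-object geometry: area, aspect ratio (minor/major ellipse axes),
    circularity 4*pi*A/P^2, tight bounding box and boundary polygon."""
    label_image = np.asarray(label_image)
    rows = []
    for rp in regionprops(label_image):
        area = float(rp.area)
        major = float(rp.axis_major_length)
        minor = float(rp.axis_minor_length)
        ar = (minor / major) if major > 0 else 1.0
        miny, minx, maxy, maxx = rp.bbox
        poly = _boundary_polygon(rp.image, (miny, minx))
        perimeter = float(poly.length) or 1.0
        circ = 4.0 * math.pi * area / perimeter**2
        rows.append(
            {
                "object_id": int(rp.label),
                "area": area,
                "aspect_ratio": ar,
                "circularity": circ,
                "xmin": float(minx),
                "ymin": float(miny),
                "xmax": float(maxx),
                "ymax": float(maxy),
                "boundary": poly,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["object_id", "area", "aspect_ratio", "circularity",
                 "xmin", "ymin", "xmax", "ymax", "boundary"],
    )


def is_spindle(aspect_ratio: float, circularity: float,
               config: SuggestConfig | None = None) -> bool:
    """Spindle-shape test for the stromal fibroblast rule: aspect ratio and
    circularity must both fall inside their closed bands."""
    config = config or SuggestConfig()
    return (
        config.fibroblast_ar_low <= aspect_ratio <= config.fibroblast_ar_high
        and config.fibroblast_circ_low <= circularity <= config.fibroblast_circ_high
    )


def assign_bootstrap_class(
    suggestions: pd.DataFrame,
    label_image: np.ndarray,
    region_mask: RegionMask,
    taxonomy: ClassTaxonomy | None = None,
    config: SuggestConfig | None = None,
) -> pd.DataFrame:
    """Attach region class and bootstrapped nucleus class to each object.

    The object's region is the majority region label under its mask.  The
    region's predominant cell type is assigned directly, except in stroma:
    there an object is a fibroblast iff its shape is spindle-like (aspect
    ratio in [0.4, 0.55] and circularity in [0.7, 0.8], closed bands),
    otherwise the configured stromal fallback class (default lymphocyte,
    since stroma also hosts scattered sTILs).
    """
    config = config or SuggestConfig()
    taxonomy = taxonomy or ClassTaxonomy.default()
    out = suggestions.copy()
    region_classes = []
    suggested = []
    for _, row in out.iterrows():
        m = label_image == row["object_id"]
        codes = region_mask.labels[m]
        majority = int(np.bincount(codes).argmax())
        region_name = region_mask.legend[majority]
        region_classes.append(region_name)
        if region_name == "stroma":
            spindle = is_spindle(row["aspect_ratio"], row["circularity"], config)
            suggested.append("fibroblast" if spindle else config.stromal_fallback_class)
        else:
            suggested.append(REGION_TO_CLASS.get(region_name, "other"))
    out["region_class"] = region_classes
    out["suggested_class"] = suggested
    return out


def suggest_nuclei(
    rgb_image: np.ndarray,
    region_mask: RegionMask,
    taxonomy: ClassTaxonomy | None = None,
    config: SuggestConfig | None = None,
) -> pd.DataFrame:
    """Full suggestion pipeline: unmix -> segment -> features -> class."""
    config = config or SuggestConfig()
    stains = macenko_unmix(rgb_image)
    labels = segment_nuclei(stains.hematoxylin, region_mask, config)
    feats = shape_features(labels)
    return assign_bootstrap_class(feats, labels, region_mask, taxonomy, config)


# ---------------------------------------------------------------------------
# Stratified FOV sampling
# ---------------------------------------------------------------------------

DEFAULT_STRATUM_FRACTIONS = {"single": 0.167, "balanced": 0.167, "discordant": 0.167}


def stratified_fov_sample(
    fov_summaries: pd.DataFrame,
    n_select: int | None = None,
    fractions: Mapping[str, float] | None = None,
    seed: int | None = None,
    dominant_threshold: float = 0.75,
    balance_ratio: float = 0.75,
    difficult_quantile: float = 0.05,
) -> list[str]:
    """Stratified FOV selection favoring informative and difficult fields.

    Strata (by default 16.7% each, remainder ~50% difficult pool):
    ``single`` — one class dominates the suggestions; ``balanced`` — two
    classes nearly equally represented; ``discordant`` — highest
    bootstrap-vs-refined discordance; ``difficult`` — union of the top 5%
    FOVs by low-confidence detections and by extreme-size detections.
    Expected columns: ``fov_id``, per-class count columns ``n_<class>``,
    optional ``discordance``, ``low_confidence``, ``extreme_size``.
    Deterministic for a fixed seed.
    """
    fractions = dict(fractions or DEFAULT_STRATUM_FRACTIONS)
    df = fov_summaries.reset_index(drop=True).copy()
    if "fov_id" not in df.columns:
        raise ValueError("fov_summaries must have a fov_id column")
    n_total = len(df)
    n_select = n_total if n_select is None else min(n_select, n_total)
    rng = np.random.default_rng(seed)

    count_cols = [c for c in df.columns if c.startswith("n_")]
    if not count_cols:
        raise ValueError("fov_summaries needs per-class count columns (n_<class>)")
    counts = df[count_cols].to_numpy(float)
    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0
    shares = np.sort(counts / totals[:, None], axis=1)[:, ::-1]

    # nearest-integer targets for the named strata; the difficult pool
    # absorbs the residual
    targets = {k: int(math.floor(n_select * f + 0.5)) for k, f in fractions.items()}
    n_difficult = n_select - sum(targets.values())

    selected: list[int] = []
    remaining = set(range(n_total))

    def draw(pool: Sequence[int], k: int, stratum: str) -> None:
        pool = [i for i in pool if i in remaining]
        if len(pool) < k:
            logger.warning(
                "stratum %r short: wanted %d FOVs, only %d eligible",
                stratum, k, len(pool),
            )
            k = len(pool)
        chosen = rng.choice(sorted(pool), size=k, replace=False) if k else []
        for i in chosen:
            selected.append(int(i))
            remaining.discard(int(i))

    single_pool = [i for i in range(n_total) if shares[i, 0] >= dominant_threshold]
    draw(single_pool, targets.get("single", 0), "single")

    balanced_pool = [
        i for i in range(n_total)
        if shares[i, 0] < dominant_threshold
        and shares[i, 1] > 0
        and shares[i, 1] / shares[i, 0] >= balance_ratio
    ]
    draw(balanced_pool, targets.get("balanced", 0), "balanced")

    k_disc = targets.get("discordant", 0)
    if "discordance" in df.columns:
        order = [i for i in np.argsort(-df["discordance"].to_numpy(float), kind="stable")
                 if i in remaining]
        for i in order[:k_disc]:
            selected.append(int(i))
            remaining.discard(int(i))
    elif k_disc:
        warnings.warn("no discordance column: discordant stratum drawn uniformly")
        draw(sorted(remaining), k_disc, "discordant")

    have_conf = "low_confidence" in df.columns and "extreme_size" in df.columns
    if have_conf:
        lc = df["low_confidence"].to_numpy(float)
        es = df["extreme_size"].to_numpy(float)
        lc_cut = np.quantile(lc, 1.0 - difficult_quantile)
        es_cut = np.quantile(es, 1.0 - difficult_quantile)
        pool = [i for i in range(n_total) if lc[i] >= lc_cut or es[i] >= es_cut]
        pool = [i for i in pool if i in remaining]
        draw(pool, n_difficult, "difficult")
    else:
        warnings.warn(
            "confidence/size columns absent: difficult pool drawn uniformly"
        )
        draw(sorted(remaining), n_difficult, "difficult")

    # top up any shortfall so exactly n_select FOVs come back when possible
    if len(selected) < n_select and remaining:
        draw(sorted(remaining), n_select - len(selected), "fill")

    return [str(df.loc[i, "fov_id"]) for i in selected]
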