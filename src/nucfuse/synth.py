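"""Synthetic scenes, H&E-like renders and simulated rater crowds.

The generator emulates the statistical structure the fusion pipeline
assumes: fields of view with elliptical ground-truth nuclei of known class,
a region mask consistent with where each class lives (tumor nuclei in tumor
regions, scattered sTILs in stroma), a Beer-Lambert H&E render driven by
per-stain optical densities, and raters with per-class detection
sensitivity, a personal confusion matrix, box-coordinate jitter and an
occasional duplicate annotation (the scenario the do-not-link constraint
exists for).

Default geometry targets 40x-scan scale, where a lymphocyte nucleus spans
roughly 20 pixels across, so that the suggestion pipeline's 300 px^2 area
floor keeps real nuclei.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import ellipse as draw_ellipse

from .core import (
    REGION_CLASSES,
    Annotation,
    BoundingBox,
    ClassTaxonomy,
    ParticipantRecord,
    RegionMask,
)

__all__ = [
    "DEFAULT_STAIN_MATRIX",
    "SceneConfig",
    "RaterModel",
    "NucleusTruth",
    "SyntheticScene",
    "make_scene",
    "render_he",
    "simulate_crowd",
    "simulate_click_matrix",
    "default_rater_models",
    "uniform_confusion",
]

#: Standard H&E optical-density stain vectors (columns: hematoxylin, eosin),
#: unit-normalized.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.650, 0.072],
     [0.704, 0.990],
     [0.286, 0.105]]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(
    DEFAULT_STAIN_MATRIX, axis=0, keepdims=True
)

#: semi-major axis range and aspect-ratio (minor/major) range per class
DEFAULT_GEOMETRY: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "tumor": ((13.0, 19.0), (0.70, 0.95)),
    "fibroblast": ((18.0, 26.0), (0.42, 0.55)),
    "lymphocyte": ((11.0, 13.0), (0.88, 1.00)),
    "plasma_cell": ((12.0, 15.0), (0.75, 0.95)),
    "other": ((12.0, 16.0), (0.60, 0.90)),
}

#: region class each nucleus class predominantly inhabits
HOME_REGION = {
    "tumor": "tumor",
    "fibroblast": "stroma",
    "lymphocyte": "lymphocytic_infiltrate",
    "plasma_cell": "plasmacytic_infiltrate",
    "other": "other",
}


@dataclass(frozen=True)
class SceneConfig:
    fov_shape: tuple[int, int] = (256, 256)          # (height, width)
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "tumor": 6, "fibroblast": 3, "lymphocyte": 8,
            "plasma_cell": 3, "other": 2,
        }
    )
    geometry: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    overlap_fraction: float = 0.1   # share of nuclei forced to touch a neighbor
    min_gap: float = 3.0            # boundary gap enforced for non-touching pairs
    home_region_prob: float = 0.93  # chance a nucleus lands inside its home region
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        for c, n in self.n_per_class.items():
            if n < 0:
                raise ValueError(f"negative nucleus count for {c!r}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NucleusTruth:
    nucleus_id: str
    class_label: str
    cx: float
    cy: float
    semi_major: float
    semi_minor: float
    theta: float  # radians, major-axis orientation
    box: BoundingBox
    polygon: Polygon


@dataclass
class SyntheticScene:
    fov_id: str
    shape: tuple[int, int]
    nuclei: list[NucleusTruth]
    region_mask: RegionMask

    def truth_boxes(self) -> np.ndarray:
        return np.array([n.box.as_tuple() for n in self.nuclei]).reshape(-1, 4)

    def touching_pairs(self) -> int:
        cnt = 0
        for i in range(len(self.nuclei)):
            for j in range(i + 1, len(self.nuclei)):
                if self.nuclei[i].polygon.intersects(self.nuclei[j].polygon):
                    cnt += 1
        return cnt

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": [n.nucleus_id for n in self.nuclei],
                "class": [n.class_label for n in self.nuclei],
                "cx": [n.cx for n in self.nuclei],
                "cy": [n.cy for n in self.nuclei],
                "xmin": [n.box.xmin for n in self.nuclei],
                "ymin": [n.box.ymin for n in self.nuclei],
                "xmax": [n.box.xmax for n in self.nuclei],
                "ymax": [n.box.ymax for n in self.nuclei],
            }
        )


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, theta: float,
                     n_vertices: int = 48) -> Polygon:
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    x = cx + a * np.cos(t) * math.cos(theta) - b * np.sin(t) * math.sin(theta)
    y = cy + a * np.cos(t) * math.sin(theta) + b * np.sin(t) * math.cos(theta)
    return Polygon(zip(x, y))


def _ellipse_box(cx: float, cy: float, a: float, b: float, theta: float,
                 shape: tuple[int, int]) -> BoundingBox:
    hw = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    hh = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    h, w = shape
    xmin = max(0.0, math.floor(cx - hw))
    ymin = max(0.0, math.floor(cy - hh))
    xmax = min(float(w), math.ceil(cx + hw))
    ymax = min(float(h), math.ceil(cy + hh))
    return BoundingBox(xmin, ymin, xmax, ymax)


def _region_layout(config: SceneConfig, rng: np.random.Generator) -> RegionMask:
    """Nearest-seed (Voronoi) partition into region classes.

    Each class present in the scene contributes its home region; stroma is
    always present so sTILs have somewhere to scatter.
    """
    h, w = config.fov_shape
    load: dict[str, int] = {"stroma": 1}
    for c, n in config.n_per_class.items():
        if n > 0:
            load[HOME_REGION[c]] = load.get(HOME_REGION[c], 0) + n
    total_load = sum(load.values())
    region_names = sorted(load, key=REGION_CLASSES.index)
    legend = {i: name for i, name in enumerate(REGION_CLASSES)}
    name_to_int = {v: k for k, v in legend.items()}
    seeds = []
    for name in region_names:
        # seed count tracks how many nuclei must fit in the region
        k = 1 + int(round(8 * load[name] / total_load))
        for _ in range(k):
            seeds.append((rng.uniform(0, h), rng.uniform(0, w), name_to_int[name]))
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.full((h, w), np.inf)
    labels = np.zeros((h, w), dtype=np.int64)
    for sy, sx, code in seeds:
        d = (yy - sy) ** 2 + (xx - sx) ** 2
        closer = d < dist
        dist[closer] = d[closer]
        labels[closer] = code
    return RegionMask(labels, legend)


def make_scene(config: SceneConfig | None = None, seed: int = 0) -> SyntheticScene:
    """Place elliptical nuclei into a region layout; deterministic per seed."""
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    h, w = config.fov_shape
    region_mask = _region_layout(config, rng)
    region_names = region_mask.class_image()

    plan: list[str] = []
    for c in sorted(config.n_per_class):
        plan.extend([c] * config.n_per_class[c])
    rng.shuffle(plan)

    # worst-case footprint check
    est_area = sum(
        math.pi * config.geometry[c][0][1] ** 2 for c in plan
    )
    if est_area > 0.6 * h * w:
        raise ValueError(
            f"infeasible nucleus density: requested ~{est_area:.0f} px^2 "
            f"in a {h}x{w} FOV"
        )

    n_total = len(plan)
    n_touch = int(round(config.overlap_fraction * n_total))
    placed: list[tuple[float, float, float, float, float, str]] = []
    nuclei: list[NucleusTruth] = []

    for k, cls in enumerate(plan):
        (a_lo, a_hi), (ar_lo, ar_hi) = config.geometry[cls]
        a = rng.uniform(a_lo, a_hi)
        b = a * rng.uniform(ar_lo, ar_hi)
        theta = rng.uniform(0, math.pi)
        force_touch = placed and (n_total - k) <= n_touch
        wants_home = rng.random() < config.home_region_prob
        ok = False
        gap = config.min_gap
        for attempt in range(1000):
            if attempt == 400:   # unlucky draw: relax constraints in stages
                force_touch = False
            if attempt == 700:
                gap = config.min_gap / 2.0
                wants_home = False
            if force_touch:
                pi = int(rng.integers(0, len(placed)))
                pcx, pcy, pa, pb, _, _ = placed[pi]
                ang = rng.uniform(0, 2 * math.pi)
                d = 0.9 * (pb + b)  # inside both min-radius circles: must touch
                cx, cy = pcx + d * math.cos(ang), pcy + d * math.sin(ang)
                if not (a < cx < w - a and a < cy < h - a):
                    continue
                # avoid piling onto third parties
                crowded = any(
                    math.hypot(cx - ox, cy - oy) < (a + oa + gap)
                    for oi, (ox, oy, oa, ob, _, _) in enumerate(placed)
                    if oi != pi
                )
                if crowded:
                    continue
                ok = True
                break
            cx = rng.uniform(a + 1, w - a - 1)
            cy = rng.uniform(a + 1, h - a - 1)
            if wants_home and attempt < 300:
                if region_names[int(cy), int(cx)] != HOME_REGION[cls]:
                    continue
            if all(
                math.hypot(cx - ox, cy - oy) >= (a + oa + gap)
                for ox, oy, oa, ob, _, _ in placed
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place nucleus {k} ({cls}); scene too dense for "
                f"fov_shape={config.fov_shape}"
            )
        placed.append((cx, cy, a, b, theta, cls))
        nuclei.append(
            NucleusTruth(
                nucleus_id=f"{config.fov_id}_n{k:04d}",
                class_label=cls,
                cx=cx,
                cy=cy,
                semi_major=a,
                semi_minor=b,
                theta=theta,
                box=_ellipse_box(cx, cy, a, b, theta, config.fov_shape),
                polygon=_ellipse_polygon(cx, cy, a, b, theta),
            )
        )
    return SyntheticScene(config.fov_id, config.fov_shape, nuclei, region_mask)


def stain_density_maps(scene: SyntheticScene,
                       hematoxylin_level: float = 0.9,
                       eosin_level: float = 0.18) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-pixel optical-density concentration maps."""
    h, w = scene.shape
    hema = np.zeros((h, w))
    for n in scene.nuclei:
        rr, cc = draw_ellipse(n.cy, n.cx, n.semi_minor, n.semi_major,
                              shape=(h, w), rotation=-n.theta)
        hema[rr, cc] = hematoxylin_level
    eosin = np.full((h, w), eosin_level) if scene.nuclei else np.zeros((h, w))
    return hema, eosin


def render_he(
    scene: SyntheticScene,
    stain_matrix: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Beer-Lambert forward render: nuclei emit hematoxylin, tissue eosin.

    OD = M @ [c_h; c_e] + Gaussian OD noise; intensity I = 256*exp(-OD) - 1,
    the exact inverse of the unmixing convention OD = -ln((I + 1) / 256).
    """
    M = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix)
    hema, eosin = stain_density_maps(scene)
    conc = np.stack([hema, eosin], axis=-1)  # (h, w, 2)
    od = conc @ M.T                          # (h, w, 3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, od.shape)
    od = np.clip(od, 0.0, None)
    img = np.clip(256.0 * np.exp(-od) - 1.0, 0, 255)
    return img.astype(np.uint8)


def uniform_confusion(classes: Sequence[str], quality: float) -> pd.DataFrame:
    """Row-stochastic confusion with ``quality`` on the diagonal and the
    remainder spread uniformly over the other classes."""
    k = len(classes)
    off = (1.0 - quality) / (k - 1) if k > 1 else 0.0
    m = np.full((k, k), off)
    np.fill_diagonal(m, quality if k > 1 else 1.0)
    return pd.DataFrame(m, index=list(classes), columns=list(classes))


@dataclass
class RaterModel:
    participant_id: str
    tier: str = "NP"
    detection_sensitivity: Mapping[str, float] | float = 0.9
    confusion: pd.DataFrame | None = None  # rows true class, cols emitted
    box_jitter_sd: float = 2.0
    click_propensity: float = 0.9          # P(click | boundary correct)
    click_false_positive: float = 0.1      # P(click | boundary wrong)
    duplicate_rate: float = 0.0

    def sensitivity_for(self, cls: str) -> float:
        if isinstance(self.detection_sensitivity, Mapping):
            return float(self.detection_sensitivity.get(cls, 0.9))
        return float(self.detection_sensitivity)


def _jitter_box(box: BoundingBox, sd: float, shape: tuple[int, int],
                rng: np.random.Generator) -> BoundingBox:
    h, w = shape
    if sd <= 0:
        return box
    for _ in range(20):
        x0, y0, x1, y1 = np.array(box.as_tuple()) + rng.normal(0, sd, 4)
        x0, x1 = np.clip([x0, x1], 0, w)
        y0, y1 = np.clip([y0, y1], 0, h)
        x0, y0 = math.floor(x0), math.floor(y0)
        x1, y1 = math.ceil(x1), math.ceil(y1)
        if x1 > x0 and y1 > y0:
            return BoundingBox(float(x0), float(y0), float(x1), float(y1))
    return box  # jitter kept degenerating the box; fall back to truth


def simulate_crowd(
    scene: SyntheticScene,
    raters: Sequence[RaterModel],
    seed: int = 0,
) -> tuple[list[Annotation], dict[str, ParticipantRecord]]:
    """Simulate independent raters annotating a scene.

    Each rater detects each nucleus with their class-specific sensitivity,
    emits a label from their confusion row, and jitters each box edge
    independently; with probability ``duplicate_rate`` a detected nucleus
    gets a second annotation (fresh jitter and label) from the same rater.
    """
    if not raters:
        raise ValueError("need at least one rater")
    classes = sorted({n.class_label for n in scene.nuclei}) or ["tumor"]
    annotations: list[Annotation] = []
    participants: dict[str, ParticipantRecord] = {}
    master = np.random.SeedSequence(seed)
    for ridx, rater in enumerate(raters):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(ridx,)
        ))
        conf = rater.confusion
        if conf is None:
            conf = uniform_confusion(classes, 0.8)
        count = 0
        for n in scene.nuclei:
            if rng.random() >= rater.sensitivity_for(n.class_label):
                continue
            n_copies = 1 + int(rng.random() < rater.duplicate_rate)
            for _ in range(n_copies):
                if n.class_label in conf.index:
                    row = conf.loc[n.class_label].to_numpy(float)
                    label = str(conf.columns[rng.choice(len(row), p=row / row.sum())])
                else:
                    label = n.class_label
                annotations.append(
                    Annotation(
                        annotation_id=f"{rater.participant_id}_{scene.fov_id}_{count:04d}",
                        participant_id=rater.participant_id,
                        fov_id=scene.fov_id,
                        box=_jitter_box(n.box, rater.box_jitter_sd, scene.shape, rng),
                        raw_class=label,
                        kind="manual_box",
                    )
                )
                count += 1
        participants[rater.participant_id] = ParticipantRecord(
            rater.participant_id, rater.tier, {scene.fov_id}
        )
    return annotations, participants


def simulate_click_matrix(
    truth_correct: Sequence[bool],
    raters: Sequence[RaterModel],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate click/approval votes on algorithmic boundary suggestions.

    Returns the suggestions x raters matrix with entries "clicked" /
    "not_clicked" (NaN where the rater skipped the FOV) plus the ground
    truth as a boolean Series.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth_correct, dtype=bool)
    index = [f"s{i:04d}" for i in range(len(truth))]
    data = {}
    for rater in raters:
        p_click = np.where(truth, rater.click_propensity, rater.click_false_positive)
        votes = np.where(rng.random(len(truth)) < p_click, "clicked", "not_clicked")
        votes = votes.astype(object)
        if missing_rate > 0:
            votes[rng.random(len(truth)) < missing_rate] = np.nan
        data[rater.participant_id] = votes
    return (
        pd.DataFrame(data, index=index),
        pd.Series(truth, index=index, name="boundary_correct"),
    )


def default_rater_models(
    n_np: int = 18,
    n_pathologist: int = 3,
    seed: int = 0,
    classes: Sequence[str] | None = None,
    duplicate_rate: float = 0.02,
) -> list[RaterModel]:
    """A heterogeneous crowd mirroring the reliability structure the fusion
    model assumes: non-pathologists with diagonal quality 0.6-0.9 and lower
    sensitivity for fibroblasts (sparse, lightly stained), pathologists with
    quality 0.85-0.97."""
    classes = list(classes or ClassTaxonomy.default().main_classes)
    factor = {"lymphocyte": 1.0, "plasma_cell": 0.92, "tumor": 0.97,
              "fibroblast": 0.72, "other": 0.85}
    rng = np.random.default_rng(seed)
    raters: list[RaterModel] = []
    for i in range(n_np):
        q = rng.uniform(0.6, 0.9)
        base = rng.uniform(0.78, 0.95)
        sens = {c: min(0.99, base * factor.get(c, 0.9)) for c in classes}
        raters.append(
            RaterModel(
                participant_id=f"NP{i:02d}",
                tier="NP",
                detection_sensitivity=sens,
                confusion=uniform_confusion(classes, q),
                box_jitter_sd=2.0,
                duplicate_rate=duplicate_rate,
            )
        )
    for i in range(n_pathologist):
        q = rng.uniform(0.85, 0.97)
        base = rng.uniform(0.9, 0.98)
        sens = {c: min(0.99, base * max(factor.get(c, 0.9), 0.85)) for c in classes}
        raters.append(
            RaterModel(
                participant_id=f"P{i:02d}",
                tier="senior_pathologist" if i % 2 else "junior_pathologist",
                detection_sensitivity=sens,
                confusion=uniform_confusion(classes, q),
                box_jitter_sd=1.5,
                duplicate_rate=duplicate_rate / 2,
            )
        )
    return raters
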