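"""Domain types, class taxonomy and file I/O shared across the toolkit.

Coordinates are 0-based, half-open pixel intervals: pixel column ``x`` lies
inside a box iff ``xmin <= x < xmax``.  Annotation tables exported by some
viewers use 1-based inclusive coordinates; the readers/writers accept a
``dialect`` flag to convert at the I/O boundary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from shapely import wkt as _shapely_wkt
from shapely.geometry import Polygon

__all__ = [
    "AMBIGUOUS",
    "UNDETECTED",
    "RESERVED_LABELS",
    "REGION_CLASSES",
    "BoundingBox",
    "Annotation",
    "ParticipantRecord",
    "ClassTaxonomy",
    "RegionMask",
    "map_class",
    "read_annotation_table",
    "write_annotation_table",
    "annotations_to_frame",
    "read_region_mask",
    "write_label_mask",
    "read_taxonomy",
]

#: Reserved labels: observable but never a true nucleus class ("ambiguous"),
#: and the pseudo-label for a rater who saw the FOV but placed no box there.
AMBIGUOUS = "ambiguous"
UNDETECTED = "undetected"
RESERVED_LABELS = (AMBIGUOUS, UNDETECTED)

#: Low-power region classes used by the bootstrapped-suggestion pipeline.
REGION_CLASSES = (
    "tumor",
    "stroma",
    "lymphocytic_infiltrate",
    "plasmacytic_infiltrate",
    "necrosis_debris",
    "other",
)

PATHOLOGIST_TIERS = frozenset(
    {"junior_pathologist", "senior_pathologist", "pathologist"}
)
TIERS = ("NP", "junior_pathologist", "senior_pathologist")


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned box in 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class Annotation:
    """One participant's mark on one FOV: a manual box or a click approving
    an algorithmic suggestion (clicks inherit the suggestion's box/boundary)."""

    annotation_id: str
    participant_id: str
    fov_id: str
    box: BoundingBox
    raw_class: str
    kind: str = "manual_box"  # or "click_approval"
    boundary: Polygon | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("manual_box", "click_approval"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")


@dataclass
class ParticipantRecord:
    participant_id: str
    tier: str = "NP"
    fovs_annotated: set[str] = field(default_factory=set)

    @property
    def is_pathologist(self) -> bool:
        return self.tier in PATHOLOGIST_TIERS


class ClassTaxonomy:
    """Two-level grouping of raw nucleus labels into main classes and
    super-classes.

    The default configuration ships five main classes (tumor, fibroblast,
    lymphocyte, plasma_cell, other) grouped into the clinically salient
    super-classes tumor / stromal / sTILs, with "other" kept as its own
    configurable catch-all.  The raw label list is configuration: studies
    differ in how fine-grained their raw vocabulary is.
    """

    def __init__(
        self,
        raw_classes: Sequence[str],
        class_of: Mapping[str, str],
        superclass_of: Mapping[str, str],
    ) -> None:
        self.raw_classes = tuple(raw_classes)
        self.class_of = dict(class_of)
        self.superclass_of = dict(superclass_of)
        for r in self.raw_classes:
            if r in RESERVED_LABELS:
                raise ValueError(f"reserved label {r!r} may not be a raw class")
            if r not in self.class_of:
                raise ValueError(f"raw class {r!r} has no main-class mapping")
        for m in set(self.class_of.values()):
            if m not in self.superclass_of:
                raise ValueError(f"main class {m!r} has no super-class mapping")

    @property
    def main_classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.raw_classes:
            m = self.class_of[r]
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    @property
    def super_classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.main_classes:
            s = self.superclass_of[m]
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def map_label(self, label: str, level: str = "main") -> str:
        if level not in ("raw", "main", "super"):
            raise ValueError(f"unknown level {level!r}")
        if label in RESERVED_LABELS:
            return label
        if label not in self.class_of and label not in self.raw_classes:
            raise KeyError(f"unknown class label {label!r}")
        if level == "raw":
            return label
        main = self.class_of[label]
        if level == "main":
            return main
        return self.superclass_of[main]

    def is_known(self, label: str) -> bool:
        return label in self.raw_classes or label in RESERVED_LABELS

    @classmethod
    def default(cls) -> "ClassTaxonomy":
        mains = ("tumor", "fibroblast", "lymphocyte", "plasma_cell", "other")
        return cls(
            raw_classes=mains,
            class_of={m: m for m in mains},
            superclass_of={
                "tumor": "tumor",
                "fibroblast": "stromal",
                "lymphocyte": "sTILs",
                "plasma_cell": "sTILs",
                "other": "other",
            },
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ClassTaxonomy":
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(cfg["raw_classes"], cfg["class_of"], cfg["superclass_of"])

    def to_dict(self) -> dict:
        return {
            "raw_classes": list(self.raw_classes),
            "class_of": dict(self.class_of),
            "superclass_of": dict(self.superclass_of),
        }


def read_taxonomy(path: str | Path) -> ClassTaxonomy:
    return ClassTaxonomy.from_file(path)


def map_class(label: str, level: str, taxonomy: ClassTaxonomy) -> str:
    """Map a raw label to the requested taxonomy level.

    Reserved labels ("ambiguous", "undetected") pass through unchanged at
    every level.
    """
    return taxonomy.map_label(label, level)


# ---------------------------------------------------------------------------
# Annotation-table I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "annotation_id",
    "participant_id",
    "tier",
    "fov_id",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
    "raw_class",
    "kind",
    "boundary_wkt",
]


def annotations_to_frame(
    annotations: Iterable[Annotation],
    participants: Mapping[str, ParticipantRecord] | None = None,
) -> pd.DataFrame:
    rows = []
    for a in annotations:
        tier = "NP"
        if participants is not None and a.participant_id in participants:
            tier = participants[a.participant_id].tier
        rows.append(
            {
                "annotation_id": a.annotation_id,
                "participant_id": a.participant_id,
                "tier": tier,
                "fov_id": a.fov_id,
                "xmin": a.box.xmin,
                "ymin": a.box.ymin,
                "xmax": a.box.xmax,
                "ymax": a.box.ymax,
                "raw_class": a.raw_class,
                "kind": a.kind,
                "boundary_wkt": a.boundary.wkt if a.boundary is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_table(
    annotations: Iterable[Annotation],
    path: str | Path,
    participants: Mapping[str, ParticipantRecord] | None = None,
) -> None:
    annotations_to_frame(annotations, participants).to_csv(path, index=False)


def read_annotation_table(
    path: str | Path,
    taxonomy: ClassTaxonomy | None = None,
    dialect: str = "zero_half_open",
) -> tuple[list[Annotation], dict[str, ParticipantRecord]]:
    """Read a multi-rater annotation CSV.

    Parameters
    ----------
    dialect:
        ``"zero_half_open"`` (native) or ``"one_inclusive"`` for exports using
        1-based inclusive pixel coordinates (converted on read).

    Returns the annotations plus per-participant records whose
    ``fovs_annotated`` is reconstructed as the union of that participant's
    fov_ids.
    """
    taxonomy = taxonomy or ClassTaxonomy.default()
    if dialect not in ("zero_half_open", "one_inclusive"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"annotation_id", "participant_id", "fov_id", "xmin", "ymin",
                "xmax", "ymax", "raw_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    annotations: list[Annotation] = []
    participants: dict[str, ParticipantRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        raw_class = str(row.raw_class).strip()
        if not taxonomy.is_known(raw_class):
            raise ValueError(f"unknown class label {raw_class!r} at row {i}")
        try:
            xmin, ymin = float(row.xmin), float(row.ymin)
            xmax, ymax = float(row.xmax), float(row.ymax)
        except ValueError as exc:
            raise ValueError(f"non-numeric box coordinate at row {i}") from exc
        if dialect == "one_inclusive":
            xmin, ymin = xmin - 1, ymin - 1
            # inclusive xmax means the pixel itself is inside
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"malformed box (xmax <= xmin or ymax <= ymin) at row {i}")
        boundary = None
        wkt_text = getattr(row, "boundary_wkt", "")
        if isinstance(wkt_text, str) and wkt_text.strip():
            boundary = _shapely_wkt.loads(wkt_text)
        kind = getattr(row, "kind", "manual_box") or "manual_box"
        ann = Annotation(
            annotation_id=str(row.annotation_id).strip(),
            participant_id=str(row.participant_id).strip(),
            fov_id=str(row.fov_id).strip(),
            box=BoundingBox(xmin, ymin, xmax, ymax),
            raw_class=raw_class,
            kind=str(kind).strip(),
            boundary=boundary,
        )
        annotations.append(ann)
        tier = str(getattr(row, "tier", "NP") or "NP").strip()
        rec = participants.setdefault(
            ann.participant_id, ParticipantRecord(ann.participant_id, tier)
        )
        rec.fovs_annotated.add(ann.fov_id)
    return annotations, participants


# ---------------------------------------------------------------------------
# Region masks
# ---------------------------------------------------------------------------


@dataclass
class RegionMask:
    """Integer label image plus a legend mapping integers to region classes."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("region mask must be a single-channel 2D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("region mask must have an integer dtype")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"mask values absent from legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_image(self) -> np.ndarray:
        """Mask as an array of region-class strings."""
        lut = np.empty(max(self.legend) + 1, dtype=object)
        for k, v in self.legend.items():
            lut[k] = v
        return lut[self.labels]


def write_label_mask(mask: RegionMask, path: str | Path,
                     legend_path: str | Path | None = None) -> None:
    path = Path(path)
    legend_path = Path(legend_path) if legend_path else path.with_suffix(".json")
    arr = mask.labels
    if arr.max(initial=0) > 65535 or arr.min(initial=0) < 0:
        raise ValueError("label values must fit in uint16 for PNG storage")
    img = Image.fromarray(arr.astype(np.uint16 if arr.max(initial=0) > 255 else np.uint8))
    img.save(path)
    legend_path.write_text(json.dumps({str(k): v for k, v in mask.legend.items()}))


def read_region_mask(path: str | Path,
                     legend_path: str | Path | None = None) -> RegionMask:
    path = Path(path)
    legend_path = Path(legend_path) if legend_path else path.with_suffix(".json")
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "P"):
        raise ValueError(
            f"region mask must be a single-channel label image, got mode {img.mode!r}"
        )
    arr = np.asarray(img).astype(np.int64)
    legend = {int(k): v for k, v in json.loads(Path(legend_path).read_text()).items()}
    return RegionMask(arr, legend)
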