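"""Constrained agglomerative clustering of multi-rater bounding boxes.

Boxes from all participants on one FOV are merged bottom-up using
intersection-over-union (IOU) as similarity with complete (maximum) linkage:
two clusters may merge only while *every* cross-pair of member boxes overlaps
at IOU >= t*.  A do-not-link constraint forbids merging two annotations from
the same participant — if one rater drew two overlapping boxes, they meant
two distinct nuclei, and the second box stays in its own branch.  Each final
cluster is summarized by its medoid box (the member maximizing summed IOU to
the others), which guarantees the anchor proposal is a real annotated box.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    UNDETECTED,
    Annotation,
    BoundingBox,
    ClassTaxonomy,
    ParticipantRecord,
)

__all__ = [
    "ClusterConfig",
    "AnchorCluster",
    "iou",
    "pairwise_iou",
    "constrained_agglomerate",
    "cluster_annotations",
    "select_medoid",
    "build_label_matrix",
]


@dataclass(frozen=True)
class ClusterConfig:
    #: minimum complete-linkage IOU for a merge to be admissible
    iou_threshold: float = 0.25
    enforce_do_not_link: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in (0, 1]")


@dataclass
class AnchorCluster:
    anchor_id: str
    members: tuple[Annotation, ...]
    medoid: Annotation
    fov_id: str

    @property
    def participant_ids(self) -> set[str]:
        return {m.participant_id for m in self.members}

    def n_members(self, tiers: Mapping[str, str] | None = None,
                  pathologists_only: bool = False) -> int:
        if not pathologists_only:
            return len(self.members)
        assert tiers is not None
        from .core import PATHOLOGIST_TIERS
        return sum(1 for m in self.members if tiers.get(m.participant_id) in PATHOLOGIST_TIERS)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint interiors."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def pairwise_iou(boxes: np.ndarray) -> np.ndarray:
    """Pairwise IOU for an (n, 4) array of [xmin, ymin, xmax, ymax] boxes."""
    boxes = np.asarray(boxes, dtype=float)
    if boxes.size == 0:
        return np.zeros((0, 0))
    x0, y0, x1, y1 = boxes.T
    ix = np.minimum(x1[:, None], x1[None, :]) - np.maximum(x0[:, None], x0[None, :])
    iy = np.minimum(y1[:, None], y1[None, :]) - np.maximum(y0[:, None], y0[None, :])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    inter[(ix <= 0) | (iy <= 0)] = 0.0
    areas = (x1 - x0) * (y1 - y0)
    union = areas[:, None] + areas[None, :] - inter
    return inter / union


def select_medoid(members: Sequence[Annotation] | AnchorCluster) -> Annotation:
    """Member maximizing summed IOU to all other members.

    Singletons return themselves; ties break to the lexicographically
    smallest annotation_id.
    """
    if isinstance(members, AnchorCluster):
        members = members.members
    if not members:
        raise ValueError("cannot take medoid of an empty cluster")
    if len(members) == 1:
        return members[0]
    boxes = np.array([m.box.as_tuple() for m in members])
    sims = pairwise_iou(boxes)
    np.fill_diagonal(sims, 0.0)
    totals = sims.sum(axis=1)
    best = max(range(len(members)),
               key=lambda i: (totals[i], _neg_id(members[i].annotation_id)))
    return members[best]


class _NegStr:
    """Reverses string ordering so max() prefers the smaller id."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def _neg_id(s: str) -> _NegStr:
    return _NegStr(s)


def constrained_agglomerate(
    annotations: Sequence[Annotation],
    config: ClusterConfig | None = None,
) -> list[AnchorCluster]:
    """Greedy complete-linkage agglomeration under the do-not-link constraint.

    Merges are performed in decreasing order of current linkage similarity
    (min cross-pair IOU) while it stays >= the threshold; a merge whose union
    would hold two annotations from one participant is treated as distance
    infinity.  Linkage is maintained incrementally via the complete-linkage
    Lance-Williams update ``sim(new, k) = min(sim(i, k), sim(j, k))``.
    Deterministic: singletons are ordered by annotation_id and ties in
    similarity break to the smallest (cluster-id, cluster-id) pair in
    creation order.
    """
    config = config or ClusterConfig()
    if not annotations:
        return []
    fovs = {a.fov_id for a in annotations}
    if len(fovs) > 1:
        raise ValueError(
            f"annotations span multiple FOVs {sorted(fovs)}; cluster per FOV "
            "(see cluster_annotations)"
        )
    fov_id = next(iter(fovs))
    anns = sorted(annotations, key=lambda a: a.annotation_id)
    n = len(anns)
    boxes = np.array([a.box.as_tuple() for a in anns])
    base_sim = pairwise_iou(boxes)

    # active clusters: cluster id -> (member indices, participant multiset)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    parts: dict[int, set[str]] = {i: {anns[i].participant_id} for i in range(n)}
    # linkage similarity between active clusters, keyed (i, j) with i < j.
    # Complete-linkage similarity only decreases under merging, so pairs
    # already below t* can never become mergeable and are never stored.
    t_star = config.iou_threshold
    link: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if base_sim[i, j] >= t_star:
                link[(i, j)] = base_sim[i, j]
    next_id = n

    while True:
        best_pair: tuple[int, int] | None = None
        best_sim = -1.0
        for (i, j) in sorted(link):
            s = link[(i, j)]
            if s < t_star or s <= best_sim:
                continue  # ties resolve to the earliest (i, j) via the sort
            if config.enforce_do_not_link and not parts[i].isdisjoint(parts[j]):
                continue
            best_pair, best_sim = (i, j), s
        if best_pair is None:
            break
        i, j = best_pair
        new = next_id
        next_id += 1
        members[new] = members.pop(i) + members.pop(j)
        parts[new] = parts.pop(i) | parts.pop(j)
        touched: dict[int, list[float]] = {}
        new_links: dict[tuple[int, int], float] = {}
        for (a, b), s in link.items():
            if a in (i, j) and b in (i, j):
                continue
            if a in (i, j) or b in (i, j):
                touched.setdefault(b if a in (i, j) else a, []).append(s)
            else:
                new_links[(a, b)] = s
        for other, sims in touched.items():
            # linkage to the merged cluster is min over both halves; a half
            # with no stored link was already below t*, so the pair drops out
            if len(sims) == 2:
                new_links[(other, new)] = min(sims)
        link = new_links

    clusters: list[AnchorCluster] = []
    order = sorted(members, key=lambda cid: min(members[cid]))
    for k, cid in enumerate(order):
        ms = tuple(anns[i] for i in sorted(members[cid]))
        medoid = select_medoid(ms)
        clusters.append(
            AnchorCluster(
                anchor_id=f"{fov_id}_a{k:04d}",
                members=ms,
                medoid=medoid,
                fov_id=fov_id,
            )
        )
    return clusters


def cluster_annotations(
    annotations: Iterable[Annotation],
    config: ClusterConfig | None = None,
) -> list[AnchorCluster]:
    """Cluster a pooled annotation table FOV by FOV."""
    by_fov: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_fov.setdefault(a.fov_id, []).append(a)
    out: list[AnchorCluster] = []
    for fov in sorted(by_fov):
        out.extend(constrained_agglomerate(by_fov[fov], config))
    return out


def build_label_matrix(
    clusters: Sequence[AnchorCluster],
    participants: Mapping[str, ParticipantRecord] | Mapping[str, set[str]],
    taxonomy: ClassTaxonomy | None = None,
    overlap_threshold: float | None = 0.25,
) -> pd.DataFrame:
    """Anchors x participants matrix of raw labels for truth inference.

    Entry semantics: the member's raw class if the participant contributed
    to the cluster; ``"undetected"`` if they annotated that FOV but placed
    no box at that location (a conscious decision not to annotate a nucleus
    there); NaN (missing) if they never saw that FOV.

    A rater whose box landed in a *different* cluster overlapping this
    anchor (IOU with the medoid >= ``overlap_threshold``) did annotate this
    location — the do-not-link constraint or strict complete linkage merely
    assigned their box elsewhere — so their entry is missing rather than
    "undetected".  Pass ``overlap_threshold=None`` for the strict reading in
    which any non-member attendee votes "undetected".
    """
    attendance: dict[str, set[str]] = {}
    for pid, rec in participants.items():
        attendance[pid] = set(rec.fovs_annotated) if isinstance(rec, ParticipantRecord) else set(rec)
    pids = sorted(attendance)
    for c in clusters:
        for m in c.members:
            if m.participant_id not in attendance:
                raise ValueError(
                    f"participant {m.participant_id!r} appears in cluster "
                    f"{c.anchor_id!r} but is absent from the attendance records"
                )
            if c.fov_id not in attendance[m.participant_id]:
                raise ValueError(
                    f"participant {m.participant_id!r} has a member in FOV "
                    f"{c.fov_id!r} not listed in their fovs_annotated"
                )

    # per (fov, participant): boxes of that participant, for overlap lookups
    fov_boxes: dict[tuple[str, str], list[BoundingBox]] = {}
    if overlap_threshold is not None:
        for c in clusters:
            for m in c.members:
                fov_boxes.setdefault((c.fov_id, m.participant_id), []).append(m.box)

    index = [c.anchor_id for c in clusters]
    mat = pd.DataFrame(np.nan, index=index, columns=pids, dtype=object)
    for c in clusters:
        member_of = {m.participant_id: m for m in c.members}
        for pid in pids:
            if c.fov_id not in attendance[pid]:
                continue
            m = member_of.get(pid)
            if m is not None:
                mat.loc[c.anchor_id, pid] = m.raw_class
                continue
            if overlap_threshold is not None and any(
                iou(c.medoid.box, b) >= overlap_threshold
                for b in fov_boxes.get((c.fov_id, pid), ())
            ):
                continue  # annotated this location via a rival cluster: missing
            mat.loc[c.anchor_id, pid] = UNDETECTED
    return mat
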