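"""Independent reference implementations used only as test oracles.

Deliberately naive and written without reference to the package internals:
the clustering oracle re-scans all admissible pairs from scratch at every
step, the perimeter oracle walks the 8-connected boundary chain pixel by
pixel, and matching is solved exactly by the Hungarian algorithm.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = min(ax1, bx1) - max(ax0, bx0)
    iy = min(ay1, by1) - max(ay0, by0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def brute_force_agglomerate(
    items: list[tuple[str, str, tuple[float, float, float, float]]],
    t_star: float,
    enforce: bool = True,
) -> set[frozenset[str]]:
    """Exhaustive constrained complete-linkage agglomeration.

    ``items`` are (annotation_id, participant_id, box) tuples.  At every
    step the full linkage (min cross-pair IOU) is recomputed from scratch
    for every admissible cluster pair and the best merge taken; ties break
    to the smallest (cluster_id, cluster_id) in creation order, with initial
    singletons ordered by annotation_id.  Returns the partition as a set of
    frozensets of annotation ids.
    """
    items = sorted(items, key=lambda t: t[0])
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(items))}
    next_id = len(items)
    while True:
        best = None
        best_sim = -1.0
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                ca, cb = ids[ai], ids[bi]
                if enforce:
                    pa = {items[i][1] for i in clusters[ca]}
                    pb = {items[i][1] for i in clusters[cb]}
                    if pa & pb:
                        continue
                sim = min(
                    box_iou(items[i][2], items[j][2])
                    for i in clusters[ca]
                    for j in clusters[cb]
                )
                if sim >= t_star and sim > best_sim:
                    best, best_sim = (ca, cb), sim
        if best is None:
            break
        ca, cb = best
        clusters[next_id] = clusters.pop(ca) + clusters.pop(cb)
        next_id += 1
    return {
        frozenset(items[i][0] for i in members) for members in clusters.values()
    }


def majority_vote(row) -> str | None:
    """Strict-majority label of one label-matrix row; None on a tie."""
    labels = [v for v in row if isinstance(v, str)]
    if not labels:
        return None
    vals, counts = np.unique(labels, return_counts=True)
    if (counts == counts.max()).sum() > 1:
        return None
    return str(vals[counts.argmax()])


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def chain_perimeter(mask: np.ndarray) -> float:
    """8-connected boundary chain length by Moore-neighbor tracing.

    Orthogonal steps count 1, diagonal steps sqrt(2).  Works for a single
    connected object without holes (all this suite needs).
    """
    mask = np.pad(np.asarray(mask, bool), 1)
    rows, cols = np.nonzero(mask)
    start = (rows[0], cols[0])  # raster-order first pixel
    if mask.sum() == 1:
        return 4.0
    length = 0.0
    current = start
    backtrack_dir = 6  # came from the left
    first_step = None
    while True:
        found = False
        for k in range(8):
            d = (backtrack_dir + 1 + k) % 8
            nr, nc = current[0] + _MOORE[d][0], current[1] + _MOORE[d][1]
            if mask[nr, nc]:
                step = math_hypot(_MOORE[d])
                length += step
                prev = current
                current = (nr, nc)
                backtrack_dir = (d + 4) % 8
                if first_step is None:
                    first_step = (prev, current)
                elif (prev, current) == first_step:
                    return length - step
                found = True
                break
        if not found:  # isolated pixel
            return 4.0


def math_hypot(d: tuple[int, int]) -> float:
    return float(np.hypot(d[0], d[1]))


def optimal_match_count(iou_matrix: np.ndarray, threshold: float) -> int:
    """Exact maximum-cardinality IOU matching via the Hungarian algorithm."""
    if iou_matrix.size == 0:
        return 0
    cost = np.where(iou_matrix >= threshold, -iou_matrix, 1.0)
    rows, cols = linear_sum_assignment(cost)
    return int(sum(iou_matrix[r, c] >= threshold for r, c in zip(rows, cols)))
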