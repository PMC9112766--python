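from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nucfuse.core import Annotation, BoundingBox, ClassTaxonomy, ParticipantRecord


@pytest.fixture(scope="session")
def taxonomy() -> ClassTaxonomy:
    return ClassTaxonomy.default()


def make_ann(
    aid: str,
    pid: str,
    box: tuple[float, float, float, float],
    cls: str = "tumor",
    fov: str = "fov0",
    kind: str = "manual_box",
) -> Annotation:
    return Annotation(aid, pid, fov, BoundingBox(*box), cls, kind)


@pytest.fixture
def ann_factory():
    return make_ann


def random_boxes(
    rng: np.random.Generator, n: int, fov_size: float = 100.0,
    min_side: float = 8.0, max_side: float = 25.0,
) -> list[tuple[float, float, float, float]]:
    out = []
    for _ in range(n):
        w = rng.uniform(min_side, max_side)
        h = rng.uniform(min_side, max_side)
        x0 = rng.uniform(0, fov_size - w)
        y0 = rng.uniform(0, fov_size - h)
        out.append((x0, y0, x0 + w, y0 + h))
    return out


def random_scene_annotations(
    rng: np.random.Generator,
    n_annotations: int,
    n_participants: int,
    fov: str = "fov0",
    cluster_spread: float = 3.0,
) -> list[Annotation]:
    """Random boxes loosely grouped around a few nucleus centers so that
    overlapping, partially overlapping and disjoint pairs all occur."""
    n_centers = max(1, n_annotations // 3)
    centers = rng.uniform(15, 85, size=(n_centers, 2))
    anns = []
    for k in range(n_annotations):
        cx, cy = centers[rng.integers(0, n_centers)]
        cx += rng.normal(0, cluster_spread)
        cy += rng.normal(0, cluster_spread)
        w = rng.uniform(10, 22)
        h = rng.uniform(10, 22)
        pid = f"p{rng.integers(0, n_participants):02d}"
        anns.append(
            make_ann(
                f"a{k:03d}", pid,
                (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                cls=["tumor", "lymphocyte", "fibroblast"][int(rng.integers(0, 3))],
                fov=fov,
            )
        )
    return anns


def simulate_label_matrix(
    rng: np.random.Generator,
    classes: list[str],
    n_anchors: int,
    n_raters: int,
    diagonals: np.ndarray | float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Forward simulation from the rater-confusion generative model:
    uniform true classes, each rater emits through a symmetric confusion
    with the given diagonal(s).  Returns (matrix, true class indices)."""
    K = len(classes)
    if np.isscalar(diagonals):
        diagonals = np.full(n_raters, float(diagonals))
    truth = rng.integers(0, K, n_anchors)
    data = {}
    for j in range(n_raters):
        q = diagonals[j]
        conf = np.full((K, K), (1 - q) / (K - 1))
        np.fill_diagonal(conf, q)
        cum = conf[truth].cumsum(axis=1)
        draws = (rng.random((n_anchors, 1)) < cum).argmax(axis=1)
        data[f"r{j:02d}"] = [classes[d] for d in draws]
    df = pd.DataFrame(data, index=[f"a{i:04d}" for i in range(n_anchors)])
    return df, truth
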