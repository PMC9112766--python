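"""Annotation-redundancy planning: how many raters does each FOV need?

Keeps a fixed pool of non-pathologist (NP) raters, randomly retains k of
them per FOV, re-infers labels by EM from the reduced label matrix, and
scores the result against a fixed reference (e.g. the pathologist-inferred
truth).  Anchors stay fixed across realizations — only the NP votes are
thinned.  A removed NP is treated as not attending the FOV, so their
entries become missing rather than "undetected".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef

from .core import UNDETECTED, ClassTaxonomy
from .clustering import AnchorCluster, build_label_matrix
from .inference import EMConfig, em_infer

__all__ = [
    "RedundancyConfig",
    "subsample_raters",
    "run_redundancy",
    "summarize_redundancy",
]


@dataclass(frozen=True)
class RedundancyConfig:
    total_nps: int = 18
    nps_per_fov: tuple[int, ...] = (2, 3, 4, 6, 10, 18)
    n_realizations: int = 1000
    seed: int = 0
    accuracy_metric: str = "per_class_agreement"  # or "mcc"
    em: EMConfig = field(default_factory=EMConfig)

    def __post_init__(self) -> None:
        if any(k > self.total_nps or k < 1 for k in self.nps_per_fov):
            raise ValueError("each nps_per_fov must lie in [1, total_nps]")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _realization_rng(master_seed: int, k: int, realization: int) -> np.random.Generator:
    # counter-based derivation: realization r is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence([master_seed, k, realization]))


def subsample_raters(
    annotations: pd.DataFrame,
    k: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Retain exactly k participants per FOV, chosen uniformly without
    replacement; no constraint on how many FOVs any single participant keeps.

    ``annotations`` needs columns participant_id and fov_id.  Raises if any
    FOV has fewer than k attending participants.
    """
    rng = np.random.default_rng(seed)
    keep_parts: list[pd.DataFrame] = []
    for fov, grp in annotations.groupby("fov_id", sort=True):
        pids = sorted(grp["participant_id"].unique())
        if len(pids) < k:
            raise ValueError(f"FOV {fov!r} has only {len(pids)} raters, need {k}")
        chosen = set(rng.choice(pids, size=k, replace=False))
        keep_parts.append(grp[grp["participant_id"].isin(chosen)])
    return pd.concat(keep_parts, ignore_index=True) if keep_parts else annotations.iloc[:0]


def _subsample_matrix(
    matrix: pd.DataFrame,
    anchor_fov: Mapping[str, str],
    attendance: Mapping[str, set[str]],
    k: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mask entries of non-retained raters (per FOV) to missing."""
    fovs = sorted({anchor_fov[a] for a in matrix.index})
    retained: dict[str, set[str]] = {}
    for fov in fovs:
        attending = sorted(p for p in matrix.columns if fov in attendance[p])
        if len(attending) < k:
            raise ValueError(f"FOV {fov!r} has only {len(attending)} NPs, need {k}")
        retained[fov] = set(rng.choice(attending, size=k, replace=False))
    out = matrix.copy()
    for anchor in out.index:
        keep = retained[anchor_fov[anchor]]
        drop = [p for p in out.columns if p not in keep]
        out.loc[anchor, drop] = np.nan
    return out


def run_redundancy(
    clusters: Sequence[AnchorCluster],
    attendance: Mapping[str, set[str]],
    reference: pd.Series,
    taxonomy: ClassTaxonomy | None = None,
    config: RedundancyConfig | None = None,
) -> pd.DataFrame:
    """Redundancy sweep: for each k and realization, thin the NP label
    matrix to k NPs per FOV, re-run EM, and score inferred labels against
    the fixed ``reference`` (anchor_id -> class).

    Returns a long table (k, realization, class, accuracy); class "overall"
    aggregates all reference anchors.  Bit-reproducible under a fixed master
    seed.
    """
    taxonomy = taxonomy or ClassTaxonomy.default()
    config = config or RedundancyConfig()
    full = build_label_matrix(list(clusters), dict(attendance), taxonomy)
    anchor_fov = {c.anchor_id: c.fov_id for c in clusters}
    ref = reference.dropna()
    ref = ref[ref != UNDETECTED]
    classes = sorted(ref.unique())

    rows = []
    for k in config.nps_per_fov:
        for r in range(config.n_realizations):
            rng = _realization_rng(config.seed, int(k), r)
            thin = _subsample_matrix(full, anchor_fov, attendance, int(k), rng)
            # anchors with no retained votes cannot be inferred in this
            # realization; reindexing below scores them as misses
            thin = thin[thin.notna().any(axis=1)]
            with warnings.catch_warnings():
                # NPs retained on no FOV are expectedly all-missing
                warnings.simplefilter("ignore", UserWarning)
                inferred = em_infer(thin, taxonomy, config.em)
            pred = inferred.labels.reindex(ref.index)
            if config.accuracy_metric == "mcc":
                rows.append({
                    "k": k, "realization": r, "class": "overall",
                    "accuracy": float(matthews_corrcoef(ref, pred)),
                })
                continue
            for cls in classes:
                m = ref == cls
                rows.append({
                    "k": k, "realization": r, "class": cls,
                    "accuracy": float((pred[m] == cls).mean()),
                })
            rows.append({
                "k": k, "realization": r, "class": "overall",
                "accuracy": float((pred == ref).mean()),
            })
    return pd.DataFrame(rows)


def summarize_redundancy(
    table: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Median accuracy per (k, class) with a bootstrapped 95% interval
    around the median (the notch of a notched box plot)."""
    rng = np.random.default_rng(seed)
    rows = []
    for (k, cls), grp in table.groupby(["k", "class"]):
        vals = grp["accuracy"].to_numpy(float)
        boots = np.median(
            vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))], axis=1
        )
        rows.append({
            "k": k, "class": cls,
            "median": float(np.median(vals)),
            "notch_lo": float(np.percentile(boots, 2.5)),
            "notch_hi": float(np.percentile(boots, 97.5)),
            "n": len(vals),
        })
    return pd.DataFrame(rows)
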