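"""Interrater agreement and accuracy analytics.

Krippendorff's alpha (nominal, missing-tolerant) and Cohen's kappa are
implemented from their coincidence/contingency definitions; detection is
scored by greedy one-to-one IOU matching; classification by multiclass MCC
and one-vs-rest AUROC (micro and macro averaged); uncertainty by percentile
bootstrap.  Agreement values live in [-1, 1]: 1 is perfect agreement, 0 is
chance level.  Display-scale helpers multiply by 100, the convention used
when quoting e.g. "alpha = 55.5".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .clustering import pairwise_iou

__all__ = [
    "krippendorff_alpha",
    "cohen_kappa",
    "fleiss_band",
    "pairwise_kappa_matrix",
    "detection_prf",
    "classification_metrics",
    "bootstrap_ci",
    "compare_groups",
    "mds_embed",
    "AgreementReport",
    "agreement_report",
]


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def krippendorff_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Nominal-metric Krippendorff alpha for an items x raters label matrix.

    Items carrying fewer than two labels are excluded from the coincidence
    matrix.  Raises if no item has two or more labels (alpha undefined).
    """
    arr = matrix.to_numpy(dtype=object) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=object)
    values: list[str] = sorted(
        {v for v in arr.ravel() if not _is_missing(v)}, key=str
    )
    idx = {v: k for k, v in enumerate(values)}
    K = len(values)
    coincidence = np.zeros((K, K))
    any_pairable = False
    for row in arr:
        labels = [v for v in row if not _is_missing(v)]
        m = len(labels)
        if m < 2:
            continue
        any_pairable = True
        w = 1.0 / (m - 1)
        # ordered pairs (a, b) at distinct positions, weighted 1/(m-1)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    coincidence[idx[a], idx[b]] += w
    if not any_pairable:
        raise ValueError("alpha undefined: every item has fewer than two labels")
    n = coincidence.sum()
    n_c = coincidence.sum(axis=1)
    d_o = n - np.trace(coincidence)
    d_e = (n_c.sum() ** 2 - (n_c**2).sum()) / (n - 1)
    if d_e == 0:
        return 1.0 if d_o == 0 else float("-inf")
    return float(1.0 - d_o / d_e)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two paired label sequences.

    Pairs with a missing value on either side are dropped.  When expected
    agreement is 1 (both raters constant with the same label), kappa is 1 if
    observed agreement is also 1, otherwise undefined.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a, b) if not (_is_missing(x) or _is_missing(y))]
    if not pairs:
        raise ValueError("no complete pairs to compare")
    n = len(pairs)
    xs, ys = zip(*pairs)
    cats = sorted(set(xs) | set(ys), key=str)
    p_o = sum(x == y for x, y in pairs) / n
    pa = {c: xs.count(c) / n for c in cats}
    pb = {c: ys.count(c) / n for c in cats}
    p_e = sum(pa[c] * pb[c] for c in cats)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 but observed is not")
    return float((p_o - p_e) / (1.0 - p_e))


_FLEISS_BANDS = [
    (0.0, "poor/chance"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "near-perfect"),
]


def fleiss_band(value: float) -> str:
    """Verbal agreement band for a kappa/alpha value (Landis-Koch cut-points:
    <=0 poor/chance, (0,.2] slight, (.2,.4] fair, (.4,.6] moderate,
    (.6,.8] substantial, (.8,1] near-perfect)."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"agreement value {value} outside [-1, 1]")
    if value <= 0:
        return "poor/chance"
    for hi, name in _FLEISS_BANDS[1:]:
        if value <= hi:
            return name
    return "near-perfect"


def pairwise_kappa_matrix(matrix: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """Symmetric rater x rater Cohen-kappa matrix from a label matrix.

    Pairs sharing fewer than ``min_overlap`` co-labeled items get NaN.
    """
    raters = list(matrix.columns)
    out = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    for i, a in enumerate(raters):
        for j in range(i + 1, len(raters)):
            b = raters[j]
            both = matrix[[a, b]].dropna()
            if len(both) < min_overlap:
                k = np.nan
            else:
                try:
                    k = cohen_kappa(both[a], both[b])
                except ValueError:
                    k = np.nan
            out.iloc[i, j] = out.iloc[j, i] = k
    return out


def detection_prf(
    participant_boxes: pd.DataFrame,
    anchor_boxes: pd.DataFrame,
    attendance: Mapping[str, set[str]] | None = None,
    match_iou: float = 0.5,
) -> pd.DataFrame:
    """Per-participant detection precision / recall / F1 against reference
    anchors.

    ``participant_boxes`` needs columns participant_id, fov_id, xmin, ymin,
    xmax, ymax; ``anchor_boxes`` needs fov_id plus the box columns.  Matching
    is greedy one-to-one in decreasing IOU order at IOU >= ``match_iou``.
    Recall counts anchors only in FOVs the participant attended (from
    ``attendance``, or inferred from their boxes).
    """
    cols = ["xmin", "ymin", "xmax", "ymax"]
    rows = []
    for pid, grp in participant_boxes.groupby("participant_id"):
        fovs = set(attendance[pid]) if attendance else set(grp["fov_id"])
        n_matched = 0
        n_boxes = len(grp)
        n_anchors = int((anchor_boxes["fov_id"].isin(fovs)).sum())
        for fov, sub in grp.groupby("fov_id"):
            ref = anchor_boxes[anchor_boxes["fov_id"] == fov]
            if ref.empty:
                continue
            sims = pairwise_iou_cross(sub[cols].to_numpy(float), ref[cols].to_numpy(float))
            n_matched += _greedy_match_count(sims, match_iou)
        if n_anchors == 0:
            rows.append({"participant_id": pid, "precision": np.nan,
                         "recall": np.nan, "f1": np.nan,
                         "n_boxes": n_boxes, "n_anchors": 0, "n_matched": 0})
            continue
        precision = n_matched / n_boxes if n_boxes else np.nan
        recall = n_matched / n_anchors
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision and recall else 0.0
        )
        rows.append({"participant_id": pid, "precision": precision,
                     "recall": recall, "f1": f1, "n_boxes": n_boxes,
                     "n_anchors": n_anchors, "n_matched": n_matched})
    return pd.DataFrame(rows).set_index("participant_id")


def pairwise_iou_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) IOU matrix between two box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    stacked = pairwise_iou(np.vstack([a, b]))
    return stacked[: len(a), len(a):]


def _greedy_match_count(sims: np.ndarray, threshold: float) -> int:
    order = np.argsort(sims, axis=None)[::-1]
    used_a: set[int] = set()
    used_b: set[int] = set()
    count = 0
    for flat in order:
        i, j = np.unravel_index(flat, sims.shape)
        if sims[i, j] < threshold:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        count += 1
    return count


def greedy_match_pairs(sims: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Greedy one-to-one matching in decreasing-IOU order; returns (row, col)
    index pairs."""
    order = np.argsort(sims, axis=None)[::-1]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = np.unravel_index(flat, sims.shape)
        if sims[i, j] < threshold:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        pairs.append((int(i), int(j)))
    return pairs


def classification_metrics(
    reference: Sequence[str],
    posteriors: pd.DataFrame | None = None,
    predicted: Sequence[str] | None = None,
) -> dict:
    """Multiclass MCC, micro/macro one-vs-rest AUROC and a confusion matrix.

    ``reference`` must exclude "undetected" (detection is scored separately).
    AUROC needs ``posteriors`` (anchors x classes scores); classes absent
    from the reference are excluded from the macro average with a warning.
    """
    reference = list(reference)
    if predicted is None:
        if posteriors is None:
            raise ValueError("need posteriors or predicted labels")
        predicted = list(posteriors.idxmax(axis=1))
    predicted = list(predicted)
    mcc = float(matthews_corrcoef(reference, predicted))
    cats = sorted(set(reference) | set(predicted))
    conf = pd.DataFrame(0, index=cats, columns=cats)
    for r, p in zip(reference, predicted):
        conf.loc[r, p] += 1
    out = {"mcc": mcc, "confusion": conf}
    if posteriors is not None:
        classes = [c for c in posteriors.columns]
        present = [c for c in classes if c in set(reference)]
        absent = [c for c in classes if c not in set(reference)]
        if absent:
            warnings.warn(
                f"classes absent from reference excluded from macro AUROC: {absent}"
            )
        scores = posteriors[present].to_numpy(float)
        # renormalize after dropping absent columns so rows remain scores
        y = np.array([present.index(r) for r in reference])
        onehot = np.zeros((len(y), len(present)))
        onehot[np.arange(len(y)), y] = 1.0
        if len(present) == 2:
            micro = macro = float(roc_auc_score(y, scores[:, 1]))
        else:
            micro = float(roc_auc_score(onehot.ravel(), scores.ravel()))
            macro = float(
                roc_auc_score(y, scores, multi_class="ovr", average="macro",
                              labels=list(range(len(present))))
            )
        out["auroc_micro"] = micro
        out["auroc_macro"] = macro
    return out


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: Sequence[float] | np.ndarray,
    n_trials: int = 1000,
    seed: int | None = None,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval (default 95%, 1000 trials)."""
    data = np.asarray(data)
    if data.shape[0] < 2:
        raise ValueError("bootstrap needs at least two observations")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    vals = np.array(
        [statistic(data[rng.integers(0, n, n)]) for _ in range(n_trials)]
    )
    lo = (100.0 - ci) / 2.0
    return (float(np.percentile(vals, lo)), float(np.percentile(vals, 100.0 - lo)))


def compare_groups(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal-length samples")
        if np.all(x - y == 0):
            raise ValueError("Wilcoxon undefined: all paired differences are zero")
        res = _stats.wilcoxon(x, y, alternative="two-sided")
    else:
        res = _stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mds_embed(
    kappa_matrix: pd.DataFrame | np.ndarray, dims: int = 2
) -> tuple[np.ndarray, float]:
    """Classical MDS (principal-coordinates) embedding of raters from their
    pairwise-kappa matrix, on dissimilarity 1 - kappa.

    Returns (coordinates, stress); coordinates are reproducible up to
    rotation/reflection.  Stress is Kruskal stress-1 of embedded vs input
    distances.
    """
    K = kappa_matrix.to_numpy(float) if isinstance(kappa_matrix, pd.DataFrame) else np.asarray(kappa_matrix, float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-9, equal_nan=True):
        raise ValueError("pairwise kappa matrix must be symmetric")
    D = np.clip(1.0 - K, 0.0, None)
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (D**2).sum()
    stress = float(np.sqrt(((emb - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    return coords, stress


@dataclass
class AgreementReport:
    alpha: float
    alpha_band: str
    pairwise_kappa: pd.DataFrame
    n_items: int
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_x100": 100.0 * self.alpha,
            "alpha_band": self.alpha_band,
            "pairwise_kappa": self.pairwise_kappa.to_dict(),
            "n_items": self.n_items,
            "n_raters": self.n_raters,
        }


def agreement_report(matrix: pd.DataFrame) -> AgreementReport:
    """Overall alpha plus the pairwise-kappa matrix for a label matrix."""
    alpha = krippendorff_alpha(matrix)
    return AgreementReport(
        alpha=alpha,
        alpha_band=fleiss_band(max(min(alpha, 1.0), -1.0)),
        pairwise_kappa=pairwise_kappa_matrix(matrix),
        n_items=matrix.shape[0],
        n_raters=matrix.shape[1],
    )
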