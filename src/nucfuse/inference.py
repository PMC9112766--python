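"""Truth inference from multi-rater label matrices by Dawid-Skene EM.

Each anchor (candidate nucleus) has a latent true state drawn from the
nucleus classes plus "undetected"; each rater emits a label through a
personal confusion matrix conditioned on that state.  "Undetected" is a
first-class state: a rater who saw the FOV but placed no box voted, in
effect, that there is no nucleus there.  "Ambiguous" is observable — a rater
may emit it — but is never a true state, so confusion matrices are
rectangular (true states x emitted labels).

EM alternates M-steps (re-estimate class priors and per-rater confusions
from posterior-weighted counts, with epsilon smoothing) and E-steps
(per-anchor posteriors over true states).  Defaults follow common practice
for this design: diagonal initial rater quality 0.7 and a fixed 70
iterations for bit-reproducibility.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import AMBIGUOUS, UNDETECTED, PATHOLOGIST_TIERS, ClassTaxonomy
from .clustering import AnchorCluster

__all__ = [
    "EMConfig",
    "InferredLabelSet",
    "em_infer",
    "infer_click_approval",
    "accept_anchors",
    "aggregate_superclass",
]


@dataclass(frozen=True)
class EMConfig:
    init_quality: float = 0.7
    n_iterations: int = 70
    smoothing_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.init_quality < 1.0:
            raise ValueError("init_quality must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class InferredLabelSet:
    """EM output: per-anchor posteriors, argmax labels, and per-rater
    reliability (confusion) estimates."""

    posteriors: pd.DataFrame          # anchors x true states
    labels: pd.Series                 # argmax true state per anchor
    is_nucleus: pd.Series             # argmax != undetected
    confusions: dict[str, pd.DataFrame]  # rater -> true x emitted
    priors: pd.Series                 # class prior over true states
    log_likelihoods: list[float] = field(default_factory=list)

    def diagonal_reliability(self) -> pd.Series:
        """P(emit own class | true class), averaged over true states, per rater."""
        out = {}
        for pid, c in self.confusions.items():
            shared = [t for t in c.index if t in c.columns]
            out[pid] = float(np.mean([c.loc[t, t] for t in shared]))
        return pd.Series(out)


def _dawid_skene(
    obs: np.ndarray,
    n_true: int,
    n_emit: int,
    true_emit_idx: np.ndarray,
    config: EMConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Core EM on an (items x raters) int array; -1 marks missing.

    ``true_emit_idx[t]`` is the emitted-label index that "matches" true
    state t (used for the diagonal initialization and frequency-based
    posterior init).
    """
    n_items, n_raters = obs.shape
    eps = config.smoothing_epsilon
    mask = obs >= 0

    # per-anchor emitted-label frequencies over true states: used to seed the
    # class prior (classic choice); anchors voting only reserved labels
    # contribute uniformly
    freq = np.zeros((n_items, n_true))
    for t in range(n_true):
        freq[:, t] = (obs == true_emit_idx[t]).sum(axis=1)
    zero = freq.sum(axis=1) == 0
    freq[zero] = 1.0
    freq /= freq.sum(axis=1, keepdims=True)
    priors = freq.sum(axis=0) + eps
    priors /= priors.sum()

    # rater confusions start symmetric: init_quality on the matching emitted
    # label, the remainder spread over the other labels
    q = config.init_quality
    init_conf = np.full((n_true, n_emit), (1.0 - q) / max(n_emit - 1, 1))
    init_conf[np.arange(n_true), true_emit_idx] = q
    conf = np.broadcast_to(init_conf, (n_raters, n_true, n_emit)).copy()

    # one-hot observation tensors, precomputed per rater
    onehots = []
    for j in range(n_raters):
        m = mask[:, j]
        O = np.zeros((int(m.sum()), n_emit))
        O[np.arange(O.shape[0]), obs[m, j]] = 1.0
        onehots.append((m, O))

    lls: list[float] = []
    post = freq
    for _ in range(config.n_iterations):
        # E-step: posteriors under current priors and confusions
        logpost = np.tile(np.log(priors), (n_items, 1))
        for j in range(n_raters):
            m, _ = onehots[j]
            logpost[m] += np.log(conf[j][:, obs[m, j]].T)
        norm = logsumexp(logpost, axis=1)
        lls.append(float(norm.sum()))
        post = np.exp(logpost - norm[:, None])
        # M-step: re-estimate priors and confusions from weighted counts
        counts = post.sum(axis=0) + eps
        priors = counts / counts.sum()
        for j in range(n_raters):
            m, O = onehots[j]
            C = post[m].T @ O + eps
            conf[j] = C / C.sum(axis=1, keepdims=True)
    return post, conf, priors, lls


def _prepare_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop all-missing raters (warn); reject all-missing anchors."""
    values = matrix.notna()
    dead_raters = [c for c in matrix.columns if not values[c].any()]
    if dead_raters:
        warnings.warn(
            f"dropping raters with no observed labels: {dead_raters}", stacklevel=3
        )
        matrix = matrix.drop(columns=dead_raters)
    dead_anchors = matrix.index[~matrix.notna().any(axis=1)]
    if len(dead_anchors):
        raise ValueError(
            f"anchors with no observed labels cannot be inferred: {list(dead_anchors)[:5]}"
        )
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("label matrix needs at least one anchor and one rater")
    return matrix


def em_infer(
    matrix: pd.DataFrame,
    taxonomy: ClassTaxonomy | None = None,
    config: EMConfig | None = None,
) -> InferredLabelSet:
    """Infer per-anchor true labels and per-rater confusions.

    ``matrix`` is an anchors x raters frame of raw class labels, with
    "undetected" for raters who saw the FOV but skipped the anchor and NaN
    for raters who never saw the FOV.
    """
    taxonomy = taxonomy or ClassTaxonomy.default()
    config = config or EMConfig()
    matrix = _prepare_matrix(matrix)

    true_states = list(taxonomy.raw_classes) + [UNDETECTED]
    emitted = list(taxonomy.raw_classes) + [AMBIGUOUS, UNDETECTED]
    emit_code = {lab: k for k, lab in enumerate(emitted)}

    obs = np.full(matrix.shape, -1, dtype=np.int64)
    arr = matrix.to_numpy(dtype=object)
    for (i, j), v in np.ndenumerate(arr):
        if isinstance(v, str):
            if v not in emit_code:
                raise ValueError(f"label {v!r} not in taxonomy or reserved labels")
            obs[i, j] = emit_code[v]
        elif v is not None and not (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"unexpected matrix entry {v!r}")

    true_emit_idx = np.array([emit_code[t] for t in true_states])
    post, conf, priors, lls = _dawid_skene(
        obs, len(true_states), len(emitted), true_emit_idx, config
    )

    posteriors = pd.DataFrame(post, index=matrix.index, columns=true_states)
    labels = posteriors.idxmax(axis=1)
    confusions = {
        pid: pd.DataFrame(conf[j], index=true_states, columns=emitted)
        for j, pid in enumerate(matrix.columns)
    }
    return InferredLabelSet(
        posteriors=posteriors,
        labels=labels,
        is_nucleus=labels != UNDETECTED,
        confusions=confusions,
        priors=pd.Series(priors, index=true_states),
        log_likelihoods=lls,
    )


CLICKED, NOT_CLICKED = "clicked", "not_clicked"


def infer_click_approval(
    click_matrix: pd.DataFrame,
    config: EMConfig | None = None,
) -> pd.Series:
    """Probability each algorithmic boundary is correct, from click votes.

    Segmentation accuracy is modeled as a binary variable (clicked vs not
    clicked) and run through the same EM machinery with |K| = 2; a click is
    the emitted label matching the true state "correct".
    """
    config = config or EMConfig()
    click_matrix = _prepare_matrix(click_matrix)
    emit_code = {CLICKED: 0, NOT_CLICKED: 1}
    obs = np.full(click_matrix.shape, -1, dtype=np.int64)
    arr = click_matrix.to_numpy(dtype=object)
    for (i, j), v in np.ndenumerate(arr):
        if isinstance(v, str):
            if v not in emit_code:
                raise ValueError(f"click entry {v!r} must be 'clicked' or 'not_clicked'")
            obs[i, j] = emit_code[v]
    post, _, _, _ = _dawid_skene(obs, 2, 2, np.array([0, 1]), config)
    return pd.Series(post[:, 0], index=click_matrix.index, name="p_boundary_correct")


def accept_anchors(
    clusters: Sequence[AnchorCluster],
    pathologist_inferred: InferredLabelSet,
    tiers: Mapping[str, str],
) -> list[str]:
    """Anchor acceptance: >= 2 pathologists detected it AND the inferred
    pathologist truth concurs it is a nucleus (argmax != undetected).
    """
    n_path_annotations = sum(
        1
        for c in clusters
        for m in c.members
        if tiers.get(m.participant_id) in PATHOLOGIST_TIERS
    )
    if n_path_annotations == 0:
        raise ValueError("no pathologist annotations: anchor acceptance is undefined")
    accepted = []
    for c in clusters:
        n_path = sum(
            1 for m in c.members if tiers.get(m.participant_id) in PATHOLOGIST_TIERS
        )
        if n_path < 2:
            continue
        if c.anchor_id not in pathologist_inferred.labels.index:
            continue
        if pathologist_inferred.labels[c.anchor_id] == UNDETECTED:
            continue
        accepted.append(c.anchor_id)
    return accepted


def aggregate_superclass(
    inferred: InferredLabelSet | pd.DataFrame,
    taxonomy: ClassTaxonomy | None = None,
) -> pd.DataFrame:
    """Aggregate class posteriors to super-classes by summing member-class
    probabilities; "undetected" is carried through unchanged."""
    taxonomy = taxonomy or ClassTaxonomy.default()
    post = inferred.posteriors if isinstance(inferred, InferredLabelSet) else inferred
    groups: dict[str, list[str]] = {}
    for col in post.columns:
        target = col if col == UNDETECTED else taxonomy.map_label(col, "super")
        groups.setdefault(target, []).append(col)
    out = pd.DataFrame(
        {sup: post[cols].sum(axis=1) for sup, cols in groups.items()},
        index=post.index,
    )
    return out
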