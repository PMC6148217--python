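"""Label atlases: the prior atlas and the similarity-weighted adaptive atlas.

The *prior atlas* is the cell-wise average of the one-hot encodings of a
pool of annotated label maps — a single spatial prior over class labels.
Because occlusions and missing parts make the true distribution of label
maps multi-modal, a single average is a blunt prior; the *weighted atlas*
adapts it to a particular image by selecting the ``m_w`` annotations most
similar to the image's current probability map (mean class F1-score) and
averaging them with their similarities as convex weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyPoolError, GridCompatibilityError
from .grids import LabelMap, ProbabilityMap, check_same_grid, uniform_padding

__all__ = [
    "Atlas",
    "AtlasWeighting",
    "one_hot",
    "prior_atlas",
    "f1_similarity",
    "atlas_weighting",
    "weighted_atlas",
]


@dataclass(frozen=True)
class Atlas:
    """A probability map plus the provenance of the maps that built it."""

    probability_map: ProbabilityMap
    provenance: tuple[tuple[str, float], ...]

    @property
    def probs(self) -> np.ndarray:
        return self.probability_map.probs

    @property
    def foreground(self) -> np.ndarray:
        return self.probability_map.foreground

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.probability_map.class_names

    @property
    def num_classes(self) -> int:
        return self.probability_map.num_classes

    @property
    def shape(self) -> tuple[int, int]:
        return self.probability_map.shape


@dataclass(frozen=True)
class AtlasWeighting:
    """Similarity weights and top-``m_w`` selection over a candidate pool."""

    identifiers: tuple[str, ...]
    weights: np.ndarray
    selection: np.ndarray
    m_w: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        s = np.asarray(self.selection, dtype=bool)
        if w.shape != s.shape or w.ndim != 1:
            raise ValueError("weights and selection must be parallel 1-D arrays")
        expected = min(self.m_w, w.size)
        if int(s.sum()) != expected:
            raise ValueError(f"exactly {expected} candidates must be selected")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "selection", s)


def one_hot(label_map: LabelMap) -> ProbabilityMap:
    """One-hot encoding of a label map; background gets the padding distribution."""
    k = label_map.num_classes
    h, w = label_map.shape
    probs = np.full((h, w, k), 1.0 / k)
    fg = label_map.foreground
    if np.any(fg):
        eye = np.eye(k)
        probs[fg] = eye[label_map.labels[fg] - 1]
    return ProbabilityMap(probs, fg, label_map.class_names)


def _one_hot_stack(maps: Sequence[LabelMap]) -> np.ndarray:
    """m×h×w×K stack of one-hot encodings (background = padding)."""
    return np.stack([one_hot(m).probs for m in maps])


def prior_atlas(maps: Sequence[LabelMap]) -> Atlas:
    """Unweighted cell-wise average of a pool of label maps.

    Foreground is the union of the pools' foregrounds; every contributing
    map carries weight ``1/m``.
    """
    maps = list(maps)
    if not maps:
        raise EmptyPoolError("prior atlas needs at least one label map")
    first = maps[0]
    for m in maps[1:]:
        check_same_grid(first, m)
    probs = _one_hot_stack(maps).mean(axis=0)
    fg = np.any([m.foreground for m in maps], axis=0)
    pmap = ProbabilityMap(probs, fg, first.class_names)
    provenance = tuple((m.identifier, 1.0 / len(maps)) for m in maps)
    return Atlas(pmap, provenance)


def _contingency(reference: LabelMap, hard: np.ndarray, pred_fg: np.ndarray):
    """Per-class (reference size, predicted size, intersection) counts."""
    k = reference.num_classes
    ref_sizes = np.bincount(reference.labels[reference.foreground] - 1, minlength=k)
    pred_sizes = np.bincount(hard[pred_fg] - 1, minlength=k)
    both = reference.foreground & pred_fg
    inter = np.bincount(
        (reference.labels[both] - 1) * k + (hard[both] - 1), minlength=k * k
    ).reshape(k, k)
    return ref_sizes, pred_sizes, inter


def _hard_assign(predicted: ProbabilityMap) -> np.ndarray:
    """Arg-max labels (1..K) on foreground, 0 elsewhere; lowest index wins ties."""
    hard = np.zeros(predicted.shape, dtype=np.int64)
    fg = predicted.foreground
    hard[fg] = np.argmax(predicted.probs[fg], axis=1) + 1
    return hard


def f1_similarity(reference: LabelMap, predicted: ProbabilityMap) -> float:
    """Mean class F1-score between a label map and a probability map.

    The probability map is hard-assigned by per-cell arg-max over its
    foreground. Per class, precision and recall of the predicted region
    against the reference region give F1 = 2pr/(p+r). Classes absent from
    both maps are excluded from the mean (no evidence either way); a class
    present on exactly one side contributes 0.
    """
    check_same_grid(reference, predicted)
    hard = _hard_assign(predicted)
    ref_sizes, pred_sizes, inter = _contingency(reference, hard, predicted.foreground)
    diag = np.diag(inter).astype(np.float64)
    denom = ref_sizes + pred_sizes  # 2pr/(p+r) == 2·TP / (|ref| + |pred|)
    involved = denom > 0
    if not np.any(involved):
        return 0.0
    f1 = 2.0 * diag[involved] / denom[involved]
    return float(f1.mean())


def atlas_weighting(
    candidates: Sequence[LabelMap],
    predicted: ProbabilityMap,
    m_w: int,
    exclude: str | None = None,
) -> AtlasWeighting:
    """F1 similarity weights over a candidate pool with top-``m_w`` selection.

    Candidates whose identifier equals ``exclude`` are dropped before
    weighting (self-exclusion at training time). Ties at the selection
    boundary break by identifier ascending for determinism.
    """
    if m_w < 1:
        raise ValueError("m_w must be ≥ 1")
    pool = [c for c in candidates if exclude is None or c.identifier != exclude]
    if not pool:
        raise EmptyPoolError("no candidate label maps remain after exclusion")
    weights = np.array([f1_similarity(c, predicted) for c in pool])
    ids = tuple(c.identifier for c in pool)
    n_select = min(m_w, len(pool))
    order = sorted(range(len(pool)), key=lambda i: (-weights[i], ids[i]))
    selection = np.zeros(len(pool), dtype=bool)
    selection[order[:n_select]] = True
    return AtlasWeighting(ids, weights, selection, m_w)


def weighted_atlas(
    candidates: Sequence[LabelMap],
    predicted: ProbabilityMap,
    m_w: int,
    exclude: str | None = None,
) -> Atlas:
    """Similarity-weighted convex combination of the ``m_w`` best candidates.

    Weights are mean class F1-scores against ``predicted``; the selected
    one-hot maps are combined with weights normalised to sum to 1. If every
    selected weight is 0 the selected maps are averaged unweighted.
    """
    pool = [c for c in candidates if exclude is None or c.identifier != exclude]
    weighting = atlas_weighting(pool, predicted, m_w)
    for c in pool:
        check_same_grid(c, predicted)
    sel = weighting.selection
    chosen = [(c, weighting.weights[i]) for i, (c, s) in enumerate(zip(pool, sel)) if s]
    # combine in identifier order so the result is independent of pool order
    chosen.sort(key=lambda cw: cw[0].identifier)
    selected = [c for c, _ in chosen]
    w = np.array([wi for _, wi in chosen])
    if w.sum() <= 0.0:
        w = np.full(len(selected), 1.0)
    w = w / w.sum()
    stack = _one_hot_stack(selected)
    probs = np.tensordot(w, stack, axes=1)
    fg = np.any([c.foreground for c in selected], axis=0)
    pmap = ProbabilityMap(probs, fg, predicted.class_names)
    provenance = tuple((c.identifier, float(wi)) for c, wi in zip(selected, w))
    return Atlas(pmap, provenance)
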