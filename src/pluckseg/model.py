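"""Auto-context training and inference.

Auto-context (AC) learns a sequence of T classifiers. Classifier t labels
each foreground cell from local appearance features concatenated with
context features read from the probability map produced by classifier
t−1 (the prior atlas before the first iteration). Two extensions are
supported and freely combined:

* integral context (IC): 2K extra features per cell — row means and
  whole-image means of the class probabilities;
* weighted-atlas auto-context (WAAC): from iteration 2 onward the feature
  vector additionally samples the stencil on an *adaptive atlas*, the
  similarity-weighted combination of the training annotations closest to
  the image's current probability map. Iteration 1 runs as plain AC: at
  that point the weighted atlas would merely duplicate the prior atlas.

The four (use_integral, use_weighted_atlas) combinations are named
``ac``, ``ac+ic``, ``waac`` and ``waac+ic``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeds import ROLE_CLASSIFIER, ROLE_SAMPLING, derive_rng, derive_seed
from .atlas import Atlas, one_hot, prior_atlas, weighted_atlas
from .classifier import PosteriorMLP
from .context import (
    StencilSpec,
    default_stencil,
    integral_context,
    integral_context_map,
    stencil_context,
    stencil_context_map,
)
from .errors import (
    FeatureSanityError,
    GridCompatibilityError,
    MissingAtlasError,
    StratificationError,
)
from .features import DecompositionConfig, FeatureGrid, appearance_features
from .grids import Image, LabelMap, ProbabilityMap, check_same_grid, resample_nearest

logger = logging.getLogger(__name__)

__all__ = [
    "VariantConfig",
    "ModelSequence",
    "sample_training_locations",
    "assemble_features",
    "feature_layout",
    "train_sequence",
    "predict_sequence",
    "apply_model",
    "argmax_labels",
]

VARIANT_NAMES = {
    (False, False): "ac",
    (True, False): "ac+ic",
    (False, True): "waac",
    (True, True): "waac+ic",
}


@dataclass(frozen=True)
class VariantConfig:
    """Configuration of one auto-context variant.

    ``T`` iterations, ``m_w`` atlas annotations, ``per_class_samples``
    stratified training locations per class. ``first_iteration_plain_ac``
    keeps the atlas block out of iteration 1 (where it would duplicate the
    prior-atlas context); exposed as a flag.
    """

    use_integral: bool = False
    use_weighted_atlas: bool = False
    T: int = 5
    m_w: int = 32
    per_class_samples: int = 1600
    stencil: StencilSpec = field(default_factory=default_stencil)
    seed: int = 0
    first_iteration_plain_ac: bool = True
    hidden_units: int = 20
    l2: float = 1e-3
    max_iter: int = 500
    tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be ≥ 1")
        if self.m_w < 1:
            raise ValueError("m_w must be ≥ 1")
        if self.per_class_samples < 1:
            raise ValueError("per_class_samples must be ≥ 1")

    @property
    def name(self) -> str:
        return VARIANT_NAMES[(self.use_integral, self.use_weighted_atlas)]

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "VariantConfig":
        for (ic, wa), n in VARIANT_NAMES.items():
            if n == name:
                return cls(use_integral=ic, use_weighted_atlas=wa, **kwargs)
        raise ValueError(
            f"unknown variant {name!r}; expected one of {sorted(VARIANT_NAMES.values())}"
        )


@dataclass
class ModelSequence:
    """The trained per-iteration classifiers plus everything inference needs."""

    classifiers: list[PosteriorMLP]
    feature_layouts: list[dict[str, slice]]
    variant: VariantConfig
    prior: Atlas
    class_names: tuple[str, ...]
    training_pool: tuple[str, ...]
    training_label_maps: list[LabelMap] = field(default_factory=list)
    training_history: list[float] = field(default_factory=list)
    decomposition: DecompositionConfig | None = None

    def __post_init__(self) -> None:
        if len(self.classifiers) != len(self.feature_layouts):
            raise ValueError("one feature layout per classifier is required")
        for clf, layout in zip(self.classifiers, self.feature_layouts):
            total = sum(s.stop - s.start for s in layout.values())
            if clf.num_inputs != total:
                raise ValueError(
                    f"classifier expects {clf.num_inputs} inputs but layout sums to {total}"
                )

    @property
    def num_iterations(self) -> int:
        return len(self.classifiers)


def feature_layout(
    variant: VariantConfig, num_local: int, num_classes: int, with_atlas: bool
) -> dict[str, slice]:
    """Named slices of the assembled feature vector, in assembly order."""
    layout: dict[str, slice] = {}
    pos = 0

    def block(name: str, length: int) -> None:
        nonlocal pos
        layout[name] = slice(pos, pos + length)
        pos += length

    block("local", num_local)
    block("stencil", len(variant.stencil) * num_classes)
    if variant.use_integral:
        block("integral", 2 * num_classes)
    if with_atlas:
        block("atlas", len(variant.stencil) * num_classes)
    return layout


def assemble_features(
    local: FeatureGrid,
    probs: ProbabilityMap,
    atlas: Atlas | None,
    location,
    variant: VariantConfig,
    expect_atlas: bool | None = None,
) -> np.ndarray:
    """Feature vector for a single foreground cell.

    Concatenation order: local appearance features, stencil context on the
    probability map, integral context (if the variant uses it), stencil
    context on the weighted atlas (if the variant uses one and
    ``expect_atlas``; defaults to the variant's atlas flag).
    """
    if expect_atlas is None:
        expect_atlas = variant.use_weighted_atlas
    if local.shape != probs.shape:
        raise GridCompatibilityError(
            f"feature grid {local.shape} and probability map {probs.shape} differ"
        )
    row, col = location
    parts = [local.values[row, col]]
    parts.append(stencil_context(probs, location, variant.stencil))
    if variant.use_integral:
        parts.append(integral_context(probs, location))
    if expect_atlas and variant.use_weighted_atlas:
        if atlas is None:
            raise MissingAtlasError(
                f"variant {variant.name!r} requires a weighted atlas at this iteration"
            )
        parts.append(stencil_context(atlas.probability_map, location, variant.stencil))
    return np.concatenate(parts)


def sample_training_locations(
    maps: Sequence[LabelMap], per_class: int, seed: int
) -> list[tuple[int, int, int, int]]:
    """Stratified sample of foreground cells: ``per_class`` per class.

    Returns (map_index, row, col, label) tuples, uniform without
    replacement within each class across the whole pool (with replacement
    only if a class has fewer cells than ``per_class``). Deterministic
    given the seed.
    """
    maps = list(maps)
    if not maps:
        raise StratificationError("empty training pool")
    k = maps[0].num_classes
    names = maps[0].class_names
    per_class_cells: list[list[np.ndarray]] = [[] for _ in range(k)]
    for idx, lm in enumerate(maps):
        labels = lm.labels
        for c in range(1, k + 1):
            rows, cols = np.nonzero(labels == c)
            if rows.size:
                cells = np.column_stack(
                    [np.full(rows.size, idx), rows, cols, np.full(rows.size, c)]
                )
                per_class_cells[c - 1].append(cells)
    rng = derive_rng(seed, ROLE_SAMPLING)
    out: list[tuple[int, int, int, int]] = []
    for c in range(1, k + 1):
        chunks = per_class_cells[c - 1]
        if not chunks:
            raise StratificationError(
                f"class {c} ({names[c - 1]!r}) has no foreground cells in the pool"
            )
        cells = np.concatenate(chunks, axis=0)
        replace_draw = cells.shape[0] < per_class
        chosen = rng.choice(cells.shape[0], size=per_class, replace=replace_draw)
        out.extend(tuple(int(v) for v in cells[i]) for i in chosen)
    return out


def argmax_labels(probs: ProbabilityMap) -> LabelMap:
    """Hard labels by per-cell arg-max (lowest class index wins ties)."""
    labels = np.zeros(probs.shape, dtype=np.int64)
    fg = probs.foreground
    labels[fg] = np.argmax(probs.probs[fg], axis=1) + 1
    return LabelMap(labels, fg, probs.class_names)


# ---------------------------------------------------------------------------
# internal per-image state used by training and inference


class _ImageState:
    """Cached per-image arrays: features at foreground cells, labels, mask."""

    def __init__(self, feature_grid: FeatureGrid, mask: np.ndarray,
                 label_map: LabelMap | None, identifier: str):
        self.features = feature_grid
        self.mask = np.asarray(mask, dtype=bool)
        self.labels = label_map
        self.identifier = identifier
        self.fg_rows, self.fg_cols = np.nonzero(self.mask)
        self.local_fg = feature_grid.values[self.fg_rows, self.fg_cols]

    def feature_matrix(self, probs: ProbabilityMap, atlas: Atlas | None,
                       variant: VariantConfig, with_atlas: bool) -> np.ndarray:
        blocks = [self.local_fg]
        ctx = stencil_context_map(probs, variant.stencil)
        blocks.append(ctx[self.fg_rows, self.fg_cols])
        if variant.use_integral:
            integral = integral_context_map(probs)
            blocks.append(integral[self.fg_rows, self.fg_cols])
        if with_atlas:
            if atlas is None:
                raise MissingAtlasError("weighted atlas required but not available")
            actx = stencil_context_map(atlas.probability_map, variant.stencil)
            blocks.append(actx[self.fg_rows, self.fg_cols])
        x = np.concatenate(blocks, axis=1)
        if not np.all(np.isfinite(x)):
            names = ["local", "stencil", "integral", "atlas"]
            offset = 0
            for name, b in zip(names, blocks):
                if not np.all(np.isfinite(b)):
                    raise FeatureSanityError(f"non-finite values in {name!r} feature block")
                offset += b.shape[1]
            raise FeatureSanityError("non-finite feature values")
        return x

    def prob_map(self, flat_probs: np.ndarray, class_names) -> ProbabilityMap:
        k = flat_probs.shape[1]
        probs = np.full((*self.mask.shape, k), 1.0 / k)
        probs[self.fg_rows, self.fg_cols] = flat_probs
        # guard against tiny negative / drifted rows from the classifier
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=2, keepdims=True)
        return ProbabilityMap(probs, self.mask, class_names)


def _prepare_states(
    samples: Sequence, decomposition: DecompositionConfig | None, *, training: bool
) -> list[_ImageState]:
    """Normalise (image, label_map[, mask]) tuples into cached states."""
    states = []
    for idx, sample in enumerate(samples):
        if len(sample) == 3:
            image, label_map, mask = sample
        else:
            image, label_map = sample
            mask = label_map.foreground
        if not isinstance(image, Image):
            image = Image(np.asarray(image), getattr(label_map, "identifier", f"img_{idx}"))
        grid = appearance_features(image, decomposition)
        if label_map is not None and grid.shape != label_map.shape:
            raise GridCompatibilityError(
                f"feature grid {grid.shape} does not match label grid {label_map.shape} "
                f"for image {image.identifier!r}; check the subsample factor"
            )
        ident = label_map.identifier if label_map is not None else image.identifier
        states.append(_ImageState(grid, mask, label_map, ident or f"img_{idx}"))
    return states


def _unique_identifiers(label_maps: Sequence[LabelMap]) -> list[LabelMap]:
    """Ensure usable, unique identifiers (needed for atlas self-exclusion)."""
    seen: set[str] = set()
    out = []
    for idx, lm in enumerate(label_maps):
        ident = lm.identifier or f"map_{idx:04d}"
        if ident in seen:
            ident = f"{ident}#{idx}"
        seen.add(ident)
        out.append(LabelMap(lm.labels, lm.foreground, lm.class_names, ident))
    return out


def train_sequence(
    samples: Sequence,
    variant: VariantConfig,
    decomposition: DecompositionConfig | None = None,
) -> ModelSequence:
    """Train the T-iteration classifier sequence on annotated images.

    ``samples`` is a sequence of (image, label_map) or (image, label_map,
    mask) tuples whose label maps share one grid. The prior atlas seeds
    every probability map; each iteration trains on stratified sampled
    locations and then refreshes every training image's probability map by
    full-image prediction (and, for WAAC variants, its self-excluded
    weighted atlas).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("training needs at least 2 annotated images")
    if decomposition is None:
        decomposition = DecompositionConfig(subsample_factor=1)
    label_maps = _unique_identifiers([s[1] for s in samples])
    samples = [(s[0], lm, *s[2:]) for s, lm in zip(samples, label_maps)]
    first = label_maps[0]
    for lm in label_maps[1:]:
        check_same_grid(first, lm)
    states = _prepare_states(samples, decomposition, training=True)
    class_names = first.class_names
    k = len(class_names)

    prior = prior_atlas(label_maps)
    locations = sample_training_locations(
        label_maps, variant.per_class_samples, derive_seed(variant.seed, ROLE_SAMPLING)
    )
    loc_by_image: dict[int, list[tuple[int, int, int]]] = {}
    for j, (map_idx, row, col, label) in enumerate(locations):
        loc_by_image.setdefault(map_idx, []).append((j, row, col))
    y_train = np.array([loc[3] for loc in locations], dtype=np.int64)

    prob_maps = [
        ProbabilityMap.from_foreground_probs(prior.probs, st.mask, class_names)
        for st in states
    ]
    atlases: list[Atlas | None] = [None] * len(states)

    classifiers: list[PosteriorMLP] = []
    layouts: list[dict[str, slice]] = []
    history: list[float] = []
    num_local = states[0].features.num_features

    for t in range(1, variant.T + 1):
        with_atlas = variant.use_weighted_atlas and (
            t >= 2 or not variant.first_iteration_plain_ac
        )
        if with_atlas and t == 1:
            atlases = [prior] * len(states)

        per_image_x = []
        for idx, st in enumerate(states):
            x_full = st.feature_matrix(prob_maps[idx], atlases[idx], variant, with_atlas)
            per_image_x.append(x_full)
        width = per_image_x[0].shape[1]
        x_train = np.empty((len(locations), width))
        cell_index = [
            {(int(r), int(c)): i for i, (r, c) in
             enumerate(zip(st.fg_rows, st.fg_cols))}
            for st in states
        ]
        for map_idx, rows in loc_by_image.items():
            lookup = cell_index[map_idx]
            for j, row, col in rows:
                x_train[j] = per_image_x[map_idx][lookup[(row, col)]]

        clf = PosteriorMLP(variant.hidden_units, variant.l2, variant.max_iter, variant.tol)
        clf.fit(x_train, y_train, derive_seed(variant.seed, ROLE_CLASSIFIER, t))
        classifiers.append(clf)
        layouts.append(feature_layout(variant, num_local, k, with_atlas))

        train_pred = np.argmax(clf.predict_proba(x_train), axis=1) + 1
        acc = float(np.mean(train_pred == y_train))
        history.append(acc)
        logger.info("iteration %d/%d: training accuracy %.3f", t, variant.T, acc)

        for idx, st in enumerate(states):
            flat = clf.predict_proba(per_image_x[idx])
            prob_maps[idx] = st.prob_map(flat, class_names)
        if variant.use_weighted_atlas:
            atlases = [
                weighted_atlas(label_maps, prob_maps[idx], variant.m_w,
                               exclude=label_maps[idx].identifier)
                for idx in range(len(states))
            ]

    return ModelSequence(
        classifiers=classifiers,
        feature_layouts=layouts,
        variant=variant,
        prior=prior,
        class_names=class_names,
        training_pool=tuple(lm.identifier for lm in label_maps),
        training_label_maps=label_maps,
        training_history=history,
        decomposition=decomposition,
    )


def apply_model(
    model: ModelSequence,
    image,
    mask: np.ndarray,
    candidates: Sequence[LabelMap] | None = None,
) -> tuple[list[ProbabilityMap], list[Atlas | None]]:
    """Run the trained sequence on one image.

    Returns the per-iteration probability maps (length T) and the
    per-iteration weighted atlases (``None`` entries where no atlas was
    computed). The initial map is the training prior atlas resampled to
    the test grid; WAAC variants recompute the weighted atlas from every
    iteration's output with no exclusion.
    """
    variant = model.variant
    if variant.use_weighted_atlas:
        if candidates is None:
            candidates = model.training_label_maps
        if not candidates:
            raise MissingAtlasError(
                "WAAC inference needs candidate label maps (the training pool)"
            )
    state = _prepare_states([(image, None, mask)], model.decomposition,
                            training=False)[0]
    class_names = model.class_names
    grid_shape = state.mask.shape
    prior_map = model.prior.probability_map
    if prior_map.shape != grid_shape:
        prior_map = resample_nearest(prior_map, grid_shape, foreground=state.mask)
    else:
        prior_map = ProbabilityMap.from_foreground_probs(
            prior_map.probs, state.mask, class_names
        )
    if variant.use_weighted_atlas and candidates is not None:
        for c in candidates:
            if c.shape != grid_shape:
                raise GridCompatibilityError(
                    f"candidate {c.identifier!r} grid {c.shape} does not match "
                    f"test grid {grid_shape}"
                )

    probs = prior_map
    atlas: Atlas | None = None
    out_maps: list[ProbabilityMap] = []
    out_atlases: list[Atlas | None] = []
    for t in range(1, model.num_iterations + 1):
        layout = model.feature_layouts[t - 1]
        with_atlas = "atlas" in layout
        if with_atlas and atlas is None:
            atlas = model.prior if prior_map.shape == model.prior.shape else Atlas(
                prior_map, model.prior.provenance
            )
        x = state.feature_matrix(probs, atlas, variant, with_atlas)
        flat = model.classifiers[t - 1].predict_proba(x)
        probs = state.prob_map(flat, class_names)
        out_maps.append(probs)
        if variant.use_weighted_atlas:
            atlas = weighted_atlas(candidates, probs, variant.m_w)
            out_atlases.append(atlas)
        else:
            out_atlases.append(None)
    return out_maps, out_atlases


def predict_sequence(
    model: ModelSequence,
    image,
    mask: np.ndarray,
    candidates: Sequence[LabelMap] | None = None,
) -> list[ProbabilityMap]:
    """Per-iteration probability maps for one test image (length T)."""
    maps, _ = apply_model(model, image, mask, candidates)
    return maps
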