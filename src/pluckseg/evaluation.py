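"""Segmentation metrics and the cross-validation harness.

Organ-level evaluation uses the Dice coefficient 2|X∩Y|/(|X|+|Y|) per
class, with classes absent from the ground truth excluded from the
medians. Pixel-level evaluation uses the confusion matrix of hard
assignments (rows = ground truth, columns = predicted) and the quadratic
proper scoring rule Q(r, i) = 2·r_i − r·r averaged over foreground cells,
where r is the predicted distribution and i the true class (1 for a
confident correct prediction, −1 for a confident wrong one, 2/K − 1/K for
a uniform one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import ROLE_CLASSIFIER, ROLE_FOLDS, derive_rng, derive_seed
from .errors import GridCompatibilityError
from .features import DecompositionConfig
from .grids import LabelMap, ProbabilityMap, check_same_grid, require_foreground
from .model import (
    ModelSequence,
    VariantConfig,
    apply_model,
    argmax_labels,
    train_sequence,
)

__all__ = [
    "dice",
    "quadratic_score",
    "confusion",
    "pixel_accuracy",
    "DiceReport",
    "ScoreReport",
    "CrossValResult",
    "cross_validate",
]


def dice(reference: LabelMap, predicted: LabelMap) -> dict[str, float | None]:
    """Per-class Dice coefficients; ``None`` marks classes absent from the reference."""
    check_same_grid(reference, predicted)
    k = reference.num_classes
    out: dict[str, float | None] = {}
    for c in range(1, k + 1):
        ref_region = reference.labels == c
        pred_region = predicted.labels == c
        ref_size = int(ref_region.sum())
        pred_size = int(pred_region.sum())
        name = reference.class_names[c - 1]
        if ref_size == 0:
            out[name] = None
            continue
        inter = int((ref_region & pred_region).sum())
        out[name] = 2.0 * inter / (ref_size + pred_size)
    return out


def quadratic_score(probs: ProbabilityMap, reference: LabelMap) -> float:
    """Mean over foreground cells of 2·r_true − Σ_c r_c²."""
    check_same_grid(probs, reference)
    require_foreground(reference.foreground)
    fg = reference.foreground
    p = probs.probs[fg]
    true_idx = reference.labels[fg] - 1
    r_true = p[np.arange(p.shape[0]), true_idx]
    return float(np.mean(2.0 * r_true - np.sum(p * p, axis=1)))


def confusion(reference: LabelMap, predicted: LabelMap) -> np.ndarray:
    """K×K counts over foreground cells; rows = ground truth, columns = predicted."""
    check_same_grid(reference, predicted)
    k = reference.num_classes
    both = reference.foreground & predicted.foreground
    ref = reference.labels[both] - 1
    pred = predicted.labels[both] - 1
    return np.bincount(ref * k + pred, minlength=k * k).reshape(k, k)


def pixel_accuracy(reference: LabelMap, predicted: LabelMap) -> float:
    """Fraction of foreground cells with matching labels."""
    check_same_grid(reference, predicted)
    both = reference.foreground & predicted.foreground
    require_foreground(both)
    return float(np.mean(reference.labels[both] == predicted.labels[both]))


@dataclass(frozen=True)
class DiceReport:
    """Per-image/per-class Dice table with the headline aggregates.

    ``per_class_median`` is the median over images where the class is
    present in the ground truth; ``class_average`` is the mean of those K
    medians.
    """

    per_image_per_class: pd.DataFrame
    per_class_median: dict[str, float]
    class_average: float


@dataclass(frozen=True)
class ScoreReport:
    """Pixel-level results: quadratic scores, accuracies and the confusion matrix."""

    per_image: pd.DataFrame
    median_quadratic: float
    confusion: np.ndarray
    class_names: tuple[str, ...]
    median_accuracy: float
    median_baseline_accuracy: float


@dataclass(frozen=True)
class CrossValResult:
    variant: str
    dice_report: DiceReport
    score_report: ScoreReport
    fold_assignment: dict[str, int]
    training_histories: list[list[float]]


def _aggregate_dice(rows: list[dict]) -> DiceReport:
    table = pd.DataFrame(rows, columns=["image_id", "class", "dice"])
    medians: dict[str, float] = {}
    for name, group in table.groupby("class", sort=False):
        present = group["dice"].dropna()
        medians[name] = float(present.median()) if len(present) else float("nan")
    class_average = float(np.nanmean(list(medians.values()))) if medians else float("nan")
    return DiceReport(table, medians, class_average)


def evaluate_predictions(
    references: Sequence[LabelMap],
    predictions: Sequence[ProbabilityMap],
    baselines: Sequence[LabelMap] | None = None,
) -> tuple[DiceReport, ScoreReport]:
    """Dice and pixel-level reports for matched reference/prediction pairs."""
    dice_rows: list[dict] = []
    score_rows: list[dict] = []
    k = references[0].num_classes
    names = references[0].class_names
    conf = np.zeros((k, k), dtype=np.int64)
    for i, (ref, probs) in enumerate(zip(references, predictions)):
        pred_labels = argmax_labels(probs)
        d = dice(ref, pred_labels)
        for name in names:
            dice_rows.append(
                {"image_id": ref.identifier, "class": name, "dice": d[name]}
            )
        conf += confusion(ref, pred_labels)
        row = {
            "image_id": ref.identifier,
            "quadratic": quadratic_score(probs, ref),
            "accuracy": pixel_accuracy(ref, pred_labels),
        }
        if baselines is not None:
            row["baseline_accuracy"] = pixel_accuracy(ref, baselines[i])
        score_rows.append(row)
    per_image = pd.DataFrame(score_rows)
    score = ScoreReport(
        per_image=per_image,
        median_quadratic=float(per_image["quadratic"].median()),
        confusion=conf,
        class_names=names,
        median_accuracy=float(per_image["accuracy"].median()),
        median_baseline_accuracy=(
            float(per_image["baseline_accuracy"].median())
            if baselines is not None
            else float("nan")
        ),
    )
    return _aggregate_dice(dice_rows), score


def cross_validate(
    dataset: Sequence,
    variant: VariantConfig,
    folds: int,
    seed: int,
    decomposition: DecompositionConfig | None = None,
) -> CrossValResult:
    """k-fold cross-validation of one auto-context variant.

    ``dataset`` is a sequence of (image, label_map) pairs. Images are
    shuffled deterministically from the seed and split into ``folds``
    subsets; each fold is predicted by a model trained on the others. The
    baseline for each image is the arg-max of the training prior atlas.
    """
    dataset = list(dataset)
    if len(dataset) < folds:
        raise ValueError("dataset must contain at least `folds` images")
    rng = derive_rng(seed, ROLE_FOLDS)
    order = rng.permutation(len(dataset))
    fold_indices = np.array_split(order, folds)

    fold_assignment: dict[str, int] = {}
    references: list[LabelMap] = []
    predictions: list[ProbabilityMap] = []
    baselines: list[LabelMap] = []
    histories: list[list[float]] = []

    for f, test_idx in enumerate(fold_indices):
        train_idx = np.setdiff1d(order, test_idx)
        train_samples = [dataset[i] for i in train_idx]
        fold_variant = dc_replace(variant, seed=derive_seed(seed, variant.seed, f))
        model = train_sequence(train_samples, fold_variant, decomposition)
        histories.append(model.training_history)
        test_refs = [dataset[i][1] for i in test_idx]
        present_train = {
            c for lm in (dataset[i][1] for i in train_idx)
            for c in np.unique(lm.labels[lm.foreground])
        }
        for ref in test_refs:
            missing = set(np.unique(ref.labels[ref.foreground])) - present_train
            if missing:
                warnings.warn(
                    f"fold {f}: classes {sorted(missing)} present in test image "
                    f"{ref.identifier!r} but absent from the training pool",
                    stacklevel=2,
                )
        for i in test_idx:
            image, ref = dataset[i][0], dataset[i][1]
            fold_assignment[ref.identifier] = f
            maps = apply_model(model, image, ref.foreground)[0]
            final = maps[-1]
            prior_probs = ProbabilityMap.from_foreground_probs(
                model.prior.probs, ref.foreground, ref.class_names
            )
            references.append(ref)
            predictions.append(final)
            baselines.append(argmax_labels(prior_probs))

    dice_report, score_report = evaluate_predictions(references, predictions, baselines)
    return CrossValResult(
        variant=variant.name,
        dice_report=dice_report,
        score_report=score_report,
        fold_assignment=fold_assignment,
        training_histories=histories,
    )
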