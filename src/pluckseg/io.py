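"""File-format conventions.

Images: PNG/TIFF sRGB. Label maps: indexed PNG, index 0 = background,
1..K = classes (palette = class colours). Masks: binary PNG (0/255).
Probability maps and atlases: multi-channel 32-bit float TIFF, one page
per class in class order, with a JSON sidecar (class names, shape) and a
mask PNG. Models: a directory with one serialized classifier per
iteration, a metadata JSON and the prior atlas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import joblib
import numpy as np
import tifffile
from PIL import Image as PILImage

from .atlas import Atlas
from .context import StencilSpec
from .features import DecompositionConfig
from .grids import Image, LabelMap, ProbabilityMap
from .model import ModelSequence, VariantConfig
from .synthetic import CLASS_NAMES, DEFAULT_COLOURS, PluckSample

__all__ = [
    "save_image", "load_image",
    "save_label_map", "load_label_map",
    "save_mask", "load_mask",
    "save_probability_map", "load_probability_map",
    "save_model", "load_model",
    "write_dataset", "load_dataset",
]


def save_image(path, image: Image | np.ndarray) -> None:
    pixels = getattr(image, "pixels", image)
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))


def load_image(path) -> Image:
    path = Path(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    return Image(pixels, path.stem)


def _palette(class_names: Sequence[str]) -> list[int]:
    flat = list(int(v) for v in DEFAULT_COLOURS["background"])
    for name in class_names:
        colour = DEFAULT_COLOURS.get(name, (255, 255, 255))
        flat.extend(int(v) for v in colour)
    flat.extend([0] * (768 - len(flat)))
    return flat


def save_label_map(path, label_map: LabelMap) -> None:
    im = PILImage.fromarray(label_map.labels.astype(np.uint8), mode="P")
    im.putpalette(_palette(label_map.class_names))
    im.save(Path(path))


def load_label_map(path, class_names: Sequence[str] = CLASS_NAMES) -> LabelMap:
    path = Path(path)
    labels = np.asarray(PILImage.open(path), dtype=np.int64)
    return LabelMap.from_labels(labels, tuple(class_names), path.stem)


def save_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_probability_map(path, pmap: ProbabilityMap) -> None:
    """Write `<stem>.tif` (K float32 pages), `<stem>.json`, `<stem>.mask.png`."""
    path = Path(path)
    stem = path.with_suffix("")
    tifffile.imwrite(
        stem.with_suffix(".tif"),
        np.moveaxis(pmap.probs.astype(np.float32), 2, 0),
    )
    stem.with_suffix(".json").write_text(json.dumps({
        "class_names": list(pmap.class_names),
        "shape": list(pmap.shape),
    }, indent=2))
    save_mask(Path(str(stem) + ".mask.png"), pmap.foreground)


def load_probability_map(path) -> ProbabilityMap:
    path = Path(path)
    stem = path.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    probs = np.moveaxis(
        np.asarray(tifffile.imread(stem.with_suffix(".tif")), dtype=np.float64), 0, 2
    )
    mask = load_mask(Path(str(stem) + ".mask.png"))
    return ProbabilityMap.from_foreground_probs(probs, mask, tuple(meta["class_names"]))


def save_model(directory, model: ModelSequence) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, clf in enumerate(model.classifiers, start=1):
        joblib.dump(clf, directory / f"classifier_{t:02d}.joblib")
    variant = model.variant
    meta = {
        "class_names": list(model.class_names),
        "training_pool": list(model.training_pool),
        "training_history": model.training_history,
        "feature_layouts": [
            {name: [s.start, s.stop] for name, s in layout.items()}
            for layout in model.feature_layouts
        ],
        "variant": {
            "use_integral": variant.use_integral,
            "use_weighted_atlas": variant.use_weighted_atlas,
            "T": variant.T,
            "m_w": variant.m_w,
            "per_class_samples": variant.per_class_samples,
            "seed": variant.seed,
            "first_iteration_plain_ac": variant.first_iteration_plain_ac,
            "hidden_units": variant.hidden_units,
            "l2": variant.l2,
            "max_iter": variant.max_iter,
            "tol": variant.tol,
            "stencil_offsets": [list(o) for o in variant.stencil.offsets],
        },
        "decomposition": None if model.decomposition is None else {
            "levels": model.decomposition.levels,
            "subsample_factor": model.decomposition.subsample_factor,
            "square_details": model.decomposition.square_details,
        },
        "prior_provenance": [list(p) for p in model.prior.provenance],
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    save_probability_map(directory / "prior_atlas.tif", model.prior.probability_map)
    pool_dir = directory / "pool"
    pool_dir.mkdir(exist_ok=True)
    for lm in model.training_label_maps:
        save_label_map(pool_dir / f"{lm.identifier}.png", lm)


def load_model(directory) -> ModelSequence:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    v = meta["variant"]
    stencil = StencilSpec(tuple(tuple(o) for o in v.pop("stencil_offsets")))
    variant = VariantConfig(stencil=stencil, **v)
    classifiers = [
        joblib.load(p) for p in sorted(directory.glob("classifier_*.joblib"))
    ]
    layouts = [
        {name: slice(lo, hi) for name, (lo, hi) in layout.items()}
        for layout in meta["feature_layouts"]
    ]
    prior_map = load_probability_map(directory / "prior_atlas.tif")
    prior = Atlas(prior_map, tuple(
        (str(i), float(w)) for i, w in meta["prior_provenance"]
    ))
    class_names = tuple(meta["class_names"])
    pool = [
        load_label_map(directory / "pool" / f"{ident}.png", class_names)
        for ident in meta["training_pool"]
    ]
    decomp = meta.get("decomposition")
    decomposition = None if decomp is None else DecompositionConfig(**decomp)
    return ModelSequence(
        classifiers=classifiers,
        feature_layouts=layouts,
        variant=variant,
        prior=prior,
        class_names=class_names,
        training_pool=tuple(meta["training_pool"]),
        training_label_maps=pool,
        training_history=list(meta["training_history"]),
        decomposition=decomposition,
    )


def write_dataset(directory, samples: Sequence[PluckSample], manifest) -> None:
    """Write images/, labels/, masks/ and manifest.csv for a generated dataset."""
    directory = Path(directory)
    for sub in ("images", "labels", "masks"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    for s in samples:
        ident = s.labels.identifier
        save_image(directory / "images" / f"{ident}.png", s.image)
        save_label_map(directory / "labels" / f"{ident}.png", s.labels)
        save_mask(directory / "masks" / f"{ident}.png", s.mask)
    manifest.to_csv(directory / "manifest.csv", index=False)


def load_dataset(directory, class_names: Sequence[str] = CLASS_NAMES):
    """Load (image, label_map) pairs written by :func:`write_dataset`."""
    directory = Path(directory)
    pairs = []
    for label_path in sorted((directory / "labels").glob("*.png")):
        ident = label_path.stem
        image = load_image(directory / "images" / f"{ident}.png")
        labels = load_label_map(label_path, class_names)
        pairs.append((image, labels))
    if not pairs:
        raise FileNotFoundError(f"no label maps found under {directory}/labels")
    return pairs
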