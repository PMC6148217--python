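"""Synthetic pluck generator: image / label-map / mask triples.

A pluck is the inter-connected group of organs (trachea and tongue
"upper", heart, lungs, diaphragm, liver) removed from a pig carcass and
hung vertically from a hook. The generator emulates the structural
regularities the segmentation methods rely on:

* the object hangs from the top row, so the vertical ordering of parts is
  consistent (upper, then lungs with an embedded heart, then diaphragm,
  then liver) while horizontal placement varies;
* the camera-facing aspect is uncontrolled: ``orientation`` ∈ [−1, 1]
  slides the heart ellipse sideways out of the silhouette, so its visible
  area shrinks to zero as |orientation| → 1 (a dorsal view), and the
  visible diaphragm band thins with |orientation| in the same way — a
  hidden heart co-occurs with a small visible diaphragm;
* the liver is very rarely missing altogether (default rate 2%);
* per-class colours are distinct in hue but overlap under texture noise —
  heart and liver in particular are deliberately close, so local colour
  alone cannot separate them and contextual features carry real signal.

Shapes are parametric band/ellipse compositions, not anatomical meshes;
the consumers of these images use colour statistics and spatial layout
only. Background is a distinct dark colour and the true mask is emitted
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._seeds import ROLE_DATASET, derive_seed
from .errors import LayoutError
from .grids import Image, LabelMap

__all__ = [
    "CLASS_NAMES",
    "PluckParams",
    "PluckSample",
    "generate_pluck",
    "generate_dataset",
]

CLASS_NAMES = ("upper", "heart", "lungs", "diaphragm", "liver")
UPPER, HEART, LUNGS, DIAPHRAGM, LIVER = 1, 2, 3, 4, 5

#: Mean sRGB colour per class. Heart and liver are near neighbours by
#: design so appearance alone cannot separate them.
DEFAULT_COLOURS: dict[str, tuple[float, float, float]] = {
    "background": (18.0, 18.0, 24.0),
    "upper": (205.0, 170.0, 150.0),
    "heart": (146.0, 44.0, 48.0),
    "lungs": (225.0, 122.0, 126.0),
    "diaphragm": (172.0, 96.0, 76.0),
    "liver": (142.0, 46.0, 50.0),
}


@dataclass(frozen=True)
class PluckParams:
    """Knobs of a single synthetic pluck.

    grid_size: (h, w) of the working grid (default 180×60).
    orientation: −1..1, dorsal↔ventral aspect; |orientation| → 1 hides
        the heart and thins the visible diaphragm.
    liver_missing_prob: probability the liver is absent entirely.
    noise_sd: per-pixel Gaussian texture noise, 8-bit scale.
    colour_jitter_sd: per-image, per-class colour offset spread.
    specular_rate: per-pixel rate of near-white specular speckles.
    """

    grid_size: tuple[int, int] = (180, 60)
    orientation: float = 0.0
    liver_missing_prob: float = 0.02
    noise_sd: float = 9.0
    colour_jitter_sd: float = 8.0
    specular_rate: float = 0.004
    colours: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COLOURS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.grid_size
        if h < 40 or w < 20:
            raise LayoutError(f"grid {h}×{w} too small; need at least 40×20")
        if not -1.0 <= self.orientation <= 1.0:
            raise ValueError("orientation must lie in [-1, 1]")
        if not 0.0 <= self.liver_missing_prob <= 1.0:
            raise ValueError("liver_missing_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PluckSample:
    """One generated pluck: image, labels, mask and bookkeeping."""

    image: Image
    labels: LabelMap
    mask: np.ndarray
    presence: dict[str, bool]
    params_used: PluckParams


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, sigma: float) -> np.ndarray:
    return gaussian_filter1d(rng.normal(0.0, sd, size=n), sigma, mode="nearest")


def generate_pluck(params: PluckParams) -> PluckSample:
    """Render one pluck, fully determined by ``params.seed``."""
    h, w = params.grid_size
    rng = np.random.default_rng(params.seed)
    o = float(params.orientation)
    vis = 1.0 - abs(o)

    # vertical partition (row fractions), lightly jittered
    upper_frac = float(np.clip(rng.normal(0.16, 0.02), 0.10, 0.22))
    lungs_frac = float(np.clip(rng.normal(0.40, 0.03), 0.32, 0.48))
    dia_base = float(np.clip(rng.normal(0.12, 0.015), 0.08, 0.16))
    dia_frac = dia_base * (0.35 + 0.65 * vis)
    bottom_frac = float(np.clip(rng.normal(0.93, 0.02), 0.86, 0.99))
    liver_missing = bool(rng.random() < params.liver_missing_prob)

    r1 = max(2, round(h * upper_frac))
    r2 = r1 + max(4, round(h * lungs_frac))
    r3 = r2 + max(2, round(h * dia_frac))
    r4 = max(r3 + 3, round(h * bottom_frac))
    last_row = r3 if liver_missing else min(r4, h)
    if last_row > h or r3 >= h:
        raise LayoutError(f"parts do not fit on a grid of height {h}")

    # silhouette: centre line with a slow wobble, zone-dependent half-width
    cx = w / 2.0 + rng.normal(0.0, w * 0.02)
    centre = cx + _smooth_noise(rng, h, w * 0.03, h / 25.0)
    half = np.empty(h)
    half[:r1] = 0.18 * w
    half[r1:r2] = 0.42 * w
    half[r2:r3] = 0.36 * w
    half[r3:] = 0.40 * w
    half = gaussian_filter1d(half, h / 45.0, mode="nearest")
    half += _smooth_noise(rng, h, w * 0.015, h / 30.0)
    half = np.clip(half, 0.10 * w, 0.48 * w)

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    mask = (np.abs(cols - centre[:, None]) <= half[:, None]) & (rows < last_row)
    if not mask[: r1].any() or not mask[r1:r2].any() or not mask[r2:r3].any():
        raise LayoutError("a mandatory part has no foreground cells")

    labels = np.zeros((h, w), dtype=np.int64)
    labels[mask & (rows < r1)] = UPPER
    labels[mask & (rows >= r1) & (rows < r2)] = LUNGS
    labels[mask & (rows >= r2) & (rows < r3)] = DIAPHRAGM
    if not liver_missing:
        labels[mask & (rows >= r3)] = LIVER

    # heart: ellipse inside the lungs band, slid sideways by orientation so
    # that at |orientation| = 1 it clears the silhouette entirely
    heart_rc = (r1 + r2) / 2.0 + rng.normal(0.0, (r2 - r1) * 0.05)
    a_r = 0.30 * (r2 - r1)
    a_c = float(np.clip(rng.normal(0.16, 0.015), 0.12, 0.20)) * w
    hw_at_heart = float(half[int(round(np.clip(heart_rc, 0, h - 1)))])
    heart_cc = centre[int(round(np.clip(heart_rc, 0, h - 1)))] + o * (hw_at_heart + a_c + 1.0)
    ellipse = ((rows - heart_rc) / a_r) ** 2 + ((cols - heart_cc) / a_c) ** 2 <= 1.0
    heart_region = ellipse & (labels == LUNGS)
    labels[heart_region] = HEART

    presence = {
        "upper": bool((labels == UPPER).any()),
        "heart": bool((labels == HEART).any()),
        "lungs": bool((labels == LUNGS).any()),
        "diaphragm": bool((labels == DIAPHRAGM).any()),
        "liver": bool((labels == LIVER).any()),
    }

    # render: per-class colour + per-image jitter + texture noise + speculars
    jitter = {
        name: rng.normal(0.0, params.colour_jitter_sd, size=3)
        for name in ("upper", "heart", "lungs", "diaphragm", "liver")
    }
    image = np.empty((h, w, 3))
    image[:] = params.colours["background"]
    for value, name in zip(
        (UPPER, HEART, LUNGS, DIAPHRAGM, LIVER), CLASS_NAMES
    ):
        region = labels == value
        if region.any():
            image[region] = np.asarray(params.colours[name]) + jitter[name]
    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=image.shape)
    if params.specular_rate > 0:
        spec = (rng.random((h, w)) < params.specular_rate) & mask
        image[spec] = rng.uniform(235.0, 255.0, size=(int(spec.sum()), 3))
    image = np.clip(image, 0.0, 255.0).astype(np.uint8)

    ident = f"pluck_{params.seed:08d}"
    return PluckSample(
        image=Image(image, ident),
        labels=LabelMap(labels, mask, CLASS_NAMES, ident),
        mask=mask,
        presence=presence,
        params_used=params,
    )


def generate_dataset(
    n: int,
    base_params: PluckParams | None = None,
    seed: int = 0,
    orientation_range: tuple[float, float] = (-1.0, 1.0),
) -> tuple[list[PluckSample], pd.DataFrame]:
    """Draw ``n`` plucks with per-sample orientation and colour variation.

    Orientation is uniform over ``orientation_range``; presence events and
    colour jitter are drawn inside each sample from its derived seed. The
    manifest records identifier, orientation and per-class presence.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if base_params is None:
        base_params = PluckParams()
    rng = np.random.default_rng(derive_seed(seed, ROLE_DATASET))
    samples: list[PluckSample] = []
    rows: list[dict] = []
    for i in range(n):
        orientation = float(rng.uniform(*orientation_range))
        sample_seed = derive_seed(seed, ROLE_DATASET, i + 1)
        params = replace(base_params, orientation=orientation, seed=sample_seed)
        sample = generate_pluck(params)
        ident = f"pluck_{i:04d}"
        sample = PluckSample(
            image=Image(sample.image.pixels, ident),
            labels=LabelMap(sample.labels.labels, sample.mask, CLASS_NAMES, ident),
            mask=sample.mask,
            presence=sample.presence,
            params_used=params,
        )
        samples.append(sample)
        rows.append({"image_id": ident, "orientation": orientation,
                     **{f"has_{k}": v for k, v in sample.presence.items()}})
    manifest = pd.DataFrame(rows)
    return samples, manifest
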