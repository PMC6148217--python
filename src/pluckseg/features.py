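"""Local appearance features: CIELUV conversion and multi-level Haar maps.

The appearance representation of a colour image is built in three steps:

1. convert sRGB to the perceptual CIE 1976 L*u*v* space (D65 white point);
2. for each of the three channels, run a multi-level 2-D Haar wavelet
   decomposition and keep, at every level, the approximation map and the
   *squared* horizontal, vertical and diagonal detail maps, each upscaled
   back to the original image size (nearest-neighbour, preserving the
   piecewise-constant character of Haar coefficients);
3. subsample every map by a fixed integer factor along both axes, taking
   the top-left pixel of each block (grid origin at pixel (0, 0)).

With the defaults (3 channels × 4 coefficient kinds × 3 levels) this yields
a 36-plane feature grid at the working resolution shared with the label
maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from skimage import color

from .errors import ChannelCountError, DecompositionDepthError

__all__ = [
    "DecompositionConfig",
    "FeatureGrid",
    "to_perceptual_colorspace",
    "haar_feature_grid",
]


@dataclass(frozen=True)
class DecompositionConfig:
    """Parameters of the Haar feature pipeline.

    levels: depth of the wavelet decomposition (default 3).
    subsample_factor: integer stride of the working grid (default 20).
    square_details: square the detail coefficient maps (default True);
        the approximation map is never squared.
    """

    levels: int = 3
    subsample_factor: int = 20
    square_details: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be ≥ 1")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be ≥ 1")


@dataclass(frozen=True)
class FeatureGrid:
    """h×w×F stack of appearance features on the subsampled working grid."""

    values: np.ndarray
    subsample_factor: int
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError("feature grid must be h×w×F")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature grid contains non-finite values")
        h = math.ceil(self.source_shape[0] / self.subsample_factor)
        w = math.ceil(self.source_shape[1] / self.subsample_factor)
        if values.shape[:2] != (h, w):
            raise ValueError(
                f"grid {values.shape[:2]} inconsistent with source "
                f"{self.source_shape} at factor {self.subsample_factor}"
            )
        object.__setattr__(self, "values", values)

    @property
    def num_features(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def to_perceptual_colorspace(image) -> np.ndarray:
    """Convert an sRGB image to CIE 1976 L*u*v* (D65 white point).

    Accepts an :class:`~pluckseg.grids.Image` or a raw H×W×3 array
    (uint8 in 0..255 or float in 0..1). Returns a float array with the
    L*, u*, v* channels; L* is 0 for black and 100 for reference white.
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ChannelCountError(
            f"expected a 3-channel image, got shape {pixels.shape}"
        )
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64) / 255.0
    return color.rgb2luv(pixels)


def _upsample_nearest(coeff: np.ndarray, factor: int, shape: tuple[int, int]) -> np.ndarray:
    up = np.repeat(np.repeat(coeff, factor, axis=0), factor, axis=1)
    return up[: shape[0], : shape[1]]


def haar_feature_grid(luv: np.ndarray, config: DecompositionConfig | None = None) -> FeatureGrid:
    """Multi-level Haar feature stack of a 3-channel raster.

    For each channel and each level ℓ the approximation map plus the
    horizontal, vertical and diagonal detail maps are computed by applying
    the 2-D Haar transform recursively to the previous approximation
    (symmetric boundary padding). Detail maps are squared; every map is
    upscaled back to H×W by nearest-neighbour and the stack is subsampled
    by ``config.subsample_factor``.

    Plane order: channel-major, then level, then (approximation,
    horizontal², vertical², diagonal²).
    """
    if config is None:
        config = DecompositionConfig()
    luv = np.asarray(luv, dtype=np.float64)
    if luv.ndim != 3 or luv.shape[2] != 3:
        raise ChannelCountError(f"expected 3 channels, got shape {luv.shape}")
    if not np.all(np.isfinite(luv)):
        raise ValueError("input raster contains non-finite values")
    h, w = luv.shape[:2]
    if min(h, w) < 2 ** config.levels:
        raise DecompositionDepthError(
            f"image {h}×{w} too small for {config.levels} decomposition levels"
        )

    planes: list[np.ndarray] = []
    for ch in range(3):
        approx = luv[:, :, ch]
        for level in range(1, config.levels + 1):
            factor = 2 ** level
            c_a, (c_h, c_v, c_d) = pywt.dwt2(approx, "haar", mode="symmetric")
            planes.append(_upsample_nearest(c_a, factor, (h, w)))
            for detail in (c_h, c_v, c_d):
                if config.square_details:
                    detail = detail ** 2
                planes.append(_upsample_nearest(detail, factor, (h, w)))
            approx = c_a

    stack = np.stack(planes, axis=2)
    f = config.subsample_factor
    return FeatureGrid(stack[::f, ::f], f, (h, w))


def appearance_features(image, config: DecompositionConfig | None = None) -> FeatureGrid:
    """Full appearance pipeline: sRGB → L*u*v* → Haar feature grid."""
    return haar_feature_grid(to_perceptual_colorspace(image), config)
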