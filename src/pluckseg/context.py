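"""Label-context features: star-stencil sampling and integral context.

The contextual input to each classifier iteration is read from the class
probability map of the previous iteration, re-centred on the query cell:

* *stencil context* — the K class probabilities at each point of a sparse
  star-shaped stencil (a set of integer (row, col) offsets including the
  centre), concatenated point-by-point. Points falling outside the grid or
  on the background contribute the uniform padding distribution.
* *integral context* — 2K values: the per-class mean over the foreground
  cells of the query's row, then the per-class mean over the whole
  foreground. On a vertically hung object the row means tell the next
  classifier which parts occur at that height, while the whole-image means
  reflect how much of each part is visible at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LocationError, StencilGeometryError
from .grids import ProbabilityMap, require_foreground, uniform_padding

__all__ = [
    "StencilSpec",
    "make_star_stencil",
    "default_stencil",
    "stencil_context",
    "stencil_context_map",
    "integral_context",
    "integral_context_map",
]

#: Default geometry: 10 equally spaced rays × 9 roughly log-spaced radii
#: (grid cells) plus the centre = 91 points.
DEFAULT_N_RAYS = 10
DEFAULT_RADII = (2, 4, 7, 11, 16, 22, 29, 37, 46)


@dataclass(frozen=True)
class StencilSpec:
    """Ordered set of integer (row, col) offsets; (0, 0) appears exactly once."""

    offsets: tuple[tuple[int, int], ...]
    includes_center: bool = True

    def __post_init__(self) -> None:
        offsets = tuple((int(r), int(c)) for r, c in self.offsets)
        if len(set(offsets)) != len(offsets):
            raise StencilGeometryError("stencil offsets are not unique")
        n_center = offsets.count((0, 0))
        if n_center != 1:
            raise StencilGeometryError(
                f"centre offset (0, 0) must appear exactly once, found {n_center}"
            )
        if not self.includes_center:
            raise StencilGeometryError("stencils must include the centre point")
        object.__setattr__(self, "offsets", offsets)

    def __len__(self) -> int:
        return len(self.offsets)


def make_star_stencil(n_rays: int, radii) -> StencilSpec:
    """Star-shaped stencil: ``n_rays`` equally spaced rays × given radii + centre.

    Offsets are ``(round(r·sin θ), round(r·cos θ))`` for each radius and each
    angle θ = 2πk/n_rays starting at 0. Radii must be strictly increasing;
    offsets that collide after rounding raise a stencil-geometry error (the
    caller must adjust the radii).
    """
    if n_rays < 1:
        raise StencilGeometryError("n_rays must be ≥ 1")
    radii = tuple(radii)
    if any(r <= 0 for r in radii):
        raise StencilGeometryError("radii must be positive")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise StencilGeometryError("radii must be strictly increasing")
    offsets: list[tuple[int, int]] = [(0, 0)]
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    for r in radii:
        for theta in angles:
            off = (int(np.rint(r * np.sin(theta))), int(np.rint(r * np.cos(theta))))
            offsets.append(off)
    return StencilSpec(tuple(offsets))


def default_stencil() -> StencilSpec:
    """The 91-point default stencil (10 rays × 9 radii + centre)."""
    return make_star_stencil(DEFAULT_N_RAYS, DEFAULT_RADII)


def _padded_with_uniform(pmap: ProbabilityMap, pad_r: int, pad_c: int) -> np.ndarray:
    k = pmap.num_classes
    probs = pmap.padded_probs()
    return np.pad(
        probs,
        ((pad_r, pad_r), (pad_c, pad_c), (0, 0)),
        mode="constant",
        constant_values=1.0 / k,
    )


def stencil_context_map(pmap: ProbabilityMap, stencil: StencilSpec) -> np.ndarray:
    """Stencil context for every cell at once: an h×w×(|stencil|·K) array.

    Row/column blocks are ordered stencil-point-major, K classes per point,
    matching :func:`stencil_context`.
    """
    h, w = pmap.shape
    pad_r = max((abs(dr) for dr, _ in stencil.offsets), default=0)
    pad_c = max((abs(dc) for _, dc in stencil.offsets), default=0)
    padded = _padded_with_uniform(pmap, pad_r, pad_c)
    blocks = [
        padded[pad_r + dr : pad_r + dr + h, pad_c + dc : pad_c + dc + w, :]
        for dr, dc in stencil.offsets
    ]
    return np.concatenate(blocks, axis=2)


def stencil_context(pmap: ProbabilityMap, location, stencil: StencilSpec) -> np.ndarray:
    """Context vector at one foreground cell: length ``|stencil| × K``.

    For each stencil offset in order, the K class probabilities at
    ``location + offset`` (padding distribution for out-of-bounds or
    background points).
    """
    row, col = location
    h, w = pmap.shape
    if not (0 <= row < h and 0 <= col < w) or not pmap.foreground[row, col]:
        raise LocationError(f"location {location!r} is not a foreground cell")
    k = pmap.num_classes
    pad = uniform_padding(k)
    out = np.empty(len(stencil) * k)
    for i, (dr, dc) in enumerate(stencil.offsets):
        r, c = row + dr, col + dc
        if 0 <= r < h and 0 <= c < w and pmap.foreground[r, c]:
            out[i * k : (i + 1) * k] = pmap.probs[r, c]
        else:
            out[i * k : (i + 1) * k] = pad
    return out


def integral_context_map(pmap: ProbabilityMap) -> np.ndarray:
    """Integral context for every cell: an h×w×2K array.

    First K planes: per-class probabilities averaged over the foreground
    cells of each row (rows without foreground get the padding
    distribution; such cells are never valid queries). Last K planes:
    per-class averages over the whole foreground, constant across cells.
    """
    require_foreground(pmap.foreground)
    h, w = pmap.shape
    k = pmap.num_classes
    fg = pmap.foreground
    masked = np.where(fg[:, :, None], pmap.probs, 0.0)
    row_counts = fg.sum(axis=1)
    row_sums = masked.sum(axis=1)
    row_means = np.full((h, k), 1.0 / k)
    has_fg = row_counts > 0
    row_means[has_fg] = row_sums[has_fg] / row_counts[has_fg, None]
    image_mean = masked.sum(axis=(0, 1)) / fg.sum()
    out = np.empty((h, w, 2 * k))
    out[:, :, :k] = row_means[:, None, :]
    out[:, :, k:] = image_mean
    return out


def integral_context(pmap: ProbabilityMap, location) -> np.ndarray:
    """2K integral-context values at one foreground cell (row block, image block)."""
    row, col = location
    h, w = pmap.shape
    if not (0 <= row < h and 0 <= col < w) or not pmap.foreground[row, col]:
        raise LocationError(f"location {location!r} is not a foreground cell")
    require_foreground(pmap.foreground)
    fg = pmap.foreground
    row_fg = fg[row]
    row_mean = pmap.probs[row][row_fg].mean(axis=0)
    image_mean = pmap.probs[fg].mean(axis=0)
    return np.concatenate([row_mean, image_mean])
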