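"""Core grid-aligned containers: images, label maps and probability maps.

All grids are 0-based, row-major, addressed as (row, col). A label map
assigns each foreground cell an integer class in ``1..K`` (0 = background);
a probability map assigns each cell a distribution over the K classes.
Background cells of a probability map hold the *padding distribution* —
uniform ``1/K`` per class — expressing maximal label uncertainty outside
the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateMaskError, GridCompatibilityError, LabelRangeError

_SUM_TOL = 1e-6


def uniform_padding(num_classes: int) -> np.ndarray:
    """The padding distribution used outside the foreground: uniform 1/K."""
    return np.full(num_classes, 1.0 / num_classes)


@dataclass(frozen=True)
class Image:
    """A colour raster with an identifier.

    ``pixels`` is H×W×3, 8-bit or float channels, interpreted as sRGB.
    """

    pixels: np.ndarray
    identifier: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise GridCompatibilityError(
                f"image must be H×W×3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise GridCompatibilityError("image must have H ≥ 1 and W ≥ 1")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class LabelMap:
    """Integer class per foreground cell; 0 on background.

    Invariant: ``labels`` is nonzero exactly on ``foreground`` and every
    nonzero value lies in ``1..K`` where ``K = len(class_names)``.
    """

    labels: np.ndarray
    foreground: np.ndarray
    class_names: tuple[str, ...]
    identifier: str = ""

    def __post_init__(self) -> None:
        labels = np.ascontiguousarray(np.asarray(self.labels, dtype=np.int64))
        fg = np.asarray(self.foreground, dtype=bool)
        names = tuple(self.class_names)
        if len(names) < 2:
            raise LabelRangeError("a label map needs K ≥ 2 classes")
        if labels.shape != fg.shape or labels.ndim != 2:
            raise GridCompatibilityError(
                f"labels {labels.shape} and foreground {fg.shape} must be the same 2-D grid"
            )
        k = len(names)
        if labels.min(initial=0) < 0 or labels.max(initial=0) > k:
            raise LabelRangeError(
                f"labels must lie in 0..{k}, found range "
                f"[{labels.min()}, {labels.max()}]"
            )
        if np.any((labels > 0) != fg):
            raise LabelRangeError("labels must be nonzero exactly on the foreground")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "class_names", names)

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, class_names, identifier: str = ""
    ) -> "LabelMap":
        labels = np.asarray(labels)
        return cls(labels, labels > 0, tuple(class_names), identifier)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-cell distribution over K classes on a 2-D grid.

    Foreground cells carry genuine posteriors; background cells carry the
    uniform padding distribution so that any cell can be read as a valid
    distribution.
    """

    probs: np.ndarray
    foreground: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.ascontiguousarray(np.asarray(self.probs, dtype=np.float64))
        fg = np.asarray(self.foreground, dtype=bool)
        names = tuple(self.class_names)
        if probs.ndim != 3 or probs.shape[:2] != fg.shape:
            raise GridCompatibilityError(
                f"probs {probs.shape} must be h×w×K matching foreground {fg.shape}"
            )
        if probs.shape[2] != len(names):
            raise GridCompatibilityError(
                f"probs has {probs.shape[2]} classes but {len(names)} names given"
            )
        if probs.min(initial=0.0) < -_SUM_TOL:
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=_SUM_TOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"per-cell probabilities must sum to 1 (worst deviation {worst:.2e})"
            )
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "foreground", fg)
        object.__setattr__(self, "class_names", names)

    @classmethod
    def from_foreground_probs(
        cls, probs: np.ndarray, foreground: np.ndarray, class_names
    ) -> "ProbabilityMap":
        """Build a map, overwriting background cells with the padding distribution."""
        probs = np.asarray(probs, dtype=np.float64).copy()
        fg = np.asarray(foreground, dtype=bool)
        k = probs.shape[2]
        probs[~fg] = uniform_padding(k)
        return cls(probs, fg, tuple(class_names))

    @classmethod
    def uniform(cls, shape: tuple[int, int], foreground, class_names) -> "ProbabilityMap":
        k = len(tuple(class_names))
        probs = np.full((*shape, k), 1.0 / k)
        return cls(probs, foreground, tuple(class_names))

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground.shape

    def padded_probs(self) -> np.ndarray:
        """Probabilities with background cells forced to the padding distribution."""
        out = self.probs.copy()
        out[~self.foreground] = uniform_padding(self.num_classes)
        return out


def check_same_grid(a, b) -> None:
    """Raise unless both containers share shape and class names."""
    if a.shape != b.shape:
        raise GridCompatibilityError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if tuple(a.class_names) != tuple(b.class_names):
        raise GridCompatibilityError(
            f"class sets differ: {a.class_names} vs {b.class_names}"
        )


def resample_nearest(pmap: ProbabilityMap, shape: tuple[int, int],
                     foreground: np.ndarray | None = None) -> ProbabilityMap:
    """Nearest-neighbour resampling of a probability map onto a new grid.

    Cell centres are matched proportionally; nearest-neighbour keeps every
    output cell an untouched source distribution.
    """
    h, w = pmap.shape
    th, tw = shape
    rows = np.minimum((((np.arange(th) + 0.5) * h / th)).astype(np.int64), h - 1)
    cols = np.minimum((((np.arange(tw) + 0.5) * w / tw)).astype(np.int64), w - 1)
    probs = pmap.probs[np.ix_(rows, cols)]
    fg = pmap.foreground[np.ix_(rows, cols)] if foreground is None else foreground
    return ProbabilityMap.from_foreground_probs(probs, fg, pmap.class_names)


def require_foreground(mask: np.ndarray) -> None:
    if not np.any(mask):
        raise DegenerateMaskError("foreground mask is empty")
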