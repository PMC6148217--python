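import numpy as np
import pytest

from pluckseg import LabelMap, ProbabilityMap


def random_label_map(rng, shape=(8, 6), k=5, identifier="", fg_prob=0.7):
    """Random label map with a non-trivial foreground."""
    fg = rng.random(shape) < fg_prob
    if not fg.any():
        fg[shape[0] // 2, shape[1] // 2] = True
    labels = np.zeros(shape, dtype=np.int64)
    labels[fg] = rng.integers(1, k + 1, size=int(fg.sum()))
    names = tuple(f"c{i}" for i in range(1, k + 1))
    return LabelMap(labels, fg, names, identifier)


def random_probability_map(rng, shape=(8, 6), k=5, fg_prob=0.7):
    """Random probability map; background holds the uniform padding."""
    fg = rng.random(shape) < fg_prob
    if not fg.any():
        fg[shape[0] // 2, shape[1] // 2] = True
    raw = rng.random((*shape, k)) + 1e-3
    raw /= raw.sum(axis=2, keepdims=True)
    names = tuple(f"c{i}" for i in range(1, k + 1))
    return ProbabilityMap.from_foreground_probs(raw, fg, names)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Nine small plucks shared by pipeline-level tests."""
    from pluckseg import PluckParams, generate_dataset

    samples, manifest = generate_dataset(9, PluckParams(grid_size=(48, 24)), seed=77)
    return samples, manifest
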