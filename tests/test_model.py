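"""Auto-context core: sampling, feature assembly, training and inference."""

import numpy as np
import pytest

from pluckseg import (
    LabelMap,
    ProbabilityMap,
    StencilSpec,
    VariantConfig,
    apply_model,
    argmax_labels,
    assemble_features,
    default_stencil,
    feature_layout,
    make_star_stencil,
    predict_sequence,
    sample_training_locations,
    train_sequence,
)
from pluckseg.errors import MissingAtlasError, StratificationError
from pluckseg.features import DecompositionConfig, FeatureGrid, appearance_features
from tests.conftest import random_label_map, random_probability_map

SMALL_STENCIL = make_star_stencil(6, (1, 3))


def small_variant(name, **kw):
    kw.setdefault("T", 2)
    kw.setdefault("per_class_samples", 60)
    kw.setdefault("stencil", SMALL_STENCIL)
    kw.setdefault("max_iter", 60)
    return VariantConfig.from_name(name, **kw)


@pytest.fixture(scope="module")
def pluck_pairs(tiny_dataset):
    samples, _ = tiny_dataset
    return [(s.image, s.labels) for s in samples]


class TestSampling:
    def test_counts_per_class(self, rng):
        maps = [random_label_map(rng, shape=(12, 10), k=4, identifier=f"m{i}")
                for i in range(3)]
        locs = sample_training_locations(maps, per_class=25, seed=3)
        labels = np.array([l[3] for l in locs])
        assert len(locs) == 100
        assert all((labels == c).sum() == 25 for c in range(1, 5))

    def test_one_per_class(self, rng):
        maps = [random_label_map(rng, shape=(10, 10), k=5)]
        locs = sample_training_locations(maps, per_class=1, seed=0)
        assert sorted(l[3] for l in locs) == [1, 2, 3, 4, 5]

    def test_deterministic_given_seed(self, rng):
        maps = [random_label_map(rng, shape=(12, 10), k=3) for _ in range(2)]
        assert (sample_training_locations(maps, 20, seed=9)
                == sample_training_locations(maps, 20, seed=9))

    def test_locations_carry_correct_labels(self, rng):
        maps = [random_label_map(rng, shape=(10, 8), k=3) for _ in range(2)]
        for idx, r, c, label in sample_training_locations(maps, 15, seed=1):
            assert maps[idx].labels[r, c] == label

    def test_without_replacement_when_enough_cells(self, rng):
        maps = [random_label_map(rng, shape=(20, 20), k=2)]
        locs = sample_training_locations(maps, per_class=30, seed=5)
        assert len(set(locs)) == len(locs)

    def test_absent_class_raises_naming_it(self):
        labels = np.ones((6, 6), dtype=np.int64)  # only class 1 present
        m = LabelMap.from_labels(labels, ("a", "b", "c"))
        with pytest.raises(StratificationError, match="'b'"):
            sample_training_locations([m], per_class=2, seed=0)


class TestFeatureAssembly:
    @staticmethod
    def _grid_and_probs(rng, k=5):
        image = rng.integers(0, 255, size=(24, 24, 3)).astype(np.uint8)
        grid = appearance_features(image, DecompositionConfig(subsample_factor=1))
        pmap = random_probability_map(rng, shape=grid.shape, k=k, fg_prob=1.0)
        return grid, pmap

    def test_ac_length_is_491(self, rng):
        grid, pmap = self._grid_and_probs(rng)
        variant = VariantConfig.from_name("ac", stencil=default_stencil())
        vec = assemble_features(grid, pmap, None, (5, 5), variant)
        assert vec.shape == (36 + 455,)

    def test_waac_ic_length_is_956(self, rng):
        from pluckseg import prior_atlas

        grid, pmap = self._grid_and_probs(rng)
        atlas = prior_atlas([random_label_map(rng, shape=grid.shape, k=5)])
        variant = VariantConfig.from_name("waac+ic", stencil=default_stencil())
        vec = assemble_features(grid, pmap, atlas, (5, 5), variant)
        assert vec.shape == (36 + 455 + 10 + 455,)

    def test_layout_lengths_sum_to_vector_length(self, rng):
        grid, pmap = self._grid_and_probs(rng)
        variant = VariantConfig.from_name("ac+ic", stencil=SMALL_STENCIL)
        vec = assemble_features(grid, pmap, None, (3, 3), variant)
        layout = feature_layout(variant, grid.num_features, 5, with_atlas=False)
        assert sum(s.stop - s.start for s in layout.values()) == vec.size
        assert list(layout) == ["local", "stencil", "integral"]

    def test_center_only_stencil_uniform_probs(self, rng):
        image = rng.integers(0, 255, size=(16, 16, 3)).astype(np.uint8)
        grid = appearance_features(image, DecompositionConfig(subsample_factor=1))
        pmap = ProbabilityMap.uniform(grid.shape, np.ones(grid.shape, bool),
                                      tuple("abcde"))
        variant = VariantConfig.from_name("ac", stencil=StencilSpec(((0, 0),)))
        vec = assemble_features(grid, pmap, None, (2, 2), variant)
        assert np.allclose(vec[-5:], 0.2)

    def test_missing_atlas_rejected(self, rng):
        grid, pmap = self._grid_and_probs(rng)
        variant = VariantConfig.from_name("waac", stencil=SMALL_STENCIL)
        with pytest.raises(MissingAtlasError):
            assemble_features(grid, pmap, None, (3, 3), variant)


class TestArgmaxLabels:
    def test_one_hot_roundtrip(self, rng):
        m = random_label_map(rng)
        from pluckseg import one_hot

        assert np.array_equal(argmax_labels(one_hot(m)).labels, m.labels)

    def test_uniform_cell_breaks_tie_to_class_one(self):
        pmap = ProbabilityMap.uniform((2, 2), np.ones((2, 2), bool), ("a", "b", "c"))
        assert (argmax_labels(pmap).labels == 1).all()

    def test_matches_per_cell_scan(self, rng):
        pmap = random_probability_map(rng, shape=(7, 6), k=4)
        out = argmax_labels(pmap)
        for r in range(7):
            for c in range(6):
                if pmap.foreground[r, c]:
                    assert out.labels[r, c] == int(np.argmax(pmap.probs[r, c])) + 1
                else:
                    assert out.labels[r, c] == 0


class TestTrainPredict:
    def test_waac_with_t1_reduces_to_ac(self, pluck_pairs):
        kw = dict(T=1, seed=4)
        ac = train_sequence(pluck_pairs[:6], small_variant("ac", **kw))
        waac = train_sequence(pluck_pairs[:6], small_variant("waac", **kw))
        image, labels = pluck_pairs[6]
        p_ac = predict_sequence(ac, image, labels.foreground)
        p_waac = predict_sequence(waac, image, labels.foreground,
                                  waac.training_label_maps)
        assert ac.feature_layouts == waac.feature_layouts
        assert np.array_equal(p_ac[0].probs, p_waac[0].probs)

    def test_training_is_deterministic(self, pluck_pairs):
        a = train_sequence(pluck_pairs[:5], small_variant("ac+ic", seed=8))
        b = train_sequence(pluck_pairs[:5], small_variant("ac+ic", seed=8))
        assert a.training_history == b.training_history
        image, labels = pluck_pairs[5]
        pa = predict_sequence(a, image, labels.foreground)[-1]
        pb = predict_sequence(b, image, labels.foreground)[-1]
        assert np.array_equal(pa.probs, pb.probs)

    def test_prediction_contract(self, pluck_pairs):
        model = train_sequence(pluck_pairs[:5], small_variant("waac+ic", seed=2, m_w=2))
        image, labels = pluck_pairs[5]
        maps = predict_sequence(model, image, labels.foreground)
        assert len(maps) == model.variant.T
        for pmap in maps:
            fg = pmap.foreground
            assert np.array_equal(fg, labels.foreground)
            assert np.allclose(pmap.probs.sum(axis=2), 1.0, atol=1e-6)
            assert pmap.probs.min() >= 0

    def test_waac_atlas_locks_onto_exact_twin(self, pluck_pairs):
        # the test image's true map has an identical twin in the candidate
        # pool: with m_w=1 the final weighted atlas must collapse onto it
        from pluckseg import one_hot

        model = train_sequence(pluck_pairs[:6], small_variant("waac", seed=5, m_w=1,
                                                              per_class_samples=150))
        image, labels = pluck_pairs[0]  # in-sample: prediction is near-perfect
        twin = LabelMap(labels.labels, labels.foreground, labels.class_names, "twin")
        candidates = model.training_label_maps + [twin]
        maps, atlases = apply_model(model, image, labels.foreground, candidates)
        final_atlas = atlases[-1]
        hard = argmax_labels(final_atlas.probability_map)
        fg = labels.foreground & hard.foreground
        agreement = np.mean(hard.labels[fg] == labels.labels[fg])
        assert agreement >= 0.99

    def test_iteration_count_and_layout_progression(self, pluck_pairs):
        model = train_sequence(pluck_pairs[:5],
                               small_variant("waac", seed=1, T=3, m_w=2))
        assert model.num_iterations == 3
        assert "atlas" not in model.feature_layouts[0]
        assert "atlas" in model.feature_layouts[1]

    def test_needs_at_least_two_images(self, pluck_pairs):
        with pytest.raises(ValueError):
            train_sequence(pluck_pairs[:1], small_variant("ac"))
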