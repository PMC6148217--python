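"""Prior and weighted atlases, one-hot encoding and F1 map similarity."""

import numpy as np
import pytest

from pluckseg import (
    LabelMap,
    f1_similarity,
    one_hot,
    prior_atlas,
    weighted_atlas,
)
from pluckseg.atlas import atlas_weighting
from pluckseg.errors import EmptyPoolError, GridCompatibilityError
from tests.conftest import random_label_map, random_probability_map

NAMES5 = tuple(f"c{i}" for i in range(1, 6))


def lm(labels, names=NAMES5, identifier=""):
    return LabelMap.from_labels(np.asarray(labels), names, identifier)


class TestOneHot:
    def test_single_cell(self):
        m = lm([[3, 0], [0, 0]])
        assert np.array_equal(one_hot(m).probs[0, 0], [0, 0, 1, 0, 0])

    def test_background_gets_padding(self):
        m = lm([[3, 0], [0, 0]])
        assert np.allclose(one_hot(m).probs[1, 1], 0.2)

    def test_argmax_roundtrip(self, rng):
        from pluckseg import argmax_labels

        for _ in range(10):
            m = random_label_map(rng, shape=(7, 5), k=4)
            back = argmax_labels(one_hot(m))
            assert np.array_equal(back.labels, m.labels)


class TestPriorAtlas:
    def test_identical_maps_reduce_to_one_hot(self, rng):
        m = random_label_map(rng)
        atlas = prior_atlas([m, m, m])
        assert np.allclose(atlas.probs, one_hot(m).probs)

    def test_two_map_disagreement_is_half_half(self):
        a = lm([[1, 1], [1, 1]])
        b = lm([[2, 1], [1, 1]])
        atlas = prior_atlas([a, b])
        assert np.allclose(atlas.probs[0, 0], [0.5, 0.5, 0, 0, 0])

    def test_matches_cell_loop_oracle(self, rng):
        maps = [random_label_map(rng, shape=(6, 5), k=3) for _ in range(5)]
        atlas = prior_atlas(maps)
        onehots = [one_hot(m).probs for m in maps]
        for r in range(6):
            for c in range(5):
                expected = np.mean([oh[r, c] for oh in onehots], axis=0)
                assert np.allclose(atlas.probs[r, c], expected)

    def test_foreground_is_union(self, rng):
        maps = [random_label_map(rng, shape=(6, 5), k=3, fg_prob=0.4) for _ in range(4)]
        atlas = prior_atlas(maps)
        union = np.any([m.foreground for m in maps], axis=0)
        assert np.array_equal(atlas.foreground, union)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(GridCompatibilityError):
            prior_atlas([random_label_map(rng, shape=(4, 4)),
                         random_label_map(rng, shape=(5, 4))])


class TestF1Similarity:
    def test_perfect_match_is_one(self, rng):
        m = random_label_map(rng)
        assert f1_similarity(m, one_hot(m)) == pytest.approx(1.0)

    def test_fully_disjoint_is_zero(self):
        ref = lm([[1, 1], [1, 1]])
        pred = lm([[2, 2], [2, 2]])
        assert f1_similarity(ref, one_hot(pred)) == 0.0

    def test_hand_contingency_toy(self):
        # reference: class 1 fills the left 2 columns, class 2 the right 2.
        # prediction shifts the class-1 region right by one column.
        ref = lm([[1, 1, 2, 2]] * 4)
        pred = lm([[1, 1, 1, 2]] * 4)
        # class1: p = 8/12, r = 8/8 → F1 = 0.8; class2: p = 4/4, r = 4/8 → F1 = 2/3
        expected = (0.8 + 2 / 3) / 2
        assert f1_similarity(ref, one_hot(pred)) == pytest.approx(expected)

    def test_absent_in_both_excluded_from_mean(self):
        # only classes 1 and 2 occur anywhere; classes 3-5 must not dilute
        ref = lm([[1, 2]])
        assert f1_similarity(ref, one_hot(ref)) == pytest.approx(1.0)

    def test_relabelling_symmetry(self, rng):
        ref = random_label_map(rng, shape=(6, 6), k=3)
        pred = random_label_map(rng, shape=(6, 6), k=3)
        base = f1_similarity(ref, one_hot(pred))
        perm = np.array([0, 3, 1, 2])  # permutation of classes 1..3
        ref_p = LabelMap(perm[ref.labels], ref.foreground, ref.class_names)
        pred_p = LabelMap(perm[pred.labels], pred.foreground, pred.class_names)
        assert f1_similarity(ref_p, one_hot(pred_p)) == pytest.approx(base)


class TestWeightedAtlas:
    def test_uniform_weights_full_selection_equals_prior(self, rng):
        m = random_label_map(rng, shape=(6, 6), k=3, identifier="ref")
        pool = []
        for i in range(4):
            pool.append(LabelMap(m.labels, m.foreground, m.class_names, f"m{i}"))
        atlas = weighted_atlas(pool, one_hot(m), m_w=10)
        assert np.allclose(atlas.probs, prior_atlas(pool).probs)

    def test_single_best_candidate(self, rng):
        truth = random_label_map(rng, shape=(6, 6), k=3, identifier="truth")
        other = random_label_map(rng, shape=(6, 6), k=3, identifier="other")
        atlas = weighted_atlas([other, truth], one_hot(truth), m_w=1)
        assert np.allclose(atlas.probs, one_hot(truth).probs)
        assert atlas.provenance == (("truth", 1.0),)

    def test_matches_brute_force_oracle(self, rng):
        predicted = random_probability_map(rng, shape=(6, 6), k=3)
        pool = [random_label_map(rng, shape=(6, 6), k=3, identifier=f"m{i}")
                for i in range(6)]
        m_w = 3
        atlas = weighted_atlas(pool, predicted, m_w)
        # oracle: rank by (weight desc, id asc), renormalise, weighted sum
        weights = [f1_similarity(c, predicted) for c in pool]
        order = sorted(range(6), key=lambda i: (-weights[i], pool[i].identifier))
        chosen = order[:m_w]
        total = sum(weights[i] for i in chosen)
        expected = np.zeros_like(atlas.probs)
        for i in chosen:
            expected += (weights[i] / total) * one_hot(pool[i]).probs
        assert np.allclose(atlas.probs, expected)

    def test_exclusion_rule(self, rng):
        truth = random_label_map(rng, shape=(5, 5), k=3, identifier="self")
        other = random_label_map(rng, shape=(5, 5), k=3, identifier="other")
        atlas = weighted_atlas([truth, other], one_hot(truth), m_w=5, exclude="self")
        assert [ident for ident, _ in atlas.provenance] == ["other"]

    def test_empty_pool_after_exclusion(self, rng):
        m = random_label_map(rng, identifier="only")
        with pytest.raises(EmptyPoolError):
            weighted_atlas([m], one_hot(m), m_w=1, exclude="only")

    def test_candidate_order_invariance(self, rng):
        predicted = random_probability_map(rng, shape=(6, 6), k=3)
        pool = [random_label_map(rng, shape=(6, 6), k=3, identifier=f"m{i}")
                for i in range(5)]
        a = weighted_atlas(pool, predicted, m_w=3)
        b = weighted_atlas(pool[::-1], predicted, m_w=3)
        assert np.array_equal(a.probs, b.probs)
        assert a.provenance == b.provenance

    def test_tie_break_by_identifier(self, rng):
        m = random_label_map(rng, shape=(5, 5), k=3)
        pool = [LabelMap(m.labels, m.foreground, m.class_names, ident)
                for ident in ("zeta", "alpha", "mid")]
        weighting = atlas_weighting(pool, one_hot(m), m_w=2)
        selected = [ident for ident, s in zip(weighting.identifiers, weighting.selection) if s]
        # all weights equal → the two lexicographically smallest ids win
        assert set(selected) == {"alpha", "mid"}

    def test_all_zero_weights_fall_back_to_unweighted_mean(self):
        ref = lm([[1, 1], [1, 1]], identifier="r")
        a = lm([[2, 2], [2, 2]], identifier="a")
        b = lm([[3, 3], [3, 3]], identifier="b")
        atlas = weighted_atlas([a, b], one_hot(ref), m_w=2)
        assert np.allclose(atlas.probs, prior_atlas([a, b]).probs)

    def test_cells_are_distributions(self, rng):
        predicted = random_probability_map(rng, shape=(7, 5), k=4)
        pool = [random_label_map(rng, shape=(7, 5), k=4, identifier=f"m{i}")
                for i in range(5)]
        atlas = weighted_atlas(pool, predicted, m_w=2)
        assert np.allclose(atlas.probs.sum(axis=2), 1.0, atol=1e-6)
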