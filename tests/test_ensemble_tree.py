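"""Entropy tree growth, gain-ratio splits, pruning, bagging."""

import copy
import itertools

import numpy as np
import pytest

from hpbcr.ensemble_tree import (EncodedMatrix, FeatureTransform, bagged_fit,
                                 bagged_predict, best_split, entropy,
                                 grow_tree, prune_tree, rules_text,
                                 tree_predict, BaggedTreeModel)


def _numeric_enc(x, y, names=None):
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    names = names or [f"f{j}" for j in range(x.shape[1])]
    return EncodedMatrix(x, np.zeros((len(y), 0), dtype=int),
                         np.asarray(y, dtype=int), names, [], [])


def _cat_enc(codes, y, n_cats=2):
    codes = np.atleast_2d(np.asarray(codes, dtype=int).T).T
    names = [f"c{j}" for j in range(codes.shape[1])]
    cats = [[str(i) for i in range(n_cats)] for _ in names]
    return EncodedMatrix(np.zeros((len(y), 0)), codes,
                         np.asarray(y, dtype=int), [], names, cats)


class TestEntropy:
    @pytest.mark.parametrize("counts, expect", [
        ((5, 5), 1.0),
        ((8, 0), 0.0),
        ((2, 6), 0.8113),  # -0.25 log2 0.25 - 0.75 log2 0.75
    ])
    def test_closed_form(self, counts, expect):
        assert entropy(counts) == pytest.approx(expect, abs=1e-4)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))


class TestBestSplit:
    def test_perfect_threshold(self):
        enc = _numeric_enc([[1], [2], [3], [4]], [0, 0, 1, 1])
        tr = FeatureTransform([], ["f0"], np.zeros(0, bool), np.array([1.0]))
        s = best_split(enc, tr, min_leaf=1)
        assert s.threshold == pytest.approx(2.5)
        assert s.gain_ratio == pytest.approx(1.0)

    def test_zero_weight_excludes_feature(self):
        enc = _numeric_enc([[1], [2], [3], [4]], [0, 0, 1, 1])
        tr = FeatureTransform([], ["f0"], np.zeros(0, bool), np.array([0.0]))
        assert best_split(enc, tr, min_leaf=1) is None

    def test_weight_scales_split_score(self):
        enc = _numeric_enc([[1], [2], [3], [4]], [0, 0, 1, 1])
        tr = FeatureTransform([], ["f0"], np.zeros(0, bool), np.array([0.4]))
        s = best_split(enc, tr, min_leaf=1)
        assert s.score == pytest.approx(0.4 * s.gain_ratio)

    def test_perfectly_aligned_binary_feature(self):
        enc = _cat_enc([0, 0, 0, 0, 1, 1, 1, 1], [0, 0, 0, 0, 1, 1, 1, 1])
        tr = FeatureTransform(["c0"], [], np.array([True]), np.zeros(0))
        assert best_split(enc, tr).gain_ratio == pytest.approx(1.0)

    def test_constant_feature_yields_no_split(self):
        enc = _numeric_enc([[2], [2], [2], [2]], [0, 0, 1, 1])
        tr = FeatureTransform([], ["f0"], np.zeros(0, bool), np.array([1.0]))
        assert best_split(enc, tr, min_leaf=1) is None


class TestGrowTree:
    def test_separable_single_feature(self):
        enc = _numeric_enc([[i] for i in range(10)], [0] * 5 + [1] * 5)
        tree = grow_tree(enc, FeatureTransform([], ["f0"], np.zeros(0, bool),
                                               np.array([1.0])))
        assert tree.kind == "internal"
        assert (tree_predict(tree, enc) == enc.y).all()

    def test_pure_node_is_a_leaf(self):
        enc = _numeric_enc([[1], [2], [3]], [1, 1, 1])
        tree = grow_tree(enc, FeatureTransform([], ["f0"], np.zeros(0, bool),
                                               np.array([1.0])))
        assert tree.kind == "leaf" and tree.predicted_class == 1

    def test_xor_solved_at_depth_two(self, rng):
        """An (uneven) XOR sample over two binary features is fit exactly;
        a balanced XOR has zero single-feature gain and would stall."""
        a = np.repeat([0, 0, 1, 1], [12, 8, 11, 9])
        b = np.r_[[0] * 12, [1] * 8, [0] * 11, [1] * 9]
        y = a ^ b
        enc = _cat_enc(np.stack([a, b], axis=1), y)
        tree = grow_tree(enc, FeatureTransform.full(["c0", "c1"], []))
        assert (tree_predict(tree, enc) == y).all()
        assert tree.kind == "internal"
        assert any(ch.kind == "internal" for ch in tree.children)

    def test_child_counts_sum_to_parent(self, study_cohort):
        from hpbcr.cohort import discretize
        from hpbcr.ensemble_tree import encode_cohort
        tab = discretize(study_cohort)
        enc = encode_cohort(tab, ["pr", "surgery", "nr_cat"], ["i_node", "age"])
        tree = grow_tree(enc, FeatureTransform.full(["pr", "surgery", "nr_cat"],
                                                    ["i_node", "age"]))

        def check(node):
            if node.kind == "internal":
                total = np.sum([c.class_counts for c in node.children], axis=0)
                assert tuple(total) == tuple(node.class_counts)
                for c in node.children:
                    check(c)

        check(tree)


class TestStumpOracle:
    def test_training_accuracy_at_least_best_stump(self):
        """Over every labeling of the 3-bit hypercube, greedy growth never
        does worse on the training set than the best single split found
        by exhaustive enumeration."""
        rows = np.array(list(itertools.product([0, 1], repeat=3)))
        tr = FeatureTransform.full(["c0", "c1", "c2"], [])
        for bits in range(256):
            y = np.array([(bits >> i) & 1 for i in range(8)])
            enc = _cat_enc(rows, y)
            tree = grow_tree(enc, tr, min_leaf=1)
            tree_acc = (tree_predict(tree, enc) == y).mean()
            best_stump = max(y.mean(), 1 - y.mean())
            for j in range(3):
                acc = 0
                for v in (0, 1):
                    part = y[rows[:, j] == v]
                    acc += max(part.sum(), len(part) - part.sum())
                best_stump = max(best_stump, acc / 8)
            assert tree_acc >= best_stump - 1e-12, bits


class TestPruning:
    def test_redundant_subtree_collapses(self):
        enc = _numeric_enc([[1], [2], [3], [4]], [1, 1, 1, 0])
        tree = grow_tree(enc, FeatureTransform([], ["f0"], np.zeros(0, bool),
                                               np.array([1.0])), min_leaf=1)
        # force children predicting the same class, then prune
        pruned = prune_tree(copy.deepcopy(tree))
        assert pruned.node_count() <= tree.node_count()

    def test_pure_tree_on_clean_data_unchanged(self):
        enc = _numeric_enc([[i] for i in range(20)], [0] * 10 + [1] * 10)
        tree = grow_tree(enc, FeatureTransform([], ["f0"], np.zeros(0, bool),
                                               np.array([1.0])))
        before = tree.node_count()
        assert prune_tree(copy.deepcopy(tree)).node_count() == before

    def test_label_noise_trees_shrink(self, rng):
        shrunk = 0
        for _ in range(20):
            x = rng.random((120, 3))
            y = rng.integers(0, 2, 120)  # pure label noise
            enc = _numeric_enc(x, y, ["a", "b", "c"])
            tr = FeatureTransform([], ["a", "b", "c"], np.zeros(0, bool),
                                  np.ones(3))
            grown = grow_tree(enc, tr)
            pruned = prune_tree(copy.deepcopy(grown))
            shrunk += pruned.node_count() < grown.node_count()
        assert shrunk >= 19


class TestBagging:
    @pytest.fixture
    def enc(self, study_cohort):
        from hpbcr.cohort import discretize
        from hpbcr.ensemble_tree import encode_cohort
        tab = discretize(study_cohort).subset(range(300))
        return encode_cohort(tab, ["pr", "hrt", "nr_cat"], ["i_node", "ts"])

    def test_defaults_and_determinism(self, enc):
        tr = FeatureTransform.full(enc.cat_names, enc.num_names)
        m1 = bagged_fit(enc, tr, seed=5)
        m2 = bagged_fit(enc, tr, seed=5)
        assert m1.n_trees == 10
        assert m1.bootstrap_seeds == m2.bootstrap_seeds
        assert np.array_equal(bagged_predict(m1, enc), bagged_predict(m2, enc))

    def test_single_class_training_rejected(self, enc):
        sub = enc.subset(np.flatnonzero(enc.y == 0))
        with pytest.raises(ValueError):
            bagged_fit(sub, FeatureTransform.full(enc.cat_names, enc.num_names))

    def test_degenerate_transform_rejected(self, enc):
        tr = FeatureTransform(enc.cat_names, enc.num_names,
                              np.zeros(3, bool), np.zeros(2))
        with pytest.raises(ValueError):
            bagged_fit(enc, tr)

    def test_separable_data_memorized(self):
        x = np.arange(40, dtype=float)[:, None]
        y = (x[:, 0] >= 20).astype(int)
        enc = _numeric_enc(x, y)
        tr = FeatureTransform([], ["f0"], np.zeros(0, bool), np.array([1.0]))
        model = bagged_fit(enc, tr, seed=0)
        assert (bagged_predict(model, enc) == y).all()

    def test_tie_votes_predict_recurrence(self, enc):
        tr = FeatureTransform.full(enc.cat_names, enc.num_names)
        model = bagged_fit(enc, tr, seed=1)
        # synthetic tie: half the trees vote each way
        from hpbcr.ensemble_tree import TreeNode
        pos = TreeNode(class_counts=(0, 5))
        neg = TreeNode(class_counts=(5, 0))
        model.trees = [pos] * 5 + [neg] * 5
        pred = bagged_predict(model, enc.subset([0]))
        assert pred[0] == 1

    def test_weight_zero_equivalent_to_feature_removal(self, enc):
        with_zero = FeatureTransform(enc.cat_names, enc.num_names,
                                     np.ones(3, bool), np.array([0.0, 1.0]))
        m_zero = bagged_fit(enc, with_zero, seed=9)
        removed = EncodedMatrix(enc.x_num[:, 1:], enc.x_cat, enc.y,
                                enc.num_names[1:], enc.cat_names,
                                enc.cat_categories)
        m_removed = bagged_fit(removed, FeatureTransform.full(enc.cat_names,
                                                              ["ts"]), seed=9)
        assert np.array_equal(bagged_predict(m_zero, enc),
                              bagged_predict(m_removed, removed))

    def test_unseen_category_routes_to_heaviest_child(self):
        codes = np.r_[np.zeros(30, int), np.ones(10, int)]
        y = np.r_[np.zeros(30, int), np.ones(10, int)]
        enc = _cat_enc(codes, y, n_cats=3)
        tr = FeatureTransform(["c0"], [], np.array([True]), np.zeros(0))
        tree = grow_tree(enc, tr)
        probe = _cat_enc(np.array([2]), np.array([0]), n_cats=3)
        # category 2 was never seen; the larger child carries class 0
        assert tree_predict(tree, probe)[0] == 0

    def test_json_roundtrip_and_rules(self, enc):
        tr = FeatureTransform.full(enc.cat_names, enc.num_names)
        model = bagged_fit(enc, tr, seed=3)
        clone = BaggedTreeModel.from_json(model.to_json())
        assert np.array_equal(bagged_predict(model, enc),
                              bagged_predict(clone, enc))
        text = rules_text(model)
        assert text.count("# Tree") == 10
        assert "IF" in text and "THEN" in text
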