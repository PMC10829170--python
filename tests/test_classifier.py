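"""Pair featurization, NLL loss, imbalance samplers and transfer training."""

import math

import numpy as np
import pytest

import ddikit as dk
from ddikit.classifier import DDIExample, _MLP
from ddikit.errors import ConfigError, ShapeError


class TestFeaturizePair:
    def test_width_is_twice_repr_dim(self):
        h1, h2 = np.ones(262), np.zeros(262)
        assert dk.featurize_pair(h1, h2).shape == (524,)

    def test_order_sensitive(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert not np.array_equal(dk.featurize_pair(a, b), dk.featurize_pair(b, a))

    def test_width_mismatch_raises(self):
        with pytest.raises(ShapeError):
            dk.featurize_pair(np.ones(3), np.ones(4))


class TestNLLLoss:
    def test_perfect_prediction_is_zero(self):
        lp = np.log(np.array([[1 - 2e-12, 1e-12, 1e-12]] * 4))
        assert dk.nll_loss(lp, np.zeros(4, dtype=int)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_four_classes(self):
        lp = np.full((5, 4), math.log(0.25))
        assert dk.nll_loss(lp, np.array([0, 1, 2, 3, 0])) == pytest.approx(math.log(4))

    def test_hand_arithmetic(self):
        lp = np.log(np.array([[0.5, 0.5], [0.25, 0.75]]))
        expected = -(math.log(0.5) + math.log(0.25)) / 2  # 1.03972
        assert dk.nll_loss(lp, np.array([0, 0])) == pytest.approx(expected, abs=1e-6)

    def test_label_out_of_range_rejected(self):
        lp = np.log(np.full((2, 3), 1 / 3))
        with pytest.raises(ValueError):
            dk.nll_loss(lp, np.array([0, 3]))

    def test_agrees_with_per_example_loop(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(5), size=20)
        y = rng.integers(0, 5, size=20)
        oracle = -sum(math.log(p[i, y[i]]) for i in range(20)) / 20
        assert dk.nll_loss(np.log(p), y) == pytest.approx(oracle, abs=1e-9)


class TestSamplers:
    labels_imbalanced = np.array([0] * 900 + [1] * 100)

    def test_balanced_batch_equal_counts(self):
        labels = np.array([0] * 500 + [1] * 30 + [2] * 20 + [3] * 10)
        for batch in dk.make_sampler(labels, "balanced_batch", 256, seed=0):
            assert len(batch) == 256
            counts = np.bincount(labels[batch], minlength=4)
            assert counts.max() - counts.min() <= 1
            assert counts.min() == 64

    def test_balanced_batch_counts_differ_at_most_one_when_uneven(self):
        labels = np.array([0] * 50 + [1] * 30 + [2] * 20)
        for batch in dk.make_sampler(labels, "balanced_batch", 100, seed=1):
            counts = np.bincount(labels[batch], minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_balanced_batch_more_classes_than_batch(self, caplog):
        labels = np.arange(20)  # 20 singleton classes
        with caplog.at_level("WARNING"):
            batches = list(dk.make_sampler(labels, "balanced_batch", 8, seed=0))
        seen = set()
        for b in batches:
            assert len(set(labels[b])) == 8  # distinct classes per batch
            seen |= set(labels[b])
        assert len(seen) > 8  # coverage rotates
        assert any("rotating" in r.message for r in caplog.records)

    def test_class_weight_equalizes_marginals(self):
        draws = np.concatenate(
            [
                self.labels_imbalanced[b]
                for _ in range(25)
                for b in dk.make_sampler(self.labels_imbalanced, "class_weight", 100, seed=7)
            ]
        )
        share = (draws == 1).mean()
        se = math.sqrt(0.25 / len(draws))
        assert abs(share - 0.5) < 3 * se

    def test_weighted_random_equalizes_marginals(self):
        draws = np.concatenate(
            [
                self.labels_imbalanced[b]
                for _ in range(25)
                for b in dk.make_sampler(self.labels_imbalanced, "weighted_random", 100, seed=3)
            ]
        )
        share = (draws == 1).mean()
        assert abs(share - 0.5) < 3 * math.sqrt(0.25 / len(draws))

    @pytest.mark.parametrize("strategy", ["balanced_batch", "class_weight", "weighted_random"])
    def test_deterministic_streams(self, strategy):
        labels = np.array([0] * 10 + [1] * 5 + [2] * 2)
        a = [b.tolist() for b in dk.make_sampler(labels, strategy, 8, seed=5)]
        b = [b.tolist() for b in dk.make_sampler(labels, strategy, 8, seed=5)]
        assert a == b


class _OneHotEncoder:
    """Stand-in encoder mapping each known token row to a fixed one-hot h."""

    def __init__(self, config, smiles_to_index):
        import ddikit.tokenizer as tok

        self.config = config
        vocab = tok.build_vocabulary()
        self._lookup = {
            tok.encode(s, vocab, config.max_len).ids.tobytes(): idx
            for s, idx in smiles_to_index.items()
        }

    def embed(self, tokens, mode="representation"):
        h = np.zeros((len(tokens), self.config.repr_dim))
        for r, row in enumerate(tokens):
            h[r, self._lookup[row.tobytes()]] = 1.0
        return h


class TestTrainAndEvaluate:
    @staticmethod
    def separable_pair_set():
        """3 drugs, 3 classes; one-hot drug features make pairs separable."""
        drugs = ["CCO", "c1ccccc1", "CC(=O)O"]
        label_of = {frozenset([0, 1]): 0, frozenset([0, 2]): 1, frozenset([1, 2]): 2}
        rng = np.random.default_rng(0)
        examples = []
        for _ in range(240):
            i, j = rng.choice(3, size=2, replace=False)
            examples.append(DDIExample(drugs[i], drugs[j], label_of[frozenset([i, j])]))
        config = dk.EncoderConfig(max_len=16, repr_dim=8, conv_channels=(8,),
                                  kernel_sizes=(3,))
        encoder = _OneHotEncoder(config, {s: k for k, s in enumerate(drugs)})
        state = dk.PretrainState(encoder=encoder, config=config)
        return examples, state

    def test_separable_three_class_problem_is_solved(self):
        examples, state = self.separable_pair_set()
        spec = dk.stratified_random_split(examples, (0.6, 0.2, 0.2), seed=0)
        parts = [[examples[i] for i in ids]
                 for ids in (spec.train_ids, spec.val_ids, spec.test_ids)]
        config = dk.ClassifierConfig(hidden_dims=(32,), n_classes=3, batch_size=32, epochs=60)
        _, reports = dk.train_and_evaluate(*parts, state, config, seed=0)
        assert reports["test"].f1_weighted >= 0.95

    def test_probability_rows_sum_to_one(self):
        examples, state = self.separable_pair_set()
        spec = dk.stratified_random_split(examples, (0.6, 0.2, 0.2), seed=1)
        parts = [[examples[i] for i in ids]
                 for ids in (spec.train_ids, spec.val_ids, spec.test_ids)]
        config = dk.ClassifierConfig(hidden_dims=(16,), n_classes=3, batch_size=32, epochs=3)
        clf, _ = dk.train_and_evaluate(*parts, state, config, seed=0)
        prob = clf.predict_proba(parts[2])
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)

    def test_reproducible_reports(self):
        examples, state = self.separable_pair_set()
        spec = dk.stratified_random_split(examples, (0.6, 0.2, 0.2), seed=2)
        parts = [[examples[i] for i in ids]
                 for ids in (spec.train_ids, spec.val_ids, spec.test_ids)]
        config = dk.ClassifierConfig(hidden_dims=(16,), n_classes=3, batch_size=32, epochs=4)
        _, r1 = dk.train_and_evaluate(*parts, state, config, seed=9)
        _, r2 = dk.train_and_evaluate(*parts, state, config, seed=9)
        assert r1["test"].as_dict() == r2["test"].as_dict()

    def test_symmetrized_training_contains_both_orders(self):
        examples, state = self.separable_pair_set()
        spec = dk.stratified_random_split(examples, (0.6, 0.2, 0.2), seed=3)
        parts = [[examples[i] for i in ids]
                 for ids in (spec.train_ids, spec.val_ids, spec.test_ids)]
        config = dk.ClassifierConfig(
            hidden_dims=(16,), n_classes=3, batch_size=32, epochs=2, symmetrize_pairs=True
        )
        clf, reports = dk.train_and_evaluate(*parts, state, config, seed=0)
        assert reports["train"].n == 2 * len(parts[0])

    def test_label_space_mismatch_rejected(self):
        examples, state = self.separable_pair_set()
        config = dk.ClassifierConfig(hidden_dims=(16,), n_classes=2, batch_size=16, epochs=1)
        with pytest.raises(ConfigError):
            dk.train_and_evaluate(examples[:50], examples[50:70], examples[70:90],
                                  state, config, seed=0)


class TestColdStartOrdering:
    def test_both_unseen_not_easier_than_random_split(
        self, ddi_pairs, smoke_state, fixture_config
    ):
        """Unseen-drug (Task-3-style) test F1 should not beat the random-split
        (Task-1-style) F1 for the same model: median over 3 seeds."""
        config = dk.ClassifierConfig(
            hidden_dims=(256, 128), n_classes=fixture_config.n_classes,
            batch_size=128, epochs=20,
        )
        f1_task1, f1_task3 = [], []
        for seed in range(3):
            spec1 = dk.stratified_random_split(ddi_pairs, (0.8, 0.1, 0.1), seed)
            parts1 = [[ddi_pairs[i] for i in ids]
                      for ids in (spec1.train_ids, spec1.val_ids, spec1.test_ids)]
            _, rep1 = dk.train_and_evaluate(*parts1, smoke_state, config, seed)
            _, spec3 = dk.unseen_drug_splits(ddi_pairs, holdout_fraction=0.2, seed=seed)
            parts3 = [[ddi_pairs[i] for i in ids]
                      for ids in (spec3.train_ids, spec3.val_ids, spec3.test_ids)]
            _, rep3 = dk.train_and_evaluate(*parts3, smoke_state, config, seed)
            f1_task1.append(rep1["test"].f1_weighted)
            f1_task3.append(rep3["test"].f1_weighted)
        assert np.median(f1_task3) <= np.median(f1_task1)
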