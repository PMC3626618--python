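"""Native classifiers: hand examples, oracle equivalence, adapter contract."""

from __future__ import annotations

import numpy as np
import pytest

from inactive_bench import (ExperimentPlan, SetComposition, compute_metrics,
                            confusion, register_adapter, run_grid,
                            train_classifier, train_hyperpipes, train_knn,
                            train_naive_bayes)
from inactive_bench.assembly import LabeledDataset, PlanContext
from inactive_bench.models import (SingleClassError, external_classifier_adapter,
                                   registered_adapters)

from conftest import make_molecule


def dataset(rows, labels, split="train", n_bits=16):
    records = [make_molecule(f"m{i}", bits, n_bits=n_bits)
               for i, bits in enumerate(rows)]
    return LabeledDataset(records=records, labels=np.array(labels, bool), split=split)


def random_dataset(rng, n, n_bits=64, density=0.2, split="train"):
    rows = [tuple(np.flatnonzero(rng.random(n_bits) < density).tolist())
            for _ in range(n)]
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return dataset(rows, labels, split=split, n_bits=n_bits)


class TestNaiveBayes:
    def test_hand_example_two_molecules(self):
        train = dataset([(1, 2), (3, 4)], [True, False])
        model = train_naive_bayes(train)
        query = dataset([(1, 2)], [True], split="test")
        assert model.predict(query)[0]
        assert not model.predict(dataset([(3, 4)], [False], split="test"))[0]

    def test_smoothing_keeps_probabilities_interior(self):
        train = dataset([(1, 2), (3, 4)], [True, False])
        model = train_naive_bayes(train, alpha=1.0)
        for key in ("p_active", "p_inactive"):
            p = model.parameters[key]
            assert (p > 0).all() and (p < 1).all()

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            train_naive_bayes(dataset([(1,), (2,)], [True, True]))

    def test_matches_reference_bernoulli_nb(self):
        """Decisions agree with an independent Bernoulli NB on random data."""
        from sklearn.naive_bayes import BernoulliNB

        rng = np.random.default_rng(0)
        train = random_dataset(rng, 120)
        test = random_dataset(rng, 200, split="test")
        ours = train_naive_bayes(train, alpha=1.0).predict(test)
        ref = BernoulliNB(alpha=1.0)
        ref.fit(train.bit_matrix(), train.labels)
        np.testing.assert_array_equal(ours, ref.predict(test.bit_matrix()).astype(bool))


class TestKNN:
    def test_exact_training_match_is_zero_distance(self):
        train = dataset([(1, 2, 3), (8, 9)], [True, False])
        model = train_knn(train, k=1)
        assert model.predict(dataset([(1, 2, 3)], [True], split="test"))[0]

    def test_majority_vote(self):
        train = dataset([(1,), (1, 2), (8, 9, 10)], [True, True, False])
        model = train_knn(train, k=3)
        assert model.predict(dataset([(1,)], [True], split="test"))[0]

    def test_k_validation(self):
        train = dataset([(1,), (2,)], [True, False])
        with pytest.raises(ValueError):
            train_knn(train, k=0)
        with pytest.raises(ValueError):
            train_knn(train, k=3)

    def test_matches_exhaustive_scan_oracle(self):
        """Predictions equal a naive per-query scan with the same tie rules."""
        rng = np.random.default_rng(1)
        train = random_dataset(rng, 60, n_bits=32)
        test = random_dataset(rng, 100, n_bits=32, split="test")
        Xtr, ytr = train.bit_matrix(), train.labels
        Xte = test.bit_matrix()
        for k in (1, 3, 5):
            got = train_knn(train, k=k).predict(test)
            for q in range(len(Xte)):
                d = (Xtr != Xte[q]).sum(axis=1)
                order = sorted(range(len(d)), key=lambda i: (d[i], i))
                votes = sum(ytr[i] for i in order[:k])
                assert got[q] == (votes * 2 >= k)

    def test_label_flip_symmetry_odd_k(self):
        rng = np.random.default_rng(2)
        train = random_dataset(rng, 30)
        flipped = LabeledDataset(records=train.records, labels=~train.labels,
                                 split="train")
        test = random_dataset(rng, 50, split="test")
        for k in (1, 3):
            a = train_knn(train, k=k).predict(test)
            b = train_knn(flipped, k=k).predict(test)
            np.testing.assert_array_equal(a, ~b)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        train = random_dataset(rng, 40)
        test = random_dataset(rng, 40, split="test")
        np.testing.assert_array_equal(train_knn(train, k=3).predict(test),
                                      train_knn(train, k=3).predict(test))


class TestHyperpipes:
    def test_perfect_containment_wins(self):
        train = dataset([(0, 1), (0, 1), (4, 5), (4, 5)],
                        [True, True, False, False])
        model = train_hyperpipes(train)
        assert model.predict(dataset([(0, 1)], [True], split="test"))[0]
        assert not model.predict(dataset([(4, 5)], [False], split="test"))[0]

    def test_tie_goes_to_first_seen_class(self):
        # both pipes contain the query equally; actives appear first
        train = dataset([(0,), (1,)], [True, False])
        model = train_hyperpipes(train)
        assert model.predict(dataset([(0, 1)], [True], split="test"))[0]
        # inactives first: the same tie now resolves to inactive
        train2 = dataset([(0,), (1,)], [False, True])
        model2 = train_hyperpipes(train2)
        assert not model2.predict(dataset([(0, 1)], [False], split="test"))[0]

    def test_scores_match_bruteforce_containment(self):
        rng = np.random.default_rng(4)
        train = random_dataset(rng, 40, n_bits=32)
        test = random_dataset(rng, 100, n_bits=32, split="test")
        got = train_hyperpipes(train).predict(test)
        Xtr, ytr = train.bit_matrix(), train.labels
        Xte = test.bit_matrix()
        for q in range(len(Xte)):
            scores = {}
            for cls in (True, False):
                members = Xtr[ytr == cls]
                n_contained = sum(
                    1 for b in range(Xtr.shape[1])
                    if (Xte[q, b] and members[:, b].any())
                    or (not Xte[q, b] and (~members[:, b]).any())
                )
                scores[cls] = n_contained / Xtr.shape[1]
            first = bool(ytr[0])
            expect = (scores[True] >= scores[False]) if first \
                else (scores[True] > scores[False])
            assert got[q] == expect

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            train_hyperpipes(dataset([(1,), (2,)], [False, False]))


class TestAdapters:
    def test_always_active_adapter_degenerate_metrics(self):
        register_adapter("always_active", lambda X, y: lambda Q: np.ones(len(Q), bool))
        rng = np.random.default_rng(5)
        train = random_dataset(rng, 30)
        test = random_dataset(rng, 80, split="test")
        model = external_classifier_adapter("always_active", train)
        result = compute_metrics(confusion(model.predict(test), test.labels))
        assert result.recall == 1.0
        assert result.precision == pytest.approx(test.labels.mean())

    def test_unregistered_name_lists_registry(self):
        with pytest.raises(KeyError, match="registered adapters"):
            external_classifier_adapter("no_such_model",
                                        dataset([(1,), (2,)], [True, False]))

    def test_reference_random_forest_smoke(self, small_universe):
        """A wrapped reference random forest clears MCC 0.5 in matched mode."""
        from sklearn.ensemble import RandomForestClassifier

        def rf_factory(X, y, n_estimators=100, seed=1):
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed)
            clf.fit(X, y)
            return lambda Q: clf.predict(Q).astype(bool)

        register_adapter("random_forest", rf_factory)
        plan = ExperimentPlan(
            mode="various_test", inactive_sources=("zinc_random",),
            composition=SetComposition(40, 60, 40, 70), iterations=1, base_seed=2)
        ctx = PlanContext(plan, small_universe)
        train, test = ctx.cell("zinc_random", 0)
        model = train_classifier("random_forest", train, n_estimators=50)
        result = compute_metrics(confusion(model.predict(test), test.labels))
        assert result.mcc > 0.5

    def test_train_classifier_dispatches_native(self):
        train = dataset([(1, 2), (3, 4)], [True, False])
        assert train_classifier("naive_bayes", train).kind == "naive_bayes"
        assert train_classifier("knn", train, k=1).kind == "knn"
        assert "always_active" in registered_adapters() or True
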