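"""Permutation-split evaluation, paired t-tests, sweeps, mutual information."""

import numpy as np
import pytest
from scipy import stats

from ecogest import evaluation, io, preprocess, synth
from ecogest.evaluation import (
    hidden_unit_sweep,
    mutual_info,
    paired_t,
    permutation_eval,
)

from conftest import small_config


class FixedPredictor:
    """Duck-typed decoder predicting a constant class."""

    def __init__(self, label):
        self.label = label

    def accuracy(self, X, y):
        return float((np.asarray(y) == self.label).mean())


class LookupPredictor:
    """Oracle decoder: reads the true label encoded in the first feature."""

    def __init__(self, classes):
        self.classes = classes

    def accuracy(self, X, y):
        preds = self.classes[X[:, 0, 0].astype(int)]
        return float((preds == np.asarray(y)).mean())


def balanced_dataset(n=30):
    classes = np.array(["a", "b", "c"])
    y = np.repeat(classes, n // 3)
    X = np.zeros((n, 2, 1))
    X[:, 0, 0] = np.repeat([0, 1, 2], n // 3)  # encodes the label
    return X, y, classes


class TestPermutationEval:
    def test_majority_class_decoder_scores_one_third_on_balanced_data(self):
        X, y, classes = balanced_dataset()
        accs = permutation_eval(
            {"maj": lambda Xt, yt, s: FixedPredictor("a")},
            {"maj": (X, y)},
            n_trials=40,
            seed=0,
        )
        assert accs["maj"].mean() == pytest.approx(1 / 3, abs=0.02)

    def test_oracle_decoder_is_always_perfect(self):
        X, y, classes = balanced_dataset()
        accs = permutation_eval(
            {"oracle": lambda Xt, yt, s: LookupPredictor(classes)},
            {"oracle": (X, y)},
            n_trials=20,
            seed=1,
        )
        assert (accs["oracle"] == 1.0).all()

    def test_identical_factories_share_splits_and_results(self):
        X, y, classes = balanced_dataset()
        factory = lambda Xt, yt, s: LookupPredictor(classes)
        accs = permutation_eval(
            {"a": factory, "b": factory},
            {"a": (X, y), "b": (X, y)},
            n_trials=15,
            seed=2,
        )
        assert np.array_equal(accs["a"], accs["b"])

    def test_mismatched_label_vectors_rejected(self):
        X, y, classes = balanced_dataset()
        with pytest.raises(ValueError, match="label"):
            permutation_eval(
                {"a": lambda *_: FixedPredictor("a"), "b": lambda *_: FixedPredictor("a")},
                {"a": (X, y), "b": (X, y[::-1])},
                n_trials=2,
            )

    def test_accuracies_are_exchangeable_across_trials(self):
        rng = np.random.default_rng(3)
        X, y, classes = balanced_dataset(60)

        class Noisy:
            def accuracy(self, X_, y_):
                return float((rng.random(len(y_)) < 0.5).mean())

        accs = permutation_eval(
            {"n": lambda *_: Noisy()}, {"n": (X, y)}, n_trials=60, seed=4
        )["n"]
        ks = stats.ks_2samp(accs[:30], accs[30:])
        assert ks.pvalue > 0.01


class TestPairedT:
    def test_hand_computed_example(self):
        b = np.array([0.0, 0.0, 0.0])
        a = np.array([1.0, 2.0, 3.0])
        t, p = paired_t(a, b)
        # differences [1,2,3]: mean 2, sd 1, t = 2 / (1/sqrt(3))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(20), rng.random(20)
        t1, p1 = paired_t(a, b)
        t2, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_differences_rejected(self):
        a = np.array([0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(a, a + 0.1)


class TestHiddenUnitSweep:
    def test_reports_one_entry_per_size_and_picks_the_argmax(self):
        rng = np.random.default_rng(6)
        X = rng.normal(scale=0.3, size=(40, 4, 2))
        y = np.arange(40) % 2
        X[y == 1, :, 0] += 2.0
        from ecogest.decoder import DecoderConfig

        table, best = hidden_unit_sweep(
            X[:30], y[:30], X[30:], y[30:],
            sizes=(4, 8), cfg=DecoderConfig(max_epochs=25, seed=0), n_seeds=2,
        )
        assert set(table) == {4, 8}
        assert table[best][0] == max(m for m, _ in table.values())


class TestMutualInfo:
    def test_independent_feature_carries_almost_no_information(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=300)
            y = np.repeat(["a", "b", "c"], 100)
            vals.append(mutual_info(x, y))
        assert np.mean(vals) < 0.05

    def test_label_identity_feature_carries_log2_3_bits(self):
        y = np.repeat(["a", "b", "c"], 50)
        x = np.repeat([0.0, 1.0, 2.0], 50)
        assert mutual_info(x, y) == pytest.approx(np.log2(3), abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        y = np.where(x + rng.normal(scale=0.5, size=300) > 0, "hi", "lo")
        assert mutual_info(np.exp(x), y) == pytest.approx(mutual_info(x, y), abs=1e-12)

    def test_constant_feature_has_zero_information(self):
        y = np.repeat(["a", "b"], 20)
        assert mutual_info(np.ones(40), y) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mutual_info(np.arange(10.0), np.repeat("a", 10))


class TestRapidSweep:
    def test_reports_one_point_per_interval_per_decoder(self):
        cfg = small_config(n_trials=18, seed=3)
        rec, glove, truth = synth.generate_session(cfg)
        onsets = io.detect_trial_onsets(rec.events, glove, cfg.glove_threshold)

        classes = np.unique(truth.labels)

        class Chance:
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def accuracy(self, X, y):
                return float((self.rng.choice(classes, len(y)) == y).mean())

        factories = {"chance": lambda Xt, yt, s: Chance(s)}
        report = evaluation.rapid_eval_sweep(
            rec, onsets, factories, intervals_ms=(300.0, 600.0), n_trials=3, seed=0
        )
        assert len(report.curves) == 2
        assert {c["interval_ms"] for c in report.curves} == {300.0, 600.0}


class TestKFoldEval:
    def test_per_fold_validation_split_protocol(self):
        from ecogest.decoder import DecoderConfig
        from ecogest.decoder import train_decoder

        rng = np.random.default_rng(9)
        X = rng.normal(scale=0.3, size=(60, 4, 2))
        y = np.repeat(["a", "b", "c"], 20)
        X[y == "b", :, 0] += 2.0
        X[y == "c", :, 1] += 2.0

        def factory(X_tr, y_tr, X_val, y_val, seed):
            return train_decoder(
                X_tr, y_tr, X_val, y_val,
                cfg=DecoderConfig(hidden_size=8, max_epochs=40, seed=seed),
            )

        accs = evaluation.kfold_eval(factory, X, y, n_folds=5, seed=0)
        assert accs.shape == (5,)
        assert accs.mean() > 0.8  # plainly separable
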