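import warnings

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from chromloop import (
    Dataset,
    EnsembleModel,
    ModelConfig,
    PerturbationConfig,
    balanced_test_set,
    chromosome_folds,
    compute_metrics,
    ensemble_predict,
    fold_indices,
    make_negative_subsets,
    perturb_sequence,
    run_cv,
    train_submodel,
)

from conftest import make_sample, random_dna


def dataset_with(n_pos, n_neg, n_chroms=20, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        samples.append(make_sample(
            sid=f"x{i}", chrom=f"chr{i % n_chroms + 1}", label=label,
            seq1="ACGT" * 5, seq2="TTGG" * 5, features=rng.normal(size=2),
        ))
    return Dataset(samples=samples, feature_names=["a", "b"])


class TestChromosomeFolds:
    def test_even_partition(self):
        ds = dataset_with(20, 40, n_chroms=20)
        plan = chromosome_folds(ds, n_folds=10, seed=0)
        assert all(len(test) == 2 for _, test in plan.folds)

    def test_no_leakage_between_train_and_test(self):
        ds = dataset_with(10, 50, n_chroms=12)
        plan = chromosome_folds(ds, n_folds=6, seed=3)
        for f in range(6):
            tr, te = fold_indices(ds, plan, f)
            tr_chroms = {ds.samples[i].chrom for i in tr}
            te_chroms = {ds.samples[i].chrom for i in te}
            assert not (tr_chroms & te_chroms)
            assert not (set(tr) & set(te))

    def test_seed_determinism(self):
        ds = dataset_with(10, 50)
        a = chromosome_folds(ds, 10, seed=5)
        b = chromosome_folds(ds, 10, seed=5)
        c = chromosome_folds(ds, 10, seed=6)
        assert a.folds == b.folds
        assert a.folds != c.folds

    def test_too_few_chromosomes(self):
        ds = dataset_with(4, 8, n_chroms=4)
        with pytest.raises(ValueError):
            chromosome_folds(ds, n_folds=10)


class TestNegativeSubsets:
    def test_forced_ten_to_one_partition(self):
        ds = dataset_with(100, 1000)
        subsets = make_negative_subsets(ds, seed=1)
        assert len(subsets) == 10
        labels = ds.labels
        for sub in subsets:
            assert sum(labels[i] for i in sub) == 100
            assert len(sub) == 200

    def test_remainder_dealing(self):
        ds = dataset_with(100, 1050)
        subsets = make_negative_subsets(ds, seed=1)  # round(10.5) == 10
        assert len(subsets) == 10
        sizes = sorted(len(s) for s in subsets)
        assert sizes[-1] - sizes[0] <= 1

    def test_negatives_partitioned_exactly(self):
        ds = dataset_with(7, 31)
        subsets = make_negative_subsets(ds, seed=2)
        labels = ds.labels
        neg_lists = [[i for i in sub if labels[i] == 0] for sub in subsets]
        flat = [i for lst in neg_lists for i in lst]
        assert len(flat) == len(set(flat)) == 31

    def test_empty_class_rejected(self):
        ds = dataset_with(5, 0)
        with pytest.raises(ValueError):
            make_negative_subsets(ds)


class _StubModel:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X, feats=None):
        n = len(X) if X is not None else len(feats)
        return np.full(n, self.p)


class TestEnsemblePredict:
    def _ensemble(self, probs):
        cfg = ModelConfig(vocab_size=8, embed_dim=4, max_tokens=4)
        return EnsembleModel(submodels=[_StubModel(p) for p in probs],
                             config=cfg)

    def test_arithmetic_mean(self):
        ens = self._ensemble([0.2, 0.4, 0.9])
        batch = ensemble_predict(ens, np.zeros((3, 8, 4), dtype=int))
        assert batch.probabilities == pytest.approx([0.5, 0.5, 0.5])

    def test_single_submodel_is_identity(self):
        ens = self._ensemble([0.7])
        X = np.zeros((2, 8, 4), dtype=int)
        assert np.array_equal(ens.predict_proba(X),
                              ens.submodels[0].predict_proba(X))

    def test_mean_within_submodel_range(self, rng):
        probs = rng.random(5)
        ens = self._ensemble(list(probs))
        out = ens.predict_proba(np.zeros((4, 8, 4), dtype=int))
        assert (out >= probs.min() - 1e-12).all()
        assert (out <= probs.max() + 1e-12).all()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel(submodels=[], config=ModelConfig())


class TestTrainSubmodel:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        F = y[:, None] + rng.normal(0, 0.5, size=(n, 3))
        return F, y

    def test_stratified_split_and_best_checkpoint(self):
        F, y = self._data(200)
        cfg = ModelConfig(mode="genomic", genomic_dense_units=(8, 4),
                          dropout_rate=0.0, max_epochs=10, patience=3)
        net, hist = train_submodel(None, F, y, cfg, seed=4)
        idx = np.arange(len(y))
        tr, va = train_test_split(idx, test_size=0.1, stratify=y,
                                  random_state=4)
        assert len(tr) == 180 and len(va) == 20
        assert y[va].sum() == 10  # stratified
        # returned weights reproduce the recorded best validation loss
        assert net.loss(None, F[va], y[va]) == pytest.approx(
            hist.best_val_loss, abs=1e-12)

    def test_patience_zero_stops_immediately_after_best(self):
        F, y = self._data(100)
        cfg = ModelConfig(mode="genomic", genomic_dense_units=(4,),
                          dropout_rate=0.0, max_epochs=30, patience=0)
        _, hist = train_submodel(None, F, y, cfg, seed=0)
        n_epochs = len(hist.val_loss)
        assert n_epochs <= hist.best_epoch + 2 or n_epochs == 30

    def test_single_class_rejected(self):
        F = np.zeros((10, 2))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError):
            train_submodel(None, F, y, ModelConfig(mode="genomic"))


class TestBalancedTestSet:
    def test_thirty_against_three_hundred(self):
        labels = np.array([1] * 30 + [0] * 300)
        out = balanced_test_set(range(330), labels, seed=0)
        assert len(out) == 60
        assert labels[out].sum() == 30

    def test_seed_deterministic(self):
        labels = np.array([1] * 5 + [0] * 50)
        assert balanced_test_set(range(55), labels, seed=9) == \
            balanced_test_set(range(55), labels, seed=9)

    def test_positive_fraction_half(self, rng):
        labels = np.zeros(80, dtype=int)
        labels[rng.choice(80, size=13, replace=False)] = 1
        out = balanced_test_set(range(80), labels, seed=1)
        assert labels[out].mean() == 0.5

    def test_more_positives_than_negatives_warns(self):
        labels = np.array([1] * 10 + [0] * 3)
        with pytest.warns(UserWarning):
            out = balanced_test_set(range(13), labels, seed=0)
        assert len(out) == 13


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (m.auprc, m.acc, m.mcc, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted_predictions(self):
        m = compute_metrics([1, 1, 0, 0], [0.1, 0.2, 0.9, 0.8])
        assert m.mcc == -1.0

    def test_confusion_counts_sum(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        p = rng.random(50)
        m = compute_metrics(y, p)
        assert sum(m.confusion) == 50

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1, 1], [0.5, 0.6, 0.7])


class TestRunCV:
    def _leaky_dataset(self, seed=0):
        """Chromosome-conditional feature signal: exploitable only when a
        chromosome appears in both train and test."""
        rng = np.random.default_rng(seed)
        samples = []
        signs = {f"chr{c}": rng.choice([-1, 1]) for c in range(1, 11)}
        codes = {f"chr{c}": rng.normal(size=3) for c in range(1, 11)}
        for i in range(300):
            chrom = f"chr{i % 10 + 1}"
            label = 1 if i % 6 == 0 else 0
            feat = np.concatenate([
                codes[chrom],
                [signs[chrom] * (2 * label - 1) + rng.normal(0, 0.7)],
            ])
            samples.append(make_sample(sid=f"s{i}", chrom=chrom, label=label,
                                       seq1="ACGT", seq2="ACGT",
                                       features=feat))
        return Dataset(samples=samples, feature_names=list("abcd"))

    def test_within_cell_returns_report_per_fold(self):
        ds = self._leaky_dataset()
        cfg = ModelConfig(mode="genomic", genomic_dense_units=(8, 4),
                          dropout_rate=0.0, max_epochs=8, patience=2)
        results = run_cv(ds, cfg, protocol="within_cell", n_folds=5, seed=0)
        assert len(results) == 5
        assert all(r.metrics is not None for r in results if r.valid)

    def test_cross_cell_matched_uses_held_out_cell_and_chromosomes(self):
        ds = self._leaky_dataset(0)
        other = self._leaky_dataset(1)
        for s in other.samples:
            s.id = "o" + s.id
        cfg = ModelConfig(mode="genomic", genomic_dense_units=(4,),
                          dropout_rate=0.0, max_epochs=4, patience=1)
        results = run_cv(ds, cfg, protocol="cross_cell_matched", n_folds=5,
                         seed=0, test_dataset=other, folds=[0])
        (res,) = results
        assert set(res.test_chroms) <= {s.chrom for s in other.samples}

    def test_plain_cv_inflates_metrics_on_leaky_fixture(self):
        ds = self._leaky_dataset()
        cfg = ModelConfig(mode="genomic", genomic_dense_units=(8, 4),
                          dropout_rate=0.0, max_epochs=12, patience=3)
        plain = run_cv(ds, cfg, protocol="cross_cell_plain", n_folds=5, seed=1)
        grouped = run_cv(ds, cfg, protocol="within_cell", n_folds=5, seed=1)
        mean = lambda rs: np.mean([r.metrics.auprc for r in rs if r.valid])
        assert mean(plain) > mean(grouped)


class TestPerturbSequence:
    def test_rate_zero_identity(self, rng):
        seq = random_dna(rng, 500)
        cfg = PerturbationConfig(rate=0.0)
        assert perturb_sequence(seq, cfg) == seq

    def test_rate_one_substitution_only(self, rng):
        seq = random_dna(rng, 300)
        cfg = PerturbationConfig(rate=1.0, type_weights=(1, 0, 0), seed=2)
        out = perturb_sequence(seq, cfg)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_deterministic_for_fixed_seed(self, rng):
        seq = random_dna(rng, 400)
        cfg = PerturbationConfig(rate=0.2, seed=11)
        assert perturb_sequence(seq, cfg) == perturb_sequence(seq, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PerturbationConfig(rate=1.5)
        with pytest.raises(ValueError):
            PerturbationConfig(rate=0.1, type_weights=(0, 0, 0))
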