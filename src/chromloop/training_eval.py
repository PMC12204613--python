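"""Chromosome-grouped cross-validation, imbalance-aware ensemble training,
metrics, cross-cell protocols, and the sequence-perturbation harness.

Interaction datasets are heavily imbalanced (1 positive : 10 negatives) and
positionally autocorrelated, so two safeguards shape evaluation here: folds
are grouped by chromosome (no chromosome contributes samples to both train and
test of a fold), and test sets are balanced by random undersampling of
negatives before metrics are computed. Class imbalance in training is handled
by partitioning the negatives into ``round(neg/pos)`` subsets, training one
sub-model per subset on that subset plus all positives, and averaging the
sub-model probabilities at prediction time.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
)
from sklearn.model_selection import train_test_split

from .io_formats import Dataset
from .model import Adam, InteractionNet, ModelConfig, PredictionBatch
from .tokenization import BPEVocabulary, encode_batch, train_bpe


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Per-fold (train chromosomes, test chromosomes) partition."""

    folds: list[tuple[frozenset[str], frozenset[str]]]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        all_chroms: set[str] = set()
        for train, test in self.folds:
            if train & test:
                raise ValueError("train and test chromosome sets overlap")
            all_chroms |= train | test
        seen_test: list[str] = []
        for _, test in self.folds:
            seen_test.extend(test)
        if len(seen_test) != len(set(seen_test)) or set(seen_test) != all_chroms:
            raise ValueError("every chromosome must be in exactly one test set")


def chromosome_folds(dataset: Dataset, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Partition chromosomes into fold groups and derive train/test sets.

    Chromosomes are shuffled by the seed and split into ``n_folds`` groups as
    evenly as possible; the samples of a fold follow their chromosome.
    """
    for s in dataset.samples:
        if s.interval1.chrom != s.interval2.chrom:
            raise ValueError(
                f"sample {s.id}: bins on different chromosomes; grouped "
                "splitting is undefined"
            )
    chroms = sorted({s.chrom for s in dataset.samples})
    if len(chroms) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct chromosomes, found {len(chroms)}"
        )
    rng = np.random.default_rng(seed)
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    groups = np.array_split(np.arange(len(order)), n_folds)
    folds = []
    for g in groups:
        test = frozenset(order[i] for i in g)
        train = frozenset(c for c in chroms if c not in test)
        folds.append((train, test))
    return FoldPlan(folds=folds, n_folds=n_folds, seed=seed)


def fold_indices(
    dataset: Dataset, plan: FoldPlan, fold: int
) -> tuple[list[int], list[int]]:
    """Sample indices (train, test) for one fold of the plan."""
    train_chroms, test_chroms = plan.folds[fold]
    train = [i for i, s in enumerate(dataset.samples) if s.chrom in train_chroms]
    test = [i for i, s in enumerate(dataset.samples) if s.chrom in test_chroms]
    return train, test


# ---------------------------------------------------------------------------
# Negative-subset ensembles
# ---------------------------------------------------------------------------


def make_negative_subsets(dataset: Dataset, seed: int = 0) -> list[list[int]]:
    """Deal negatives into ``round(neg/pos)`` disjoint subsets, each joined
    with all positives. Returns index lists into ``dataset.samples``.
    """
    pos = [i for i, s in enumerate(dataset.samples) if s.label == 1]
    neg = [i for i, s in enumerate(dataset.samples) if s.label == 0]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative sample")
    r = max(int(round(len(neg) / len(pos))), 1)
    rng = np.random.default_rng(seed)
    neg = [neg[i] for i in rng.permutation(len(neg))]
    subsets = []
    for i in range(r):
        subsets.append(pos + neg[i::r])
    return subsets


@dataclass
class EnsembleModel:
    """Trained sub-models whose averaged sigmoid output is the prediction."""

    submodels: list[InteractionNet]
    config: ModelConfig

    def __post_init__(self) -> None:
        if not self.submodels:
            raise ValueError("ensemble needs at least one sub-model")

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)

    def predict_proba(self, X, feats=None) -> np.ndarray:
        return np.mean(
            [m.predict_proba(X, feats) for m in self.submodels], axis=0
        )


def ensemble_predict(
    ensemble: EnsembleModel, X, feats=None, threshold: float | None = None
) -> PredictionBatch:
    """Arithmetic mean of sub-model probabilities, thresholded at 0.5."""
    probs = ensemble.predict_proba(X, feats)
    thr = ensemble.config.threshold if threshold is None else threshold
    return PredictionBatch.from_probabilities(probs, thr)


# ---------------------------------------------------------------------------
# Sub-model training
# ---------------------------------------------------------------------------


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    best_val_loss: float


def train_submodel(
    X: np.ndarray | None,
    feats: np.ndarray | None,
    y: np.ndarray,
    config: ModelConfig,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> tuple[InteractionNet, TrainHistory]:
    """Train one sub-model with a stratified 9:1 train/validation split,
    binary cross-entropy, Adam, and early stopping on validation loss.

    Returns the network restored to its best-validation-loss state.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset must contain both classes")
    idx = np.arange(len(y))
    tr_idx, va_idx = train_test_split(
        idx, test_size=val_fraction, stratify=y, random_state=seed
    )

    def take(arr, ix):
        return None if arr is None else np.asarray(arr)[ix]

    Xtr, Xva = take(X, tr_idx), take(X, va_idx)
    Ftr, Fva = take(feats, tr_idx), take(feats, va_idx)
    ytr, yva = y[tr_idx], y[va_idx]

    rng = np.random.default_rng(seed)
    net = InteractionNet(config, n_features=0 if feats is None else feats.shape[1],
                         rng=rng)
    opt = Adam(net.params, lr=config.lr)
    best_state = net.get_state()
    best_val = net.loss(Xva, Fva, yva)
    best_epoch = -1
    bad_epochs = 0
    history = TrainHistory([], [], best_epoch, best_val)

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            b = order[start : start + config.batch_size]
            if len(b) < 2:
                continue  # batch norm needs >= 2 samples
            loss, grads = net.loss_and_grads(
                take(Xtr, b), take(Ftr, b), ytr[b], rng=rng
            )
            opt.step(net.params, grads)
            epoch_loss += loss * len(b)
        history.train_loss.append(epoch_loss / len(ytr))
        val_loss = net.loss(Xva, Fva, yva)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    net.set_state(best_state)
    history.best_epoch = best_epoch
    history.best_val_loss = best_val
    return net, history


def train_ensemble(
    dataset: Dataset,
    train_idx: Sequence[int],
    config: ModelConfig,
    vocab: BPEVocabulary | None = None,
    encoded: np.ndarray | None = None,
    seed: int = 0,
    topk: int | None = None,
) -> tuple[EnsembleModel, BPEVocabulary | None]:
    """Train a negative-subset ensemble on the given training indices.

    The BPE vocabulary, if needed and not supplied, is learned from the
    training-split sequences only (both bins, forward strand) — test
    sequences never influence it. ``encoded`` may carry pre-computed
    (N, 8, max_tokens) channels for the whole dataset to avoid re-encoding.
    """
    train_idx = list(train_idx)
    use_seq = config.mode != "genomic"
    if use_seq and vocab is None:
        corpus = []
        for i in train_idx:
            corpus.append(dataset.samples[i].seq1)
            corpus.append(dataset.samples[i].seq2)
        vocab = train_bpe(corpus, target_size=config.vocab_size)
    if use_seq and encoded is None:
        encoded = encode_batch(
            dataset.samples, vocab, k=topk or config.max_tokens,
            max_tokens=config.max_tokens,
        )
    feats_all = dataset.feature_matrix() if config.mode != "seq" else None
    labels = dataset.labels

    train_ds = dataset.subset(train_idx)
    subsets = make_negative_subsets(train_ds, seed=seed)
    submodels = []
    for si, subset_local in enumerate(subsets):
        global_idx = [train_idx[j] for j in subset_local]
        Xs = encoded[global_idx] if use_seq else None
        Fs = feats_all[global_idx] if feats_all is not None else None
        net, _ = train_submodel(Xs, Fs, labels[global_idx], config,
                                seed=seed * 1000 + si)
        submodels.append(net)
    return EnsembleModel(submodels=submodels, config=config), vocab


# ---------------------------------------------------------------------------
# Balanced evaluation and metrics
# ---------------------------------------------------------------------------


def balanced_test_set(indices: Sequence[int], labels: np.ndarray,
                      seed: int = 0) -> list[int]:
    """Undersample negatives (without replacement) to match the positives."""
    indices = list(indices)
    pos = [i for i in indices if labels[i] == 1]
    neg = [i for i in indices if labels[i] == 0]
    if not pos:
        raise ValueError("test fold has no positive samples")
    if len(pos) > len(neg):
        warnings.warn("more positives than negatives; keeping all negatives")
        chosen = neg
    else:
        rng = np.random.default_rng(seed)
        chosen = [neg[i] for i in rng.choice(len(neg), size=len(pos), replace=False)]
    return sorted(pos + chosen)


@dataclass
class MetricsReport:
    auprc: float
    acc: float
    mcc: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    n: int


def compute_metrics(labels: Sequence[int], probabilities: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    """AUPRC (step-wise precision-recall integration) plus thresholded
    accuracy, Matthews correlation, and F1."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC/MCC are undefined for single-class labels")
    pred = (p > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return MetricsReport(
        auprc=float(average_precision_score(y, p)),
        acc=float(accuracy_score(y, pred)),
        mcc=float(matthews_corrcoef(y, pred)),
        f1=float(f1_score(y, pred)),
        confusion=(tp, fp, tn, fn),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    test_chroms: list[str]
    metrics: MetricsReport | None
    valid: bool  # False when the test set lacks positives


def run_cv(
    dataset: Dataset,
    config: ModelConfig,
    protocol: str = "within_cell",
    n_folds: int = 10,
    seed: int = 0,
    test_dataset: Dataset | None = None,
    folds: Sequence[int] | None = None,
    topk: int | None = None,
) -> list[FoldResult]:
    """Cross-validated ensemble evaluation.

    ``within_cell``: chromosome-grouped folds on one dataset.
    ``cross_cell_matched``: grouped folds planned on the training cell line;
    each fold's test chromosomes select the evaluation samples from the other
    cell line (``test_dataset``).
    ``cross_cell_plain``: standard (non-grouped) K-fold over samples —
    included to demonstrate the leakage inflation this causes.
    """
    if protocol not in ("within_cell", "cross_cell_matched", "cross_cell_plain"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if protocol == "cross_cell_matched" and test_dataset is None:
        raise ValueError("cross_cell_matched requires test_dataset")

    labels = dataset.labels
    results: list[FoldResult] = []

    if protocol == "cross_cell_plain":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(dataset))
        groups = np.array_split(order, n_folds)
        fold_sets = [
            (sorted(set(range(len(dataset))) - set(g.tolist())), sorted(g.tolist()))
            for g in groups
        ]
        chrom_info = [[] for _ in fold_sets]
    else:
        plan = chromosome_folds(dataset, n_folds=n_folds, seed=seed)
        fold_sets, chrom_info = [], []
        for f in range(n_folds):
            tr, te = fold_indices(dataset, plan, f)
            if protocol == "cross_cell_matched":
                test_chroms = plan.folds[f][1]
                te = [
                    i for i, s in enumerate(test_dataset.samples)
                    if s.chrom in test_chroms
                ]
            fold_sets.append((tr, te))
            chrom_info.append(sorted(plan.folds[f][1]))

    eval_ds = test_dataset if protocol == "cross_cell_matched" else dataset
    eval_labels = eval_ds.labels
    chosen = range(n_folds) if folds is None else folds
    for f in chosen:
        tr, te = fold_sets[f]
        if not any(eval_labels[i] == 1 for i in te):
            results.append(FoldResult(f, chrom_info[f], None, valid=False))
            continue
        ensemble, vocab = train_ensemble(
            dataset, tr, config, seed=seed + f, topk=topk
        )
        bal = balanced_test_set(te, eval_labels, seed=seed + f)
        use_seq = config.mode != "genomic"
        Xte = (
            encode_batch([eval_ds.samples[i] for i in bal], vocab,
                         k=topk or config.max_tokens,
                         max_tokens=config.max_tokens)
            if use_seq else None
        )
        Fte = (
            np.stack([eval_ds.samples[i].features for i in bal])
            if config.mode != "seq" else None
        )
        batch = ensemble_predict(ensemble, Xte, Fte)
        report = compute_metrics(eval_labels[bal], batch.probabilities,
                                 threshold=config.threshold)
        results.append(FoldResult(f, chrom_info[f], report, valid=True))
    return results


# ---------------------------------------------------------------------------
# Sequence perturbation
# ---------------------------------------------------------------------------


@dataclass
class PerturbationConfig:
    """Per-base mutation model: each base independently suffers an event with
    probability ``rate``; the event type is drawn from ``type_weights``
    (substitution, insertion, deletion), default 10:1:1."""

    rate: float
    type_weights: tuple[float, float, float] = (10.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must be in [0, 1]")
        w = np.asarray(self.type_weights, dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("type weights must be non-negative, not all zero")


_BASES = np.array(list("ACGT"))


def perturb_sequence(sequence: str, cfg: PerturbationConfig,
                     rng: np.random.Generator | None = None,
                     return_counts: bool = False):
    """Apply point mutations, single-base insertions, and deletions.

    Substitution replaces the base with a different uniform base; deletion
    removes it; insertion adds one uniform base after it. Deterministic for a
    fixed config seed (or supplied generator). With ``return_counts`` the
    per-type event tally is returned alongside the mutated sequence.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    counts = {"substitution": 0, "insertion": 0, "deletion": 0}
    n = len(sequence)
    hit = rng.random(n) < cfg.rate if (n and cfg.rate > 0) else np.zeros(0, bool)
    if not hit.any():
        return (sequence, counts) if return_counts else sequence
    w = np.asarray(cfg.type_weights, dtype=float)
    p = w / w.sum()
    kinds = rng.choice(3, size=int(hit.sum()), p=p)  # 0=sub, 1=ins, 2=del
    out = []
    ki = 0
    for i, ch in enumerate(sequence):
        if not hit[i]:
            out.append(ch)
            continue
        kind = kinds[ki]
        ki += 1
        if kind == 0:  # substitute with a different base
            options = [b for b in "ACGT" if b != ch] or list("ACGT")
            out.append(options[rng.integers(len(options))])
            counts["substitution"] += 1
        elif kind == 1:  # insert after
            out.append(ch)
            out.append(_BASES[rng.integers(4)])
            counts["insertion"] += 1
        else:  # deletion -> emit nothing
            counts["deletion"] += 1
    mutated = "".join(out)
    return (mutated, counts) if return_counts else mutated
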