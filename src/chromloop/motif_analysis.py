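"""PWM motif scanning, matched-region erasure, and corrected importance scores.

A motif match is a length-L window whose summed PWM score reaches the motif's
threshold; thresholds are calibrated to a tail p-value under an i.i.d.
background by exact dynamic programming on a discretized score grid. Erasure
replaces matched positions with uniform random bases and the trained model is
re-applied; the drop in AUPRC (delta), normalized by the motif's mean
occurrence per sample and re-weighted by an entropy-derived correction factor
``alpha * f * log2(alpha * f) + 1``, yields the importance score. With
``alpha = NUM_M / e`` the factor is minimal when a motif's length-weighted
proportion f equals 1/NUM_M and grows on either side, up-weighting motifs
whose share of all matched sequence deviates from uniform.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BinPairSample, MotifModel
from .training_eval import EnsembleModel, compute_metrics
from .tokenization import BPEVocabulary, encode_batch

_CODE = {c: i for i, c in enumerate("ACGTN")}


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    sample_id: str
    seq_index: int  # 1 or 2
    offset: int
    length: int
    score: float


def pwm_window_score(window: str, pwm: np.ndarray) -> float:
    """Summed PWM score of a window; undefined (error) for windows with N."""
    pwm = np.asarray(pwm, dtype=float)
    if len(window) != pwm.shape[0]:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.shape[0]}"
        )
    total = 0.0
    for i, ch in enumerate(window):
        j = _CODE.get(ch)
        if j is None or j > 3:
            raise ValueError(f"window contains non-ACGT base {ch!r}")
        total += pwm[i, j]
    return total


def _encode_codes(sequence: str) -> np.ndarray:
    return np.frombuffer(
        sequence.encode("ascii").translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    )


def window_scores(sequence: str, pwm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all L_s - L_m + 1 step-1 windows and their validity.

    Windows containing N are marked invalid (score undefined, reported 0).
    """
    pwm = np.asarray(pwm, dtype=float)
    L = pwm.shape[0]
    codes = _encode_codes(sequence)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    padded = np.hstack([pwm, np.zeros((L, 1))])  # N column scores 0, masked out
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        c = codes[i : i + n]
        valid &= c < 4
        scores += padded[i][c]
    scores[~valid] = 0.0
    return scores, valid


def scan_sequence(sequence: str, motif: MotifModel,
                  sample_id: str = "", seq_index: int = 1) -> list[MotifMatch]:
    """All windows with score >= the motif threshold, in offset order."""
    if motif.threshold is None:
        raise ValueError(f"motif {motif.name}: threshold not set")
    scores, valid = window_scores(sequence, motif.pwm)
    hits = np.nonzero(valid & (scores >= motif.threshold))[0]
    return [
        MotifMatch(motif.name, sample_id, seq_index, int(i), motif.length,
                   float(scores[i]))
        for i in hits
    ]


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------


def score_distribution(
    pwm: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    precision: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of window scores under an i.i.d. background.

    PWM entries are quantized to multiples of ``precision`` and the
    distribution of their sum is built by dynamic-programming convolution of
    the per-position distributions. Returns (grid scores ascending, probs).
    """
    pwm = np.asarray(pwm, dtype=float)
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must sum to 1")
    q = np.rint(pwm / precision).astype(np.int64)
    dist = np.array([1.0])
    lo = 0
    for i in range(q.shape[0]):
        row = q[i]
        row_lo = int(row.min())
        width = len(dist) + int(row.max()) - row_lo
        new = np.zeros(width)
        for j in range(4):
            off = int(row[j]) - row_lo
            new[off : off + len(dist)] += bg[j] * dist
        dist = new
        lo += row_lo
    scores = (lo + np.arange(len(dist))) * precision
    return scores, dist


def pvalue_threshold(
    pwm: np.ndarray,
    pvalue: float,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    precision: float = 1e-4,
) -> float:
    """Smallest score whose tail probability P(Q >= s) is <= pvalue.

    As pvalue -> 1 this approaches the minimal achievable score. If even the
    maximal score has tail mass above pvalue, a value just beyond it is
    returned, so that nothing matches.
    """
    if not (0.0 < pvalue < 1.0) and pvalue != 1.0:
        raise ValueError("pvalue must be in (0, 1]")
    scores, dist = score_distribution(pwm, background, precision)
    support = dist > 0
    scores, dist = scores[support], dist[support]
    if len(scores) == 1:
        warnings.warn("degenerate PWM: every window has the same score; "
                      "threshold is undefined")
        return float(scores[0])
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= pvalue + 1e-15)[0]
    if len(ok) == 0:
        return float(scores[-1] + precision)
    return float(scores[ok[0]])


def assign_thresholds(
    motifs: Sequence[MotifModel],
    pvalue: float = 1e-4,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    precision: float = 1e-4,
) -> None:
    """Set each motif's threshold to its p-value-calibrated score, in place."""
    for m in motifs:
        m.threshold = pvalue_threshold(m.pwm, pvalue, background, precision)
        m.pvalue = pvalue


# ---------------------------------------------------------------------------
# Erasure
# ---------------------------------------------------------------------------


def erase_matches(sequence: str, matches: Sequence[MotifMatch],
                  rng: np.random.Generator) -> str:
    """Replace the union of matched intervals with uniform random bases.

    Length-preserving; positions outside matches are untouched; overlapping
    matches are erased once.
    """
    if not matches:
        return sequence
    mask = np.zeros(len(sequence), dtype=bool)
    for m in matches:
        if m.offset < 0 or m.offset + m.length > len(sequence):
            raise ValueError(
                f"match [{m.offset}, {m.offset + m.length}) out of bounds "
                f"for length {len(sequence)}"
            )
        mask[m.offset : m.offset + m.length] = True
    chars = np.array(list(sequence))
    n_erase = int(mask.sum())
    chars[mask] = np.array(list("ACGT"))[rng.integers(0, 4, size=n_erase)]
    return "".join(chars)


def _match_rng(seed: int, sample_id: str, motif_name: str) -> np.random.Generator:
    """RNG stream keyed by (sample, motif) so per-motif erasures are
    reproducible and independent of iteration order."""
    key = [seed & 0x7FFFFFFF,
           zlib.crc32(sample_id.encode()) & 0x7FFFFFFF,
           zlib.crc32(motif_name.encode()) & 0x7FFFFFFF]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Statistics and scores
# ---------------------------------------------------------------------------


@dataclass
class MotifStats:
    """Per-motif occurrence statistics over a sample set.

    ``C_m`` is the mean match count per sample (both bin sequences counted
    together); ``f_m`` the length-weighted proportion; ``C`` the sum of the
    C_m; ``alpha`` the correction factor base.
    """

    C_m: dict[str, float]
    l_m: dict[str, int]
    f_m: dict[str, float]
    C: float
    num_samples: int
    num_motifs: int
    alpha: float
    alpha_rule: str


def count_matches(samples: Sequence[BinPairSample],
                  motifs: Sequence[MotifModel]) -> dict[str, np.ndarray]:
    """Per-sample match counts (both sequences) for every motif."""
    out = {}
    for motif in motifs:
        counts = np.zeros(len(samples), dtype=int)
        for i, s in enumerate(samples):
            counts[i] = len(scan_sequence(s.seq1, motif, s.id, 1)) + len(
                scan_sequence(s.seq2, motif, s.id, 2)
            )
        out[motif.name] = counts
    return out


def motif_statistics(samples: Sequence[BinPairSample],
                     motifs: Sequence[MotifModel],
                     alpha_rule: str = "corrected") -> MotifStats:
    """Occurrence statistics feeding the importance score.

    ``alpha_rule='corrected'`` uses alpha = NUM_M / e (the value for which the
    correction factor attains its minimum at f = 1/NUM_M); ``'as_printed'``
    uses alpha = e / NUM_M.
    """
    if not samples:
        raise ValueError("need at least one sample")
    counts = count_matches(samples, motifs)
    num_m = len(motifs)
    C_m = {name: float(c.mean()) for name, c in counts.items()}
    l_m = {m.name: m.length for m in motifs}
    denom = sum(C_m[n] * l_m[n] for n in C_m)
    if denom == 0:
        raise ValueError("no motif matched any sample; proportions undefined")
    f_m = {n: C_m[n] * l_m[n] / denom for n in C_m}
    if alpha_rule == "corrected":
        alpha = num_m / math.e
    elif alpha_rule == "as_printed":
        alpha = math.e / num_m
    else:
        raise ValueError(f"alpha_rule must be 'corrected' or 'as_printed'")
    return MotifStats(C_m=C_m, l_m=l_m, f_m=f_m, C=float(sum(C_m.values())),
                      num_samples=len(samples), num_motifs=num_m,
                      alpha=alpha, alpha_rule=alpha_rule)


def correction_factor(f_m: float, alpha: float) -> float:
    """Entropy-derived bracket term ``alpha*f*log2(alpha*f) + 1``."""
    if f_m <= 0:
        raise ValueError("f_m must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    af = alpha * f_m
    return af * math.log2(af) + 1.0


def importance_score(delta: float, C_m: float, f_m: float, alpha: float) -> float:
    """``(delta / C_m) * correction_factor(f_m, alpha)``; needs C_m > 0."""
    if C_m <= 0:
        raise ValueError("importance score undefined for motifs that never match")
    return (delta / C_m) * correction_factor(f_m, alpha)


def shannon_entropy(probabilities: Sequence[float]) -> float:
    """Shannon entropy in bits; 0*log(0) taken as 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# Erasure experiment
# ---------------------------------------------------------------------------


@dataclass
class ImportanceRecord:
    motif: str
    condition: str
    P: float
    P_prime: float | None
    delta: float | None
    C_m: float
    f_m: float | None
    bracket: float | None
    score: float | None
    rank: int | None = None
    top20: bool = False


def _erased_samples(samples: Sequence[BinPairSample], motif: MotifModel,
                    condition: str, seed: int) -> list[tuple[str, str]]:
    """(seq1, seq2) per sample with the motif's matches erased per condition."""
    out = []
    for s in samples:
        rng = _match_rng(seed, s.id, motif.name)
        seq1, seq2 = s.seq1, s.seq2
        if condition in ("seq1_only", "both"):
            seq1 = erase_matches(seq1, scan_sequence(seq1, motif, s.id, 1), rng)
        if condition in ("seq2_only", "both"):
            seq2 = erase_matches(seq2, scan_sequence(seq2, motif, s.id, 2), rng)
        out.append((seq1, seq2))
    return out


@dataclass
class ErasureGroup:
    """One evaluation unit of an erasure experiment: a trained ensemble with
    the held-out samples it scores (e.g. one chromosome fold)."""

    ensemble: EnsembleModel
    samples: list[BinPairSample]
    vocab: BPEVocabulary
    baseline_X: np.ndarray | None = None
    topk: int | None = None


def _group_probs(group: ErasureGroup, motif: MotifModel | None,
                 condition: str, seed: int) -> np.ndarray:
    """Ensemble probabilities for a group, with a motif optionally erased."""
    from .tokenization import encode_pair

    cfg = group.ensemble.config
    k = group.topk or cfg.max_tokens
    feats = (np.stack([s.features for s in group.samples])
             if cfg.mode != "seq" else None)
    if group.baseline_X is None:
        group.baseline_X = encode_batch(group.samples, group.vocab, k=k,
                                        max_tokens=cfg.max_tokens)
    if motif is None:
        return group.ensemble.predict_proba(group.baseline_X, feats)
    X = group.baseline_X.copy()
    pairs = _erased_samples(group.samples, motif, condition, seed)
    for i, (s, (e1, e2)) in enumerate(zip(group.samples, pairs)):
        if e1 is not s.seq1 or e2 is not s.seq2:
            mod = type(s)(id=s.id, interval1=s.interval1,
                          interval2=s.interval2, seq1=e1, seq2=e2,
                          features=s.features, label=s.label, chrom=s.chrom)
            X[i] = encode_pair(mod, group.vocab, k=k,
                               max_tokens=cfg.max_tokens).channels
    return group.ensemble.predict_proba(X, feats)


def pooled_erasure_experiment(
    groups: Sequence[ErasureGroup],
    motifs: Sequence[MotifModel],
    condition: str = "both",
    seed: int = 0,
    stats: MotifStats | None = None,
    n_replicates: int = 1,
) -> list[ImportanceRecord]:
    """Erasure experiment with predictions pooled over evaluation groups.

    For each motif, its matches are erased in the designated sequence(s) of
    every group's samples; each group's own trained ensemble re-predicts its
    samples, the probabilities are pooled, and the AUPRC drop delta = P - P'
    is averaged over ``n_replicates`` independent erasure-noise draws.
    Averaging per-group AUPRC (rather than pooling raw probabilities, whose
    calibration differs between independently trained ensembles) stabilises
    the estimates without ever scoring a sample with a model trained on its
    chromosome.
    """
    if condition not in ("seq1_only", "seq2_only", "both"):
        raise ValueError(f"unknown condition {condition!r}")
    all_samples = [s for g in groups for s in g.samples]
    group_labels = [np.array([s.label for s in g.samples]) for g in groups]
    base_auprc = [
        compute_metrics(yl, _group_probs(g, None, condition, seed)).auprc
        for g, yl in zip(groups, group_labels)
    ]
    P = float(np.mean(base_auprc))
    stats = stats or motif_statistics(all_samples, motifs)

    records = []
    for motif in motifs:
        C_m = stats.C_m[motif.name]
        if C_m == 0:
            records.append(ImportanceRecord(
                motif.name, condition, P, None, None, 0.0, None, None, None))
            continue
        deltas = []
        for rep in range(n_replicates):
            for g, yl, p0 in zip(groups, group_labels, base_auprc):
                probs = _group_probs(g, motif, condition, seed + 10007 * rep)
                deltas.append(p0 - compute_metrics(yl, probs).auprc)
        delta = float(np.mean(deltas))
        P_prime = P - delta
        bracket = correction_factor(stats.f_m[motif.name], stats.alpha)
        score = importance_score(delta, C_m, stats.f_m[motif.name], stats.alpha)
        records.append(ImportanceRecord(
            motif.name, condition, P, P_prime, delta, C_m,
            stats.f_m[motif.name], bracket, score))

    ranked = sorted([r for r in records if r.score is not None],
                    key=lambda r: -r.score)
    n_top = max(int(round(0.2 * len(ranked))), 1) if ranked else 0
    for rank, rec in enumerate(ranked, start=1):
        rec.rank = rank
        rec.top20 = rank <= n_top
    return records


def run_erasure_experiment(
    ensemble: EnsembleModel,
    samples: Sequence[BinPairSample],
    motifs: Sequence[MotifModel],
    vocab: BPEVocabulary,
    condition: str = "both",
    seed: int = 0,
    stats: MotifStats | None = None,
    topk: int | None = None,
    baseline_X: np.ndarray | None = None,
    n_replicates: int = 1,
) -> list[ImportanceRecord]:
    """Erase each motif in turn, re-predict, and score the AUPRC drop.

    The same trained ensemble scores the original samples (baseline AUPRC P)
    and, per motif, the samples with that motif's matches erased in the
    designated sequence(s) (P'_m). Records are ranked by score descending
    (motifs that never match get a null score and are excluded from ranking);
    the top 20% by score are flagged.
    """
    group = ErasureGroup(ensemble=ensemble, samples=list(samples), vocab=vocab,
                         baseline_X=None if baseline_X is None
                         else baseline_X.copy(),
                         topk=topk)
    return pooled_erasure_experiment([group], motifs, condition=condition,
                                     seed=seed, stats=stats,
                                     n_replicates=n_replicates)


def collateral_effect_count(samples: Sequence[BinPairSample],
                            motif: MotifModel,
                            motifs: Sequence[MotifModel],
                            seed: int = 0) -> int:
    """Number of *other* motifs whose total match count changes when this
    motif's matches are erased (both sequences), re-scanned at the same
    thresholds."""
    before = {m.name: int(c.sum()) for m, c in
              zip(motifs, count_matches(samples, motifs).values())}
    pairs = _erased_samples(samples, motif, "both", seed)
    erased = [
        type(s)(id=s.id, interval1=s.interval1, interval2=s.interval2,
                seq1=e1, seq2=e2, features=s.features, label=s.label,
                chrom=s.chrom)
        for s, (e1, e2) in zip(samples, pairs)
    ]
    after = {name: int(c.sum())
             for name, c in count_matches(erased, motifs).items()}
    return sum(
        1 for m in motifs
        if m.name != motif.name and before[m.name] != after[m.name]
    )


def importance_table(records: Sequence[ImportanceRecord]) -> "pd.DataFrame":
    """Records as a tidy table (motif, condition, C_m, f_m, bracket, delta,
    score, rank), sorted by rank with unranked motifs last."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in records])
    return df.sort_values("rank", na_position="last").reset_index(drop=True)
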