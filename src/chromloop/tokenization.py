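"""Byte-pair-encoding tokenization of DNA and the eight-channel pair encoding.

A BPE vocabulary is learned from raw nucleotide streams by iteratively merging
the most frequent adjacent token pair. Each bin-pair sample is then turned into
eight fixed-length integer channels: for each of its two sequences, both the
forward and the reverse orientation are segmented, and the token occurrences
are filtered to the top-k by corpus frequency and, separately, by token length
(order preserved), giving four standardized subsequences per sequence.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import BinPairSample, reverse_complement

PAD_TOKEN = "<pad>"
PAD_ID = 0
BASE_SYMBOLS = ("A", "C", "G", "T", "N")


class EncodingError(ValueError):
    """Raised when a sequence contains a symbol absent from the vocabulary."""


@dataclass
class BPEVocabulary:
    """An ordered token table with the merge rules that produced it.

    ``tokens[i]`` is the token with integer id ``i``; id 0 is reserved for
    padding and the five base symbols are always present. ``merges`` lists the
    learned (left, right) pairs in training order; ``frequencies`` holds each
    token's count in the rewritten training corpus at the end of training.
    """

    tokens: list[str]
    merges: list[tuple[str, str]]
    frequencies: dict[str, int]
    target_size: int

    def __post_init__(self) -> None:
        if self.tokens[PAD_ID] != PAD_TOKEN:
            raise ValueError("token id 0 must be the padding token")
        missing = set(BASE_SYMBOLS) - set(self.tokens)
        if missing:
            raise ValueError(f"base symbols missing from vocabulary: {missing}")
        if len(self.tokens) > self.target_size:
            raise ValueError("vocabulary exceeds its target size")
        for left, right in self.merges:
            if left + right not in self.token_to_id:
                raise ValueError(f"merge product {left + right!r} not in token table")

    @cached_property
    def token_to_id(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.tokens)}

    @cached_property
    def _merge_ranks(self) -> dict[tuple[int, int], tuple[int, int]]:
        """(left id, right id) -> (rank, merged id), for the encoder."""
        t2i = self.token_to_id
        return {
            (t2i[l], t2i[r]): (rank, t2i[l + r])
            for rank, (l, r) in enumerate(self.merges)
        }

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TokenizedPair:
    """Eight fixed-length integer-id channels for one bin-pair sample.

    Channel order: seq1-fwd-freq, seq1-fwd-len, seq1-rev-freq, seq1-rev-len,
    then the same four for seq2. Padding (id 0) only as a trailing suffix.
    """

    channels: np.ndarray  # (8, max_tokens) int32
    max_tokens: int

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int32)
        if self.channels.shape != (8, self.max_tokens):
            raise ValueError(
                f"channels must have shape (8, {self.max_tokens}), "
                f"got {self.channels.shape}"
            )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _PairIndex:
    """Adjacent-pair counts with positions, bucketed by count for O(1) max.

    Positions are (sequence index, element index) in corpus order, so the
    minimum position of a pair is its first occurrence in the rewritten
    corpus — the tie-break the trainer needs.
    """

    def __init__(self) -> None:
        self.counts: dict[tuple[int, int], int] = {}
        self.positions: dict[tuple[int, int], set[tuple[int, int]]] = {}
        self.buckets: dict[int, set[tuple[int, int]]] = {}
        self.max_count = 0

    def _move(self, pair: tuple[int, int], old: int, new: int) -> None:
        if old > 0:
            bucket = self.buckets[old]
            bucket.discard(pair)
            if not bucket:
                del self.buckets[old]
        if new > 0:
            self.buckets.setdefault(new, set()).add(pair)
            if new > self.max_count:
                self.max_count = new

    def add(self, pair: tuple[int, int], pos: tuple[int, int]) -> None:
        old = self.counts.get(pair, 0)
        self.counts[pair] = old + 1
        self.positions.setdefault(pair, set()).add(pos)
        self._move(pair, old, old + 1)

    def remove(self, pair: tuple[int, int], pos: tuple[int, int]) -> None:
        old = self.counts[pair]
        self.counts[pair] = old - 1
        self.positions[pair].discard(pos)
        self._move(pair, old, old - 1)
        if old == 1:
            del self.counts[pair]
            del self.positions[pair]

    def drop(self, pair: tuple[int, int]) -> None:
        old = self.counts.pop(pair, 0)
        self.positions.pop(pair, None)
        self._move(pair, old, 0)

    def best(self) -> tuple[tuple[int, int], int] | None:
        """Most frequent pair; ties broken by earliest first corpus position."""
        while self.max_count > 0 and self.max_count not in self.buckets:
            self.max_count -= 1
        if self.max_count == 0:
            return None
        candidates = self.buckets[self.max_count]
        if len(candidates) == 1:
            (pair,) = candidates
        else:
            pair = min(candidates, key=lambda p: min(self.positions[p]))
        return pair, self.max_count


def train_bpe(
    corpus: Sequence[str], target_size: int = 4096, min_pair_count: int = 2
) -> BPEVocabulary:
    """Learn a BPE vocabulary from nucleotide strings.

    Starting from the base symbols, each iteration merges the most frequent
    adjacent token pair (ties: the pair whose first occurrence appears earliest
    in the rewritten corpus), records the merge, and rewrites the corpus, until
    ``target_size`` tokens exist or no pair occurs ``min_pair_count`` times.
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("corpus must contain at least one non-empty sequence")
    if target_size < 1 + len(BASE_SYMBOLS):
        raise ValueError("target_size must be at least the alphabet size")

    tokens: list[str] = [PAD_TOKEN, *BASE_SYMBOLS]
    token_to_id = {t: i for i, t in enumerate(tokens)}
    for seq in corpus:
        bad = set(seq) - set(BASE_SYMBOLS)
        if bad:
            raise EncodingError(f"corpus contains non-nucleotide symbols {sorted(bad)}")

    # Doubly linked token list per sequence; dead elements keep their slot.
    ids = [[token_to_id[c] for c in seq] for seq in corpus]
    nxt = [list(range(1, len(s) + 1)) for s in ids]
    prv = [list(range(-1, len(s) - 1)) for s in ids]

    index = _PairIndex()
    for si, s in enumerate(ids):
        for pi in range(len(s) - 1):
            index.add((s[pi], s[pi + 1]), (si, pi))

    merges: list[tuple[str, str]] = []
    while len(tokens) < target_size:
        found = index.best()
        if found is None or found[1] < min_pair_count:
            break
        (a, b), _ = found
        new_id = len(tokens)
        tokens.append(tokens[a] + tokens[b])
        merges.append((tokens[a], tokens[b]))

        for si, pi in sorted(index.positions[(a, b)]):
            s, nx, pv = ids[si], nxt[si], prv[si]
            if s[pi] != a:  # killed by an earlier overlapping merge
                continue
            j = nx[pi]
            if j >= len(s) or s[j] != b:
                continue
            p_prev, p_next = pv[pi], nx[j]
            if p_prev >= 0:
                index.remove((s[p_prev], a), (si, p_prev))
            if p_next < len(s):
                index.remove((b, s[p_next]), (si, j))
            s[pi] = new_id
            s[j] = -1  # dead
            nx[pi] = p_next
            if p_next < len(s):
                pv[p_next] = pi
            if p_prev >= 0:
                index.add((s[p_prev], new_id), (si, p_prev))
            if p_next < len(s):
                index.add((new_id, s[p_next]), (si, pi))
        index.drop((a, b))

    frequencies: dict[str, int] = {t: 0 for t in tokens}
    for s in ids:
        for tid in s:
            if tid >= 0:
                frequencies[tokens[tid]] += 1

    return BPEVocabulary(
        tokens=tokens, merges=merges, frequencies=frequencies, target_size=target_size
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def segment(sequence: str, vocab: BPEVocabulary) -> list[str]:
    """Tokenize a sequence by applying the learned merges in training order.

    Standard BPE inference: repeatedly merge the adjacent pair with the lowest
    merge rank (left-to-right within a rank) until no learned pair remains.
    The concatenation of the output always equals the input.
    """
    if not sequence:
        return []
    t2i = vocab.token_to_id
    try:
        s = [t2i[c] for c in sequence]
    except KeyError as exc:
        raise EncodingError(f"symbol {exc.args[0]!r} not in vocabulary") from exc
    ranks = vocab._merge_ranks
    n = len(s)
    nxt = list(range(1, n + 1))
    prv = list(range(-1, n - 1))
    heap: list[tuple[int, int, int, int]] = []

    def push(pos: int, left: int, right: int) -> None:
        hit = ranks.get((left, right))
        if hit is not None:
            heapq.heappush(heap, (hit[0], pos, left, right))

    for i in range(n - 1):
        push(i, s[i], s[i + 1])

    while heap:
        rank, pi, a, b = heapq.heappop(heap)
        if s[pi] != a:
            continue
        j = nxt[pi]
        if j >= n or s[j] != b:
            continue
        new_id = ranks[(a, b)][1]
        p_prev, p_next = prv[pi], nxt[j]
        s[pi] = new_id
        s[j] = -1
        nxt[pi] = p_next
        if p_next < n:
            prv[p_next] = pi
        if p_prev >= 0:
            push(p_prev, s[p_prev], new_id)
        if p_next < n:
            push(pi, new_id, s[p_next])

    return [vocab.tokens[tid] for tid in s if tid >= 0]


def reverse_orientation(sequence: str, mode: str = "revcomp") -> str:
    """The 'reverse direction' reading of a sequence.

    ``revcomp`` (default) returns the reverse complement — the other strand
    read 5'→3'. ``mirror`` returns the plain string reversal.
    """
    if mode == "revcomp":
        return reverse_complement(sequence)
    if mode == "mirror":
        return sequence[::-1]
    raise ValueError(f"mode must be 'revcomp' or 'mirror', got {mode!r}")


def select_topk(
    tokens: Sequence[str], vocab: BPEVocabulary, criterion: str, k: int
) -> list[str]:
    """Keep the k highest-ranked token occurrences, preserving original order.

    ``criterion='frequency'`` ranks by the vocabulary's corpus frequency,
    ``'length'`` by token string length, both descending. Ties are broken in
    favour of the earlier position, so the result is deterministic. With fewer
    than k occurrences the input is returned unchanged (as a copy).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if criterion == "frequency":
        keys = [vocab.frequencies.get(t, 0) for t in tokens]
    elif criterion == "length":
        keys = [len(t) for t in tokens]
    else:
        raise ValueError(f"criterion must be 'frequency' or 'length', got {criterion!r}")
    if len(tokens) <= k:
        return list(tokens)
    order = sorted(range(len(tokens)), key=lambda i: (-keys[i], i))[:k]
    return [tokens[i] for i in sorted(order)]


def _to_ids(tokens: Sequence[str], vocab: BPEVocabulary, max_tokens: int) -> np.ndarray:
    t2i = vocab.token_to_id
    ids = [t2i[t] for t in tokens[:max_tokens]]
    out = np.full(max_tokens, PAD_ID, dtype=np.int32)
    out[: len(ids)] = ids
    return out


def encode_pair(
    sample: BinPairSample,
    vocab: BPEVocabulary,
    k: int = 500,
    max_tokens: int = 500,
    reverse_mode: str = "revcomp",
) -> TokenizedPair:
    """Encode one sample as eight standardized token-id channels.

    For each sequence and each orientation the segmentation is filtered to the
    top-k occurrences by frequency and by length, mapped to ids, and
    right-padded (or truncated) to ``max_tokens``.
    """
    channels = np.empty((8, max_tokens), dtype=np.int32)
    row = 0
    for seq in (sample.seq1, sample.seq2):
        for oriented in (seq, reverse_orientation(seq, reverse_mode)):
            toks = segment(oriented, vocab)
            for criterion in ("frequency", "length"):
                selected = select_topk(toks, vocab, criterion, k)
                channels[row] = _to_ids(selected, vocab, max_tokens)
                row += 1
    return TokenizedPair(channels=channels, max_tokens=max_tokens)


def encode_batch(
    samples: Iterable[BinPairSample],
    vocab: BPEVocabulary,
    k: int = 500,
    max_tokens: int = 500,
    reverse_mode: str = "revcomp",
) -> np.ndarray:
    """Encode samples into an (N, 8, max_tokens) int32 array."""
    return np.stack(
        [encode_pair(s, vocab, k, max_tokens, reverse_mode).channels for s in samples]
    )


# ---------------------------------------------------------------------------
# Serialization: token table TSV + merges TSV + JSON metadata
# ---------------------------------------------------------------------------


def save_vocabulary(vocab: BPEVocabulary, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.tokens.tsv", "w") as fh:
        fh.write("id\ttoken\tfrequency\n")
        for i, tok in enumerate(vocab.tokens):
            fh.write(f"{i}\t{tok}\t{vocab.frequencies.get(tok, 0)}\n")
    with open(f"{prefix}.merges.tsv", "w") as fh:
        fh.write("left\tright\n")
        for left, right in vocab.merges:
            fh.write(f"{left}\t{right}\n")
    Path(f"{prefix}.meta.json").write_text(
        json.dumps({"target_size": vocab.target_size, "n_tokens": len(vocab.tokens)})
    )


def load_vocabulary(prefix: str | Path) -> BPEVocabulary:
    prefix = Path(prefix)
    tokens, freqs = [], {}
    with open(f"{prefix}.tokens.tsv") as fh:
        next(fh)
        for line in fh:
            _, tok, freq = line.rstrip("\n").split("\t")
            tokens.append(tok)
            freqs[tok] = int(freq)
    merges = []
    with open(f"{prefix}.merges.tsv") as fh:
        next(fh)
        for line in fh:
            left, right = line.rstrip("\n").split("\t")
            merges.append((left, right))
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    return BPEVocabulary(
        tokens=tokens, merges=merges, frequencies=freqs, target_size=meta["target_size"]
    )
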