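"""Desk-scale synthetic bin-pair datasets with planted, label-driving motifs.

The generator emulates the statistical structure the pipeline assumes, without
any download: paired bins on named chromosomes, a 1:10 positive:negative
ratio, genomic feature vectors, and two causal consensus motifs — one planted
in the first bin sequence, the other in the second — whose presence drives the
interaction label. Decoy motifs are planted independently of the label.
Backgrounds are i.i.d. uniform over A/C/G/T (an optional GC skew is exposed);
a ground-truth manifest records every planted offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    BinPairSample,
    Dataset,
    GenomicInterval,
    MotifModel,
    save_dataset,
    write_hocomoco,
)

_DEFAULT_DECOYS = 18


@dataclass
class SyntheticConfig:
    n_positive: int = 200
    neg_ratio: int = 10
    seq_len: int = 2000
    n_chromosomes: int = 20
    causal_motifs: tuple[str, ...] = ("TGACTCA", "CCAATCA")
    decoy_motifs: tuple[str, ...] | None = None  # None -> 18 random consensi
    plant_prob_pos: float = 0.9
    plant_prob_neg: float = 0.1
    decoy_plant_prob: float = 0.3
    n_informative_features: int = 8
    n_noise_features: int = 24
    feature_noise_sd: float = 0.5
    label_flip_prob: float = 0.02
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.plant_prob_pos, self.plant_prob_neg,
                  self.decoy_plant_prob, self.label_flip_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        for cons in self.causal_motifs:
            if set(cons) - set("ACGT"):
                raise ValueError(f"consensus {cons!r} not over ACGT")
            if len(cons) > self.seq_len:
                raise ValueError("consensus longer than seq_len")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _plant(seq: str, consensus: str, rng: np.random.Generator) -> tuple[str, int]:
    offset = int(rng.integers(0, len(seq) - len(consensus) + 1))
    return seq[:offset] + consensus + seq[offset + len(consensus):], offset


def random_consensi(n: int, length: int = 7,
                    rng: np.random.Generator | None = None) -> tuple[str, ...]:
    rng = rng or np.random.default_rng(0)
    return tuple(
        "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        for _ in range(n)
    )


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a labelled bin-pair dataset plus its ground-truth manifest.

    Positives carry causal motif 1 in seq1 and causal motif 2 in seq2 with
    probability ``plant_prob_pos`` each (negatives: ``plant_prob_neg``);
    decoys are planted label-independently in both sequences. Label noise
    flips the causal signal of a sample with probability ``label_flip_prob``
    while keeping its recorded label, so the class ratio is exactly
    ``neg_ratio``. Informative features equal the signal label plus Gaussian
    noise; noise features are standard Gaussian. Chromosomes are assigned
    round-robin within each class so every chromosome carries both classes
    at the global ratio.
    """
    rng = np.random.default_rng(config.seed)
    decoys = (config.decoy_motifs if config.decoy_motifs is not None
              else random_consensi(_DEFAULT_DECOYS, rng=rng))
    motif1, motif2 = config.causal_motifs[0], config.causal_motifs[-1]
    n_neg = config.n_positive * config.neg_ratio
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    samples: list[BinPairSample] = []
    manifest: dict = {
        "config": {**asdict(config), "decoy_motifs": list(decoys)},
        "samples": {},
    }
    cursors = {c: 0 for c in chroms}
    gap = 1000

    order = [1] * config.n_positive + [0] * n_neg
    pos_seen = neg_seen = 0
    for label in order:
        if label == 1:
            chrom = chroms[pos_seen % len(chroms)]
            sid = f"pos{pos_seen}"
            pos_seen += 1
        else:
            chrom = chroms[neg_seen % len(chroms)]
            sid = f"neg{neg_seen}"
            neg_seen += 1

        # label noise flips the *causal signal*, not the recorded label, so
        # the positive:negative ratio stays exactly neg_ratio
        signal_label = label
        if rng.random() < config.label_flip_prob:
            signal_label = 1 - label
        p_plant = (config.plant_prob_pos if signal_label == 1
                   else config.plant_prob_neg)

        seq1 = _random_seq(rng, config.seq_len, config.gc_content)
        seq2 = _random_seq(rng, config.seq_len, config.gc_content)
        planted: dict[str, list] = {}
        # decoys first so a causal plant is never clobbered by a decoy
        for dec in decoys:
            for si in (1, 2):
                if rng.random() < config.decoy_plant_prob:
                    if si == 1:
                        seq1, off = _plant(seq1, dec, rng)
                    else:
                        seq2, off = _plant(seq2, dec, rng)
                    planted.setdefault(dec, []).append([si, off])
        if rng.random() < p_plant:
            seq1, off = _plant(seq1, motif1, rng)
            planted.setdefault(motif1, []).append([1, off])
        if rng.random() < p_plant:
            seq2, off = _plant(seq2, motif2, rng)
            planted.setdefault(motif2, []).append([2, off])

        informative = signal_label + rng.normal(
            0.0, config.feature_noise_sd, size=config.n_informative_features
        )
        noise = rng.normal(0.0, 1.0, size=config.n_noise_features)
        start = cursors[chrom]
        iv1 = GenomicInterval(chrom, start, start + config.seq_len)
        iv2 = GenomicInterval(chrom, iv1.end + gap, iv1.end + gap + config.seq_len)
        cursors[chrom] = iv2.end + gap

        samples.append(BinPairSample(
            id=sid, interval1=iv1, interval2=iv2, seq1=seq1, seq2=seq2,
            features=np.concatenate([informative, noise]),
            label=label, chrom=chrom,
        ))
        manifest["samples"][sid] = {
            "signal_label": signal_label, "label": label, "chrom": chrom,
            "planted": planted,
        }

    feature_names = (
        [f"informative_{i}" for i in range(config.n_informative_features)]
        + [f"noise_{i}" for i in range(config.n_noise_features)]
    )
    dataset = Dataset(samples=samples, feature_names=feature_names,
                      cell_line="synthetic")
    return dataset, manifest


def make_pwms_from_consensi(
    consensi: Sequence[str],
    match_weight: float = 2.0,
    mismatch_weight: float = -1.0,
    max_mismatches: int = 1,
    names: Sequence[str] | None = None,
) -> list[MotifModel]:
    """One PWM per consensus: ``match_weight`` on the consensus base,
    ``mismatch_weight`` elsewhere; threshold set so windows with up to
    ``max_mismatches`` mismatches pass (2L - 3 for one mismatch at defaults).
    """
    if not consensi:
        raise ValueError("need at least one consensus")
    if match_weight <= mismatch_weight:
        raise ValueError("match weight must exceed mismatch weight")
    out = []
    for ci, cons in enumerate(consensi):
        if not cons or set(cons) - set("ACGT"):
            raise ValueError(f"invalid consensus {cons!r}")
        L = len(cons)
        pwm = np.full((L, 4), mismatch_weight, dtype=float)
        for i, ch in enumerate(cons):
            pwm[i, "ACGT".index(ch)] = match_weight
        threshold = L * match_weight - max_mismatches * (match_weight - mismatch_weight)
        name = names[ci] if names else f"motif_{cons}"
        out.append(MotifModel(name=name, pwm=pwm, threshold=float(threshold)))
    return out


def dataset_motifs(config: SyntheticConfig, manifest: dict,
                   max_mismatches: int = 0) -> list[MotifModel]:
    """The causal + decoy PWMs of a generated dataset.

    Thresholds default to exact-match: a 7-mer admits ~0.24 chance matches
    per 4 kb sample, so match counts reflect plantings rather than background
    hits (one allowed mismatch would add ~5 chance matches per sample and
    swamp the planted signal in erasure experiments).
    """
    decoys = manifest["config"]["decoy_motifs"]
    consensi = list(config.causal_motifs) + list(decoys)
    names = ([f"causal_{i}_{c}" for i, c in enumerate(config.causal_motifs)]
             + [f"decoy_{i}_{c}" for i, c in enumerate(decoys)])
    return make_pwms_from_consensi(consensi, names=names,
                                   max_mismatches=max_mismatches)


def leakage_fixture(
    config: SyntheticConfig,
    chrom_signal: bool = True,
    signal_strength: float = 2.0,
    chrom_code_dim: int = 6,
) -> tuple[Dataset, dict]:
    """A dataset whose feature signal is chromosome-conditional.

    Each chromosome gets a fixed random code vector (always appended to the
    features) and a hidden sign s_c; with ``chrom_signal`` the informative
    direction is s_c * (2y - 1), so a model can exploit it only by learning a
    per-chromosome rule — which inflates plain K-fold CV (chromosomes shared
    between train and test) relative to chromosome-grouped CV. With
    ``chrom_signal=False`` the signed signal is replaced by pure noise and the
    two protocols should agree within noise.
    """
    base_cfg = SyntheticConfig(**{
        **asdict(config),
        "n_informative_features": 0,  # no chromosome-agnostic label signal
    })
    dataset, manifest = generate_dataset(base_cfg)
    rng = np.random.default_rng(config.seed + 7919)
    chroms = sorted({s.chrom for s in dataset.samples})
    codes = {c: rng.normal(0.0, 1.0, size=chrom_code_dim) for c in chroms}
    signs = {c: rng.choice([-1.0, 1.0]) for c in chroms}

    n_signal = max(config.n_informative_features, 4)
    new_samples = []
    for s in dataset.samples:
        y = manifest["samples"][s.id]["signal_label"]
        if chrom_signal:
            signal = signs[s.chrom] * (2 * y - 1) * signal_strength + rng.normal(
                0.0, 1.0, size=n_signal)
        else:
            signal = rng.normal(0.0, 1.0, size=n_signal)
        feats = np.concatenate([codes[s.chrom], signal, s.features])
        new_samples.append(BinPairSample(
            id=s.id, interval1=s.interval1, interval2=s.interval2,
            seq1=s.seq1, seq2=s.seq2, features=feats, label=s.label,
            chrom=s.chrom,
        ))
    names = ([f"chrom_code_{i}" for i in range(chrom_code_dim)]
             + [f"signal_{i}" for i in range(n_signal)]
             + dataset.feature_names)
    manifest["leakage"] = {"chrom_signal": chrom_signal,
                           "signs": {c: float(v) for c, v in signs.items()}}
    return Dataset(samples=new_samples, feature_names=names,
                   cell_line="synthetic-leakage"), manifest


def save_synthetic(config: SyntheticConfig, out_dir: str | Path) -> None:
    """Emit the dataset, PWM file, and manifest as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, manifest = generate_dataset(config)
    save_dataset(dataset, out)
    write_hocomoco(out / "motifs.txt", dataset_motifs(config, manifest))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
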