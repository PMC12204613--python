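import numpy as np
import pytest

from chromloop import (
    BinPairSample,
    Dataset,
    GenomicInterval,
    SyntheticConfig,
    generate_dataset,
    train_bpe,
)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table2_vocab():
    """Vocabulary trained two iterations on the worked-example corpus."""
    return train_bpe(["AACGCACTATATA"], target_size=8)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for fast pipeline-level tests."""
    cfg = SyntheticConfig(n_positive=20, neg_ratio=5, seq_len=120,
                          n_chromosomes=10, seed=7)
    ds, manifest = generate_dataset(cfg)
    return cfg, ds, manifest


def make_sample(sid="s0", chrom="chr1", seq1="ACGT" * 10, seq2="TTGG" * 10,
                label=1, features=(0.0, 1.0)):
    return BinPairSample(
        id=sid,
        interval1=GenomicInterval(chrom, 0, len(seq1)),
        interval2=GenomicInterval(chrom, 2 * len(seq1), 2 * len(seq1) + len(seq2)),
        seq1=seq1, seq2=seq2,
        features=np.asarray(features, dtype=float),
        label=label, chrom=chrom,
    )


@pytest.fixture
def toy_dataset():
    """12 samples on 4 chromosomes, 4 positives / 8 negatives."""
    rng = np.random.default_rng(0)
    samples = []
    for i in range(12):
        chrom = f"chr{i % 4 + 1}"
        label = 1 if i < 4 else 0
        samples.append(make_sample(
            sid=f"s{i}", chrom=chrom, label=label,
            seq1=random_dna(rng, 40), seq2=random_dna(rng, 40),
            features=rng.normal(size=3),
        ))
    return Dataset(samples=samples, feature_names=["f0", "f1", "f2"])
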