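"""Readers/writers for the formats the pipeline touches, and the core dataset types.

Coordinates are 0-based half-open (BED convention) throughout. Sequences are
uppercase strings over {A, C, G, T, N}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


class CoordinateError(ValueError):
    """Raised for invalid genomic coordinates (start >= end, out of range)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chromosome name must be non-empty")
        if self.end <= self.start:
            raise CoordinateError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BinPairSample:
    """Two chromatin bins, their sequences, genomic features, and a label.

    ``chrom`` is the chromosome shared by both bins; the chromosome-grouped
    splitter relies on it.
    """

    id: str
    interval1: GenomicInterval
    interval2: GenomicInterval
    seq1: str
    seq2: str
    features: np.ndarray
    label: int
    chrom: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"sample {self.id}: non-finite feature values")
        for seq, iv, which in (
            (self.seq1, self.interval1, "seq1"),
            (self.seq2, self.interval2, "seq2"),
        ):
            if seq and len(seq) != len(iv):
                raise ValueError(
                    f"sample {self.id}: {which} length {len(seq)} != interval "
                    f"length {len(iv)}"
                )


@dataclass
class Dataset:
    """An ordered collection of bin-pair samples with aligned feature names."""

    samples: list[BinPairSample]
    feature_names: list[str]
    cell_line: str = "synthetic"

    def __post_init__(self) -> None:
        n_feat = len(self.feature_names)
        for s in self.samples:
            if s.features.shape != (n_feat,):
                raise ValueError(
                    f"sample {s.id}: feature vector length {s.features.shape} "
                    f"!= {n_feat} feature names"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def chromosomes(self) -> list[str]:
        return sorted({s.chrom for s in self.samples})

    def positives(self) -> list[BinPairSample]:
        return [s for s in self.samples if s.label == 1]

    def negatives(self) -> list[BinPairSample]:
        return [s for s in self.samples if s.label == 0]

    def class_ratio(self) -> float:
        """Negative:positive ratio (the paper's datasets keep this at 10)."""
        n_pos = len(self.positives())
        if n_pos == 0:
            raise ValueError("dataset has no positive samples")
        return len(self.negatives()) / n_pos

    def subset(self, indices: Iterable[int], cell_line: str | None = None) -> "Dataset":
        return Dataset(
            samples=[self.samples[i] for i in indices],
            feature_names=list(self.feature_names),
            cell_line=cell_line or self.cell_line,
        )

    def feature_matrix(self) -> np.ndarray:
        return np.stack([s.features for s in self.samples])


@dataclass
class MotifModel:
    """A position weight matrix with an optional match-score threshold.

    ``pwm`` has one row per motif position and four columns in A, C, G, T
    order. ``threshold`` is the minimal window score declared a match;
    ``pvalue`` records the tail probability that threshold encodes.
    """

    name: str
    pwm: np.ndarray
    threshold: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError(
                f"motif {self.name}: PWM must have 4 columns, got {self.pwm.shape}"
            )
        if self.pwm.shape[0] < 1:
            raise ValueError(f"motif {self.name}: PWM must have >= 1 row")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError(f"motif {self.name}: threshold must be finite")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _clean_sequence(seq: str, on_invalid: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if not bad:
        return seq
    if on_invalid == "error":
        raise FormatError(f"invalid sequence characters: {sorted(bad)}")
    if on_invalid == "mask":
        return "".join(c if c in VALID_BASES else "N" for c in seq)
    raise ValueError(f"on_invalid must be 'error' or 'mask', got {on_invalid!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, on_invalid: str = "error") -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping.

    Characters outside {A, C, G, T, N} either raise (``on_invalid='error'``)
    or are mapped to N (``'mask'``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTA")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = _clean_sequence(str(rec.seq), on_invalid)
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_sequences(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """Extract ``[start, end)`` from the chromosome, reverse-complemented on '-'.

    Equivalent to ``bedtools getfasta -s`` for a single interval.
    """
    if interval.chrom not in genome:
        raise CoordinateError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise CoordinateError(
            f"interval end {interval.end} beyond chromosome "
            f"{interval.chrom} length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


# ---------------------------------------------------------------------------
# Paired-bin BED-like TSV
# ---------------------------------------------------------------------------
# Dialect: tab-separated, no header, columns
#   chrom1 start1 end1 chrom2 start2 end2 label [id]
# with 0-based half-open coordinates and binary labels.


def read_bed_pairs(
    path: str | Path,
) -> list[tuple[GenomicInterval, GenomicInterval, int, str]]:
    """Parse paired-bin intervals with labels; returns (iv1, iv2, label, id)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2, lab = fields[:7]
            pair_id = fields[7] if len(fields) > 7 else f"pair{lineno}"
            if lab not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            iv1 = GenomicInterval(c1, int(s1), int(e1))
            iv2 = GenomicInterval(c2, int(s2), int(e2))
            out.append((iv1, iv2, int(lab), pair_id))
    return out


def write_bed_pairs(
    path: str | Path,
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval, int, str]],
) -> None:
    with open(path, "w") as fh:
        for iv1, iv2, label, pair_id in pairs:
            fh.write(
                f"{iv1.chrom}\t{iv1.start}\t{iv1.end}\t"
                f"{iv2.chrom}\t{iv2.start}\t{iv2.end}\t{label}\t{pair_id}\n"
            )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | Path, ids: Sequence[str] | None = None, sep: str = "\t"
) -> tuple[list[str], pd.DataFrame]:
    """Read a header-ed numeric feature table indexed by sample id.

    When ``ids`` is given the rows are aligned to that order; any missing or
    extra id is an error, as is any non-numeric or missing cell. No silent
    imputation.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if ids is not None:
        ids = [str(i) for i in ids]
        missing = set(ids) - set(df.index)
        if missing:
            raise ValueError(f"{path}: feature table missing ids {sorted(missing)[:5]}")
        df = df.loc[ids]
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric feature columns {non_numeric}")
    if df.isna().any().any():
        raise ValueError(f"{path}: feature table contains missing values")
    return list(df.columns), df


def write_feature_table(
    path: str | Path, ids: Sequence[str], names: Sequence[str], matrix: np.ndarray,
    sep: str = "\t",
) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(ids), columns=list(names))
    df.index.name = "id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# HOCOMOCO plain-text PCM/PWM
# ---------------------------------------------------------------------------


def read_hocomoco(
    path: str | Path,
    pseudocount: float = 0.01,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    kind: str = "auto",
) -> list[MotifModel]:
    """Parse plain-text motif matrices: '>' header lines, then L rows of 4 numbers.

    Count matrices (PCM) are converted to natural-log odds against the
    background with the given pseudocount:
    ``log(((n_ij + pc) / (N_i + 4 pc)) / bg_j)``. A file whose matrices contain
    any negative entry is treated as already being log-odds (``kind='auto'``);
    force the interpretation with ``kind='pcm'`` or ``kind='pwm'``.
    Thresholds are left unset; fill them with
    :func:`chromloop.motif_analysis.pvalue_threshold`.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.asarray(background, dtype=float)
    blocks: list[tuple[str, list[list[float]]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = []
                blocks.append((line[1:].split()[0], current))
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: matrix row before any '>' header")
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 fields per row, got {len(fields)}"
                )
            current.append([float(x) for x in fields])
    if not blocks:
        raise FormatError(f"{path}: no motifs found")
    motifs = []
    for name, rows in blocks:
        if not rows:
            raise FormatError(f"{path}: motif {name!r} has no rows")
        mat = np.asarray(rows, dtype=float)
        as_counts = {"auto": bool(np.all(mat >= 0)), "pcm": True, "pwm": False}[kind]
        if as_counts:
            totals = mat.sum(axis=1, keepdims=True)
            probs = (mat + pseudocount) / (totals + 4 * pseudocount)
            mat = np.log(probs / bg)
        motifs.append(MotifModel(name=name, pwm=mat))
    return motifs


def write_hocomoco(path: str | Path, motifs: Sequence[MotifModel]) -> None:
    """Write motifs in the same plain-text dialect (values as given)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for row in m.pwm:
                fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Dataset assembly and on-disk layout
# ---------------------------------------------------------------------------


def build_dataset(
    genome: Mapping[str, str],
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval, int, str]],
    feature_names: Sequence[str],
    features: pd.DataFrame,
    cell_line: str = "unknown",
) -> Dataset:
    """Assemble a Dataset from a genome, labelled bin pairs, and features."""
    samples = []
    for iv1, iv2, label, pair_id in pairs:
        if iv1.chrom != iv2.chrom:
            raise ValueError(
                f"pair {pair_id}: bins on different chromosomes "
                f"({iv1.chrom} vs {iv2.chrom}); chromosome-grouped splitting "
                "requires a shared chromosome"
            )
        samples.append(
            BinPairSample(
                id=pair_id,
                interval1=iv1,
                interval2=iv2,
                seq1=extract_sequences(genome, iv1),
                seq2=extract_sequences(genome, iv2),
                features=features.loc[pair_id].to_numpy(dtype=float),
                label=label,
                chrom=iv1.chrom,
            )
        )
    return Dataset(samples=samples, feature_names=list(feature_names), cell_line=cell_line)


def save_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Write a dataset as plain-text files: bin FASTA, paired BED, feature TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = {}
    pairs = []
    for s in dataset.samples:
        seqs[f"{s.id}_1"] = s.seq1
        seqs[f"{s.id}_2"] = s.seq2
        pairs.append((s.interval1, s.interval2, s.label, s.id))
    write_fasta(out / "bins.fa", seqs)
    write_bed_pairs(out / "pairs.bed", pairs)
    write_feature_table(
        out / "features.tsv",
        [s.id for s in dataset.samples],
        dataset.feature_names,
        dataset.feature_matrix(),
    )
    (out / "meta.json").write_text(
        json.dumps({"cell_line": dataset.cell_line, "n_samples": len(dataset)})
    )


def load_dataset(in_dir: str | Path) -> Dataset:
    """Inverse of :func:`save_dataset`."""
    ind = Path(in_dir)
    seqs = read_fasta(ind / "bins.fa")
    pairs = read_bed_pairs(ind / "pairs.bed")
    names, feats = read_feature_table(ind / "features.tsv", ids=[p[3] for p in pairs])
    meta = json.loads((ind / "meta.json").read_text())
    samples = []
    for iv1, iv2, label, pair_id in pairs:
        samples.append(
            BinPairSample(
                id=pair_id,
                interval1=iv1,
                interval2=iv2,
                seq1=seqs[f"{pair_id}_1"],
                seq2=seqs[f"{pair_id}_2"],
                features=feats.loc[pair_id].to_numpy(dtype=float),
                label=label,
                chrom=iv1.chrom,
            )
        )
    return Dataset(samples=samples, feature_names=names, cell_line=meta["cell_line"])
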