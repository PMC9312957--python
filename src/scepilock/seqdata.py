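"""Sequence dataset preparation.

Peaks are standardized to fixed 1,000-bp windows, one-hot encoded as 4 x L
binary matrices with row order A, G, C, T, paired with their reverse
complements (training sees both strands), combined with reference-genome
negative fragments, and split 8:1:1 into train/validation/test.

Base codes used throughout: A=0, G=1, C=2, T=3, N(or any ambiguity)=4.
With this row order the reverse complement of a one-hot matrix is simply the
matrix flipped along both axes (A<->T is row 0<->3, G<->C is row 1<->2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

from . import io as sio
from .intervals import GenomicInterval

BASE_ORDER = "AGCT"
N_CODE = 4

_CODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


# ---------------------------------------------------------------------------
# Genome access


class Genome:
    """Random-access FASTA genome with normalized (uppercase, N-collapsed) bases."""

    def __init__(self, fasta_path: str | os.PathLike):
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self.sizes: dict[str, int] = {name: len(rec) for name, rec in self._fasta.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self.sizes:
            raise KeyError(f"chromosome {chrom!r} not in genome "
                           f"(has {sorted(self.sizes)})")
        return self.sizes[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Fetch [start, end) (0-based half-open), uppercase, ambiguity -> N."""
        size = self.chrom_length(chrom)
        if start < 0 or end > size or start >= end:
            raise ValueError(
                f"fetch {chrom}:{start}-{end} out of bounds for length {size}"
            )
        seq = str(self._fasta[chrom][start:end]).upper()
        if any(b not in "ACGTN" for b in set(seq)):
            seq = "".join(b if b in "ACGTN" else "N" for b in seq)
        return seq

    def fetch_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        seq = self.fetch(chrom, start, end)
        return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def load_genome(fasta_path: str | os.PathLike) -> Genome:
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    return Genome(fasta_path)


# ---------------------------------------------------------------------------
# Encoding


def encode_codes(sequence: str) -> np.ndarray:
    """Map a DNA string to uint8 base codes (A=0,G=1,C=2,T=3, other=4)."""
    return _CODE_LUT[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def one_hot(sequence: str | np.ndarray) -> np.ndarray:
    """One-hot encode a sequence to a 4 x L binary matrix, rows A, G, C, T.

    Ambiguous bases (N) become all-zero columns.
    """
    codes = encode_codes(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    mat = np.zeros((4, codes.size), dtype=np.float32)
    valid = codes < 4
    mat[codes[valid], np.flatnonzero(valid)] = 1.0
    return mat


def decode(matrix: np.ndarray) -> str:
    """Inverse of `one_hot` (all-zero columns decode to N)."""
    matrix = np.asarray(matrix)
    codes = np.where(matrix.sum(axis=0) > 0, matrix.argmax(axis=0), N_CODE)
    return "".join((BASE_ORDER + "N")[c] for c in codes)


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes < 4, 3 - codes, N_CODE).astype(np.uint8)
    return rc[::-1].copy()


def reverse_complement(matrix: np.ndarray) -> np.ndarray:
    """Reverse complement of a one-hot matrix: flip both axes.

    In A,G,C,T row order, complementing swaps rows 0<->3 and 1<->2, which is a
    row reversal; reading the opposite strand reverses the columns.
    """
    return np.ascontiguousarray(np.asarray(matrix)[::-1, ::-1])


@dataclass
class EncodedExample:
    """A standardized window with its label vector and strand pair.

    Stores the forward-strand base codes; the one-hot matrices are derived on
    demand so large datasets stay compact in memory.
    """

    codes: np.ndarray  # uint8, length L, forward strand
    labels: np.ndarray  # int8, length m, in {0, 1}
    source: GenomicInterval

    @property
    def forward(self) -> np.ndarray:
        return one_hot(self.codes)

    @property
    def reverse(self) -> np.ndarray:
        return one_hot(reverse_complement_codes(self.codes))

    def __len__(self) -> int:
        return self.codes.size


# ---------------------------------------------------------------------------
# Peaks and labels


def load_peak_labels(
    bed_paths: Sequence[str | os.PathLike] | None = None,
    cell_types: Sequence[str] | None = None,
    bed_path: str | os.PathLike | None = None,
    label_table: str | os.PathLike | None = None,
) -> tuple[list[GenomicInterval], np.ndarray, list[str]]:
    """Load peaks with multi-hot cell-type labels.

    Two dialects:
      * one BED per cell type (`bed_paths`, optionally `cell_types` names):
        identical intervals across files merge into one row with a multi-hot
        label; overlapping-but-unequal peaks stay separate rows;
      * a single peak BED plus a peak x cell-type 0/1 table (`bed_path` +
        `label_table`), matched on peak name.

    Returns (intervals sorted by coordinate, labels matrix, cell-type names).
    """
    if bed_paths is not None:
        names = list(cell_types) if cell_types is not None else [
            os.path.splitext(os.path.basename(str(p)))[0] for p in bed_paths
        ]
        m = len(bed_paths)
        if m == 0:
            raise ValueError("need at least one cell type")
        rows: dict[tuple[str, int, int], np.ndarray] = {}
        keep_name: dict[tuple[str, int, int], str | None] = {}
        for c, path in enumerate(bed_paths):
            for iv in sio.read_bed(path):
                key = (iv.chrom, iv.start, iv.end)
                if key not in rows:
                    rows[key] = np.zeros(m, dtype=np.int8)
                    keep_name[key] = iv.name
                rows[key][c] = 1
        keys = sorted(rows)
        intervals = [
            GenomicInterval(c, s, e, name=keep_name[(c, s, e)]) for c, s, e in keys
        ]
        labels = np.stack([rows[k] for k in keys]) if keys else np.zeros((0, m), np.int8)
        return intervals, labels, names

    if bed_path is None or label_table is None:
        raise ValueError("provide either per-cell-type bed_paths or bed_path + label_table")
    peaks = sio.read_bed(bed_path)
    peak_ids, labels, names = sio.read_label_table(label_table)
    by_name = {iv.name: iv for iv in peaks}
    missing = [p for p in peak_ids if p not in by_name]
    if missing:
        raise ValueError(f"label table rows missing from BED: {missing[:5]}")
    idx = sorted(range(len(peak_ids)),
                 key=lambda i: (by_name[peak_ids[i]].chrom,
                                by_name[peak_ids[i]].start,
                                by_name[peak_ids[i]].end))
    intervals = [by_name[peak_ids[i]] for i in idx]
    return intervals, labels[idx], names


def standardize_window(
    interval: GenomicInterval, genome: Genome, length: int = 1000
) -> GenomicInterval:
    """Center a fixed-length window on the peak midpoint, clamped to the chromosome.

    The window is centered on floor((start+end)/2); if it would overhang a
    chromosome end it is shifted inward so the full `length` is retained.
    """
    size = genome.chrom_length(interval.chrom)
    if size < length:
        raise ValueError(
            f"chromosome {interval.chrom} (length {size}) shorter than window {length}"
        )
    mid = interval.midpoint()
    start = mid - length // 2
    start = min(max(start, 0), size - length)
    return GenomicInterval(interval.chrom, start, start + length, name=interval.name)


def encode_peaks(
    intervals: Sequence[GenomicInterval],
    labels: np.ndarray,
    genome: Genome,
    length: int = 1000,
) -> list[EncodedExample]:
    """Standardize windows and encode them, keeping the label pairing."""
    labels = np.asarray(labels, dtype=np.int8)
    out = []
    for iv, lab in zip(intervals, labels):
        win = standardize_window(iv, genome, length)
        out.append(EncodedExample(genome.fetch_codes(win.chrom, win.start, win.end), lab, win))
    return out


# ---------------------------------------------------------------------------
# Negative regions


def sample_negatives(
    genome: Genome,
    exclusion: Iterable[GenomicInterval],
    n: int = 10000,
    length: int = 1000,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Sample accessible-nowhere negative fragments from the reference genome.

    Each chromosome is tiled into consecutive non-overlapping `length`-bp
    fragments starting at 0; any tile sharing >= 1 bp with an exclusion
    interval (the peak set) is discarded, and `n` of the survivors are drawn
    uniformly without replacement.
    """
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exclusion:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    eligible: list[GenomicInterval] = []
    for chrom in sorted(genome.sizes):
        size = genome.sizes[chrom]
        n_tiles = size // length
        if n_tiles == 0:
            continue
        keep = np.ones(n_tiles, dtype=bool)
        for s, e in excl_by_chrom.get(chrom, ()):
            # tiles intersecting [s, e): floor(s/length) .. floor((e-1)/length)
            first = max(s // length, 0)
            last = min((e - 1) // length, n_tiles - 1)
            if first <= last:
                keep[first : last + 1] = False
        for t in np.flatnonzero(keep):
            eligible.append(GenomicInterval(chrom, int(t) * length, (int(t) + 1) * length))

    if n > len(eligible):
        raise ValueError(
            f"requested {n} negative fragments but only {len(eligible)} tiles "
            "survive peak exclusion"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in np.sort(idx)]


def encode_negatives(
    negatives: Sequence[GenomicInterval], genome: Genome, n_cell_types: int
) -> list[EncodedExample]:
    """Encode negative fragments with all-zero label vectors."""
    zero = np.zeros(n_cell_types, dtype=np.int8)
    return [
        EncodedExample(genome.fetch_codes(iv.chrom, iv.start, iv.end), zero.copy(), iv)
        for iv in negatives
    ]


# ---------------------------------------------------------------------------
# Splits


@dataclass
class DatasetSplit:
    """Train/validation/test partition of examples by source interval."""

    train: list[EncodedExample]
    validation: list[EncodedExample]
    test: list[EncodedExample]
    split_seed: int = 0

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def split_dataset(
    examples: Sequence[EncodedExample],
    ratio: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly split examples 8:1:1 (by source interval) into train/val/test.

    Splitting happens before strand doubling, so a window's forward sequence
    and its reverse complement can never land in different partitions.
    """
    if len(examples) < 10:
        raise ValueError("need at least 10 examples to split")
    if any(r <= 0 for r in ratio):
        raise ValueError(f"split ratio must be positive, got {ratio}")
    total = sum(ratio)
    n = len(examples)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = round(n * ratio[0] / total)
    n_val = round(n * ratio[1] / total)
    train = [examples[i] for i in order[:n_train]]
    val = [examples[i] for i in order[n_train : n_train + n_val]]
    test = [examples[i] for i in order[n_train + n_val :]]
    return DatasetSplit(train, val, test, split_seed=seed)


def holdout_chromosome(
    examples: Sequence[EncodedExample], chrom: str
) -> tuple[list[EncodedExample], list[EncodedExample]]:
    """Leave-one-chromosome-out partition: (train+val pool, held-out test)."""
    chroms = {ex.source.chrom for ex in examples}
    if chrom not in chroms:
        raise ValueError(f"chromosome {chrom!r} not present (has {sorted(chroms)})")
    test = [ex for ex in examples if ex.source.chrom == chrom]
    pool = [ex for ex in examples if ex.source.chrom != chrom]
    return pool, test


# ---------------------------------------------------------------------------
# Prepared-dataset persistence (one .npz + sidecar metadata per split)


def save_prepared(path: str | os.PathLike, split: DatasetSplit, cell_types: Sequence[str]) -> None:
    os.makedirs(path, exist_ok=True)
    payload: dict[str, np.ndarray] = {"cell_types": np.array(list(cell_types))}
    for part in ("train", "validation", "test"):
        exs: list[EncodedExample] = getattr(split, part)
        payload[f"{part}_codes"] = (
            np.stack([e.codes for e in exs]) if exs else np.zeros((0, 0), np.uint8)
        )
        payload[f"{part}_labels"] = (
            np.stack([e.labels for e in exs]) if exs else np.zeros((0, len(cell_types)), np.int8)
        )
        payload[f"{part}_chrom"] = np.array([e.source.chrom for e in exs])
        payload[f"{part}_start"] = np.array([e.source.start for e in exs], dtype=np.int64)
        payload[f"{part}_end"] = np.array([e.source.end for e in exs], dtype=np.int64)
    payload["split_seed"] = np.array(split.split_seed)
    np.savez_compressed(os.path.join(path, "dataset.npz"), **payload)


def load_prepared(path: str | os.PathLike) -> tuple[DatasetSplit, list[str]]:
    with np.load(os.path.join(path, "dataset.npz"), allow_pickle=False) as z:
        cell_types = [str(c) for c in z["cell_types"]]
        parts = {}
        for part in ("train", "validation", "test"):
            codes, labels = z[f"{part}_codes"], z[f"{part}_labels"]
            chrom, start, end = z[f"{part}_chrom"], z[f"{part}_start"], z[f"{part}_end"]
            parts[part] = [
                EncodedExample(
                    codes[i],
                    labels[i],
                    GenomicInterval(str(chrom[i]), int(start[i]), int(end[i])),
                )
                for i in range(codes.shape[0])
            ]
        split = DatasetSplit(parts["train"], parts["validation"], parts["test"],
                             split_seed=int(z["split_seed"]))
    return split, cell_types
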