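"""Readers and writers for the plain-text genomics formats the pipeline touches.

All coordinates on disk follow the native convention of each format: BED and
bedGraph are 0-based half-open, variant TSV/VCF positions are 1-based.
In memory everything is 0-based half-open (see `intervals`).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


# ---------------------------------------------------------------------------
# FASTA / chrom sizes


def write_fasta(path: str | os.PathLike, records: Mapping[str, str], width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at `width` columns."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")


def write_chrom_sizes(path: str | os.PathLike, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split("\t")[:2]
            sizes[name] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3+ intervals; raises with the line number on malformed input."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
            except ValueError as exc:
                raise ValueError(f"{path}: invalid interval at line {lineno}: {exc}") from exc
    return out


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6 (name/score/strand filled with deterministic defaults)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = iv.name if iv.name is not None else f"region_{i}"
            score = 0.0 if scores is None else scores[i]
            strand = iv.strand if iv.strand is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# Peak x cell-type label table


def write_label_table(
    path: str | os.PathLike,
    peak_ids: Sequence[str],
    labels: np.ndarray,
    cell_types: Sequence[str],
) -> None:
    df = pd.DataFrame(np.asarray(labels, dtype=int), columns=list(cell_types))
    df.insert(0, "peak_id", list(peak_ids))
    df.to_csv(path, sep="\t", index=False)


def read_label_table(path: str | os.PathLike) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    peak_ids = df.iloc[:, 0].astype(str).tolist()
    cell_types = list(df.columns[1:])
    labels = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{path}: label table entries must be 0/1")
    return peak_ids, labels, cell_types


# ---------------------------------------------------------------------------
# Variants (4-column TSV with optional truth column, and minimal VCF)


def read_variant_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a variant TSV: chrom, pos (1-based), ref, alt[, extra columns]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant TSV missing columns {sorted(missing)}")
    return df


def write_variant_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read SNV records from an uncompressed VCF.

    Only CHROM/POS/ID/REF/ALT are consumed; multi-allelic records are split;
    non-SNV alleles are dropped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: malformed VCF line: {line!r}")
            chrom, pos, vid, ref, alts = fields[:5]
            for alt in alts.split(","):
                if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
                    rows.append(
                        {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                         "id": None if vid == "." else vid}
                    )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])


# ---------------------------------------------------------------------------
# bedGraph / fixed-step WIG score tracks


def write_bedgraph(
    path: str | os.PathLike, per_chrom_scores: Mapping[str, np.ndarray]
) -> None:
    """Write per-base scores as bedGraph, run-length merging equal adjacent values."""
    with open(path, "w") as fh:
        for chrom, scores in per_chrom_scores.items():
            scores = np.asarray(scores)
            if scores.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(scores[1:] != scores[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [scores.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{scores[s]:g}\n")


def read_score_track(
    path: str | os.PathLike, chrom_sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a bedGraph or fixed-step WIG track into dense per-base arrays.

    Bases not covered by the track read as 0.
    """
    arrays = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("fixedStep") or "fixedStep" in first:
            _read_fixedstep(fh, arrays)
        else:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                if chrom in arrays:
                    arrays[chrom][int(start) : int(end)] = float(value)
    return arrays


def _read_fixedstep(fh, arrays: dict[str, np.ndarray]) -> None:
    chrom, pos, step, span = None, 0, 1, 1
    for line in fh:
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        if line.startswith("fixedStep"):
            params = dict(kv.split("=") for kv in line.split()[1:])
            chrom = params["chrom"]
            pos = int(params["start"]) - 1  # WIG is 1-based
            step = int(params.get("step", 1))
            span = int(params.get("span", 1))
            continue
        if chrom in arrays:
            arrays[chrom][pos : pos + span] = float(line)
        pos += step
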