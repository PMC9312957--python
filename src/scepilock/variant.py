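"""Variant impact quantification.

For each single-nucleotide variant, the wild-type and mutant alleles of its
host 1,000-bp window are scored by the trained classifier (strand-max
probabilities), and the per-cell-type delta score is the absolute difference
|p_WT - p_mut|. A large delta marks a variant whose substitution alone flips
the predicted accessibility of the surrounding peak for that cell type.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import GenomicInterval
from .model import ClassifierModel, predict
from .seqdata import BASE_ORDER, EncodedExample, Genome, standardize_window

logger = logging.getLogger(__name__)

_BASE_TO_CODE = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant; `pos` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT" or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only SNVs with ref/alt in A,C,G,T are supported, got "
                f"{self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass
class DeltaRecord:
    variant: VariantRecord
    host_peak: GenomicInterval
    p_wt: np.ndarray
    p_mut: np.ndarray
    delta: np.ndarray

    @property
    def max_delta(self) -> float:
        return float(self.delta.max())

    @property
    def argmax_cell_type(self) -> int:
        return int(self.delta.argmax())


# ---------------------------------------------------------------------------
# Ingest


def load_variants(path: str | os.PathLike, genome: Genome | None = None) -> list[VariantRecord]:
    """Read variants from a 4-column TSV or a VCF; verify ref against the genome."""
    text = str(path)
    df = sio.read_vcf(path) if text.endswith(".vcf") else sio.read_variant_tsv(path)
    records = []
    for row in df.itertuples(index=False):
        rec = VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            id=str(row.id) if "id" in df.columns and row.id is not None else None,
        )
        if genome is not None:
            found = genome.fetch(rec.chrom, rec.pos0, rec.pos0 + 1)
            if found != rec.ref:
                raise ValueError(
                    f"variant {rec.chrom}:{rec.pos} claims ref {rec.ref} but the "
                    f"genome carries {found}"
                )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Window location and allele pairs


def locate_host_window(
    variant: VariantRecord,
    peaks: Sequence[GenomicInterval],
    genome: Genome,
    length: int = 1000,
    window_on_variant: bool = False,
) -> GenomicInterval | None:
    """Standardized window of the peak hosting the variant.

    When several standardized peak windows contain the variant, the peak
    whose midpoint is nearest wins (ties to the leftmost). Without a host
    peak the variant is skipped (None) unless `window_on_variant`, which
    centers a window on the variant itself, clamped at chromosome ends.
    """
    hosts = []
    for peak in peaks:
        if peak.chrom != variant.chrom:
            continue
        win = standardize_window(peak, genome, length)
        if win.contains_point(variant.chrom, variant.pos0):
            hosts.append((abs(peak.midpoint() - variant.pos0), peak.start, win))
    if hosts:
        hosts.sort(key=lambda h: (h[0], h[1]))
        return hosts[0][2]
    if window_on_variant:
        size = genome.chrom_length(variant.chrom)
        start = min(max(variant.pos0 - length // 2, 0), size - length)
        return GenomicInterval(variant.chrom, start, start + length)
    logger.info("variant %s:%s lies in no peak window; skipped", variant.chrom, variant.pos)
    return None


def build_allele_pair(
    window: GenomicInterval, genome: Genome, variant: VariantRecord,
    n_cell_types: int = 0,
) -> tuple[EncodedExample, EncodedExample]:
    """Wild-type and mutant encoded windows differing only at the variant base."""
    wt_codes = genome.fetch_codes(window.chrom, window.start, window.end)
    offset = variant.pos0 - window.start
    if not 0 <= offset < len(window):
        raise ValueError(f"variant {variant.chrom}:{variant.pos} outside window {window}")
    found_code = int(wt_codes[offset])
    expected = _BASE_TO_CODE[variant.ref]
    if found_code != expected:
        found = (BASE_ORDER + "N")[found_code]
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: variant says "
            f"{variant.ref}, genome carries {found}"
        )
    mut_codes = wt_codes.copy()
    mut_codes[offset] = _BASE_TO_CODE[variant.alt]
    zeros = np.zeros(n_cell_types, dtype=np.int8)
    return (
        EncodedExample(wt_codes, zeros.copy(), window),
        EncodedExample(mut_codes, zeros.copy(), window),
    )


# ---------------------------------------------------------------------------
# Delta scores


def delta_score(
    model: ClassifierModel,
    wt: EncodedExample,
    mut: EncodedExample,
    variant: VariantRecord,
) -> DeltaRecord:
    """Per-cell-type |p_WT - p_mut| with strand-max probabilities."""
    probs = predict(model, [wt, mut])
    p_wt, p_mut = probs[0], probs[1]
    return DeltaRecord(
        variant=variant, host_peak=wt.source, p_wt=p_wt, p_mut=p_mut,
        delta=np.abs(p_wt - p_mut),
    )


class _HostIndex:
    """Per-chromosome sorted index of standardized peak windows.

    Same nearest-midpoint / leftmost tie rule as `locate_host_window`, but
    answers point queries in O(log n_peaks).
    """

    def __init__(self, peaks: Sequence[GenomicInterval], genome: Genome, length: int):
        self.length = length
        self._by_chrom: dict[str, tuple[np.ndarray, list]] = {}
        buckets: dict[str, list] = {}
        for peak in peaks:
            win = standardize_window(peak, genome, length)
            buckets.setdefault(peak.chrom, []).append((win.start, peak.start,
                                                       peak.midpoint(), win))
        for chrom, rows in buckets.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            self._by_chrom[chrom] = (starts, rows)

    def find(self, variant: VariantRecord) -> GenomicInterval | None:
        entry = self._by_chrom.get(variant.chrom)
        if entry is None:
            return None
        starts, rows = entry
        pos = variant.pos0
        lo = int(np.searchsorted(starts, pos - self.length + 1, side="left"))
        hi = int(np.searchsorted(starts, pos, side="right"))
        hosts = [
            (abs(mid - pos), peak_start, win)
            for _ws, peak_start, mid, win in rows[lo:hi]
            if win.contains_point(variant.chrom, pos)
        ]
        if not hosts:
            return None
        hosts.sort(key=lambda h: (h[0], h[1]))
        return hosts[0][2]


def score_variants(
    model: ClassifierModel,
    variants: Sequence[VariantRecord],
    peaks: Sequence[GenomicInterval],
    genome: Genome,
    window_on_variant: bool = False,
) -> list[DeltaRecord]:
    records = []
    length = model.config.input_length
    index = _HostIndex(peaks, genome, length)
    for variant in variants:
        window = index.find(variant)
        if window is None:
            if not window_on_variant:
                logger.info("variant %s:%s lies in no peak window; skipped",
                            variant.chrom, variant.pos)
                continue
            window = locate_host_window(variant, [], genome, length, True)
        wt, mut = build_allele_pair(window, genome, variant, model.config.n_cell_types)
        records.append(delta_score(model, wt, mut, variant))
    return records


def rank_variants(
    records: Sequence[DeltaRecord], cell_type_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Table of variants sorted by max delta score, descending.

    Ties are broken by (chrom, pos); the sort is stable.
    """
    if not records:
        raise ValueError("no delta records to rank")
    m = records[0].p_wt.shape[0]
    names = list(cell_type_names) if cell_type_names is not None else [
        f"ct{c}" for c in range(m)
    ]
    rows = []
    for rec in records:
        row = {
            "id": rec.variant.id or "",
            "chrom": rec.variant.chrom,
            "pos": rec.variant.pos,
            "ref": rec.variant.ref,
            "alt": rec.variant.alt,
        }
        for c, name in enumerate(names):
            row[f"p_wt_{name}"] = rec.p_wt[c]
            row[f"p_mut_{name}"] = rec.p_mut[c]
            row[f"delta_{name}"] = rec.delta[c]
        row["max_delta"] = rec.max_delta
        row["argmax_cell_type"] = names[rec.argmax_cell_type]
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["max_delta", "chrom", "pos"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return df
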