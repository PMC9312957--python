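"""Self-contained synthetic benchmark data.

Builds a toy multi-chromosome genome in which cell-type-specific transcription
factor motifs (high-information PWMs, default width 10 bp — the eukaryotic
mean TF site is ~10 bp) are planted inside non-overlapping fixed-length peaks.
Peak labels are multi-hot over cell types and derive exactly from which
motifs a peak carries, so classifier accuracy, saliency localization, and
variant delta scores can all be checked against known ground truth.

What this emulates: the label structure of per-cell-type scATAC-seq peak
calls, shared (multi-cell-type) peaks, reference-genome negatives, a
conservation-like per-base score track elevated over functional bases, and
motif-disrupting vs. neutral single-nucleotide variants. What it does not
emulate: read-level data, fragment files, peak-calling noise, or realistic
genomic sequence composition beyond a global GC fraction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import GenomicInterval
from .seqdata import BASE_ORDER

_ALPHABETICAL_ROWS = np.array([0, 2, 1, 3])  # rows A,G,C,T visited in A<C<G<T order
_CODE_TO_BYTE = np.frombuffer("AGCT".encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class MotifModel:
    """A position weight matrix (rows A, G, C, T) tied to one or more cell types."""

    id: str
    pwm: np.ndarray  # (4, w) column-stochastic
    assigned_cell_types: frozenset[int]

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[0] != 4 or pwm.shape[1] < 1:
            raise ValueError(f"PWM must be 4 x w with w >= 1, got {pwm.shape}")
        if (pwm < 0).any() or (pwm > 1).any():
            raise ValueError("PWM entries must lie in [0, 1]")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1 within 1e-9")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def consensus_codes(self) -> np.ndarray:
        return self.pwm.argmax(axis=0)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (2 + sum p log2 p)."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        return 2.0 + (self.pwm * np.log2(p)).sum(axis=0)

    def sample_codes(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one motif instance (base codes) column-by-column from the PWM."""
        u = rng.random(self.width)
        cdf = np.cumsum(self.pwm, axis=0)
        return (u[None, :] > cdf).sum(axis=0).astype(np.uint8)


def default_motifs(
    n_cell_types: int, width: int = 10, consensus_prob: float = 0.97, seed: int = 0
) -> list[MotifModel]:
    """One distinct high-information motif per cell type.

    Consensus sequences are drawn to be mutually distant (pairwise Hamming
    distance >= width // 2) so cell-type signals do not alias.
    """
    rng = np.random.default_rng([seed, 1001])
    consensi: list[np.ndarray] = []
    while len(consensi) < n_cell_types:
        cand = rng.integers(0, 4, size=width)
        if all((cand != c).sum() >= width // 2 for c in consensi):
            consensi.append(cand)
    off = (1.0 - consensus_prob) / 3.0
    motifs = []
    for c, cons in enumerate(consensi):
        pwm = np.full((4, width), off)
        pwm[cons, np.arange(width)] = consensus_prob
        motifs.append(MotifModel(id=f"motif_{c}", pwm=pwm, assigned_cell_types=frozenset({c})))
    return motifs


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the toy study.

    Defaults are the benchmark conditions used throughout the test suite:
    3 cell types with one distinct 10-bp motif each, 2,000 positive peaks per
    cell type of 1,000 bp, a 4 x 6 Mb genome with human-like GC (0.41), 20%
    of peaks shared between two cell types, and two planted motif instances
    per (peak, cell type).
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 6_000_000
    n_cell_types: int = 3
    motifs: tuple[MotifModel, ...] | None = None
    peaks_per_cell_type: int = 2000
    peak_length: int = 1000
    motifs_per_peak: int = 2
    background_gc: float = 0.41
    shared_peak_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError(f"background_gc must lie in [0, 1], got {self.background_gc}")
        if not 0.0 <= self.shared_peak_fraction <= 1.0:
            raise ValueError("shared_peak_fraction must lie in [0, 1]")
        if self.chrom_length < 10 * self.peak_length:
            raise ValueError("chrom_length must be >= 10 x peak_length")
        total = self.n_chromosomes * self.chrom_length
        need = self.peaks_per_cell_type * self.n_cell_types * self.peak_length
        if need > total // 2:
            raise ValueError(
                f"peak demand {need} bp exceeds half the genome ({total // 2} bp); "
                "no room left for negative fragments"
            )
        if self.motifs is not None:
            assigned = set().union(*(m.assigned_cell_types for m in self.motifs))
            if assigned != set(range(self.n_cell_types)):
                raise ValueError("every cell type needs at least one assigned motif")

    def resolved_motifs(self) -> list[MotifModel]:
        if self.motifs is not None:
            return list(self.motifs)
        return default_motifs(self.n_cell_types, seed=self.seed)

    @property
    def cell_type_names(self) -> list[str]:
        return [f"ct{c}" for c in range(self.n_cell_types)]


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream modules must rediscover."""

    peaks: list[GenomicInterval]
    peak_labels: np.ndarray  # (n_peaks, m) int8
    motif_placements: list[tuple[GenomicInterval, str, frozenset[int]]]
    placement_peak_index: list[int]

    def placements_for_cell_type(self, c: int) -> list[GenomicInterval]:
        return [iv for iv, _mid, cts in self.motif_placements if c in cts]


# ---------------------------------------------------------------------------
# Genome


def codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BYTE[codes].tobytes().decode("ascii")


def generate_genome(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Draw the i.i.d. background genome as per-chromosome base-code arrays.

    P(G) = P(C) = background_gc / 2, P(A) = P(T) = (1 - background_gc) / 2.
    Deterministic for a fixed spec seed.
    """
    gc = spec.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A, G, C, T
    rng = np.random.default_rng([spec.seed, 11])
    genome = {}
    for i in range(spec.n_chromosomes):
        genome[f"chr{i + 1}"] = rng.choice(4, size=spec.chrom_length, p=probs).astype(np.uint8)
    return genome


def write_genome(genome: dict[str, np.ndarray], fasta_path, sizes_path=None) -> None:
    sio.write_fasta(fasta_path, {c: codes_to_str(codes) for c, codes in genome.items()})
    if sizes_path is not None:
        sio.write_chrom_sizes(sizes_path, {c: len(v) for c, v in genome.items()})


# ---------------------------------------------------------------------------
# Peaks, labels, motif planting


def generate_peaks_and_labels(
    spec: SyntheticSpec, genome: dict[str, np.ndarray]
) -> GroundTruth:
    """Place non-overlapping peaks, plant motif instances, derive labels.

    Peaks sit on a grid with >= peak_length gaps (slot pitch 2 x peak_length),
    which guarantees non-overlap and leaves every other genome tile free for
    negative sampling. Motif instances are written into `genome` in place, so
    the genome FASTA must be written after this step. A peak's label vector
    has label[c] = 1 iff it carries >= 1 instance of a motif assigned to c.
    """
    rng = np.random.default_rng([spec.seed, 22])
    motifs = spec.resolved_motifs()
    by_cell_type: dict[int, list[MotifModel]] = {c: [] for c in range(spec.n_cell_types)}
    for m in motifs:
        for c in m.assigned_cell_types:
            by_cell_type[c].append(m)

    pitch = 2 * spec.peak_length
    slots = [
        (chrom, s * pitch)
        for chrom in sorted(genome)
        for s in range(len(genome[chrom]) // pitch)
    ]
    n_total = spec.peaks_per_cell_type * spec.n_cell_types
    if n_total > len(slots):
        raise RuntimeError(
            f"cannot place {n_total} non-overlapping peaks; only {len(slots)} "
            "grid slots available"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    chosen.sort()

    # primary cell type round-robin; a shared fraction gains one extra type
    primary = np.arange(n_total) % spec.n_cell_types
    rng.shuffle(primary)
    n_shared = int(round(spec.shared_peak_fraction * n_total))
    shared_idx = set(int(j) for j in rng.choice(n_total, size=n_shared, replace=False))

    peaks: list[GenomicInterval] = []
    labels = np.zeros((n_total, spec.n_cell_types), dtype=np.int8)
    placements: list[tuple[GenomicInterval, str, frozenset[int]]] = []
    placement_peak: list[int] = []

    for i, slot in enumerate(chosen):
        chrom, start = slots[slot]
        peak = GenomicInterval(chrom, start, start + spec.peak_length, name=f"peak_{i}")
        peaks.append(peak)
        cts = {int(primary[i])}
        if i in shared_idx and spec.n_cell_types > 1:
            extra = int(rng.integers(0, spec.n_cell_types - 1))
            if extra >= primary[i]:
                extra += 1
            cts.add(extra)
        occupied: list[tuple[int, int]] = []
        for c in sorted(cts):
            pool = by_cell_type[c]
            for _ in range(spec.motifs_per_peak):
                motif = pool[int(rng.integers(0, len(pool)))]
                off = _place_without_overlap(rng, spec.peak_length, motif.width, occupied)
                occupied.append((off, off + motif.width))
                inst = motif.sample_codes(rng)
                genome[chrom][start + off : start + off + motif.width] = inst
                iv = GenomicInterval(chrom, start + off, start + off + motif.width,
                                     name=motif.id)
                placements.append((iv, motif.id, motif.assigned_cell_types))
                placement_peak.append(i)
                for cc in motif.assigned_cell_types:
                    labels[i, cc] = 1

    return GroundTruth(peaks, labels, placements, placement_peak)


def _place_without_overlap(
    rng: np.random.Generator, peak_length: int, width: int, occupied: list[tuple[int, int]]
) -> int:
    # strictly inside the peak: 1-bp margin at both ends
    for _ in range(1000):
        off = int(rng.integers(1, peak_length - width - 1))
        if all(off + width <= s or off >= e for s, e in occupied):
            return off
    raise RuntimeError("could not place motif instance without overlap")


# ---------------------------------------------------------------------------
# Variants


def generate_variants(
    spec: SyntheticSpec,
    genome: dict[str, np.ndarray],
    truth: GroundTruth,
    n_disrupting: int,
    n_neutral: int,
) -> pd.DataFrame:
    """Emit motif-disrupting and neutral SNVs with truth labels.

    Disrupting: at a high-information PWM column (> 1 bit) whose planted base
    is the consensus, substitute the lowest-probability base of that column
    (ties broken in fixed A < C < G < T order). Neutral: inside a peak but at
    least 2 x motif-width bp from any planted instance; the alt allele is a
    random non-reference base. Positions are reported 1-based.
    """
    if not truth.motif_placements:
        raise ValueError("ground truth has no motif placements")
    rng = np.random.default_rng([spec.seed, 33])
    motif_by_id = {m.id: m for m in spec.resolved_motifs()}
    max_w = max(m.width for m in motif_by_id.values())

    rows = []

    # disrupting candidates: (placement index, column)
    candidates: list[tuple[int, int]] = []
    for pi, (iv, mid, _cts) in enumerate(truth.motif_placements):
        motif = motif_by_id[mid]
        ic = motif.information_content()
        cons = motif.consensus_codes()
        planted = genome[iv.chrom][iv.start : iv.end]
        for col in range(motif.width):
            if ic[col] > 1.0 and planted[col] == cons[col]:
                candidates.append((pi, col))
    if n_disrupting > len(candidates):
        raise ValueError(
            f"requested {n_disrupting} disrupting variants but only "
            f"{len(candidates)} eligible (placement, column) sites exist "
            f"(shortfall {n_disrupting - len(candidates)})"
        )
    # at most one variant per placement keeps variants independent
    order = rng.permutation(len(candidates))
    used_placements: set[int] = set()
    picked: list[tuple[int, int]] = []
    for j in order:
        pi, col = candidates[j]
        if pi not in used_placements:
            picked.append((pi, col))
            used_placements.add(pi)
        if len(picked) == n_disrupting:
            break
    if len(picked) < n_disrupting:
        raise ValueError(
            f"only {len(picked)} placements carry an eligible site; "
            f"shortfall {n_disrupting - len(picked)}"
        )
    for pi, col in picked:
        iv, mid, cts = truth.motif_placements[pi]
        motif = motif_by_id[mid]
        ref_code = int(genome[iv.chrom][iv.start + col])
        alt_code = _lowest_prob_base(motif.pwm[:, col])
        rows.append(
            {
                "chrom": iv.chrom,
                "pos": iv.start + col + 1,
                "ref": BASE_ORDER[ref_code],
                "alt": BASE_ORDER[alt_code],
                "truth": "disrupting",
                "motif_id": mid,
                "cell_types": ",".join(str(c) for c in sorted(cts)),
            }
        )

    # neutral candidates: peak bases >= 2*max_w from any placement
    placements_by_peak: dict[int, list[GenomicInterval]] = {}
    for pi, peak_i in enumerate(truth.placement_peak_index):
        placements_by_peak.setdefault(peak_i, []).append(truth.motif_placements[pi][0])
    peak_order = rng.permutation(len(truth.peaks))
    neutral_sites: list[tuple[str, int]] = []
    for peak_i in peak_order:
        peak = truth.peaks[peak_i]
        mask = np.ones(len(peak), dtype=bool)
        for pl in placements_by_peak.get(int(peak_i), ()):  # pad exclusion by 2*max_w
            lo = max(pl.start - peak.start - 2 * max_w, 0)
            hi = min(pl.end - peak.start + 2 * max_w, len(peak))
            mask[lo:hi] = False
        offs = np.flatnonzero(mask)
        if offs.size:
            off = int(offs[rng.integers(0, offs.size)])
            neutral_sites.append((peak.chrom, peak.start + off))
        if len(neutral_sites) >= n_neutral:
            break
    if len(neutral_sites) < n_neutral:
        raise ValueError(
            f"requested {n_neutral} neutral variants but only "
            f"{len(neutral_sites)} eligible peaks found "
            f"(shortfall {n_neutral - len(neutral_sites)})"
        )
    for chrom, pos0 in neutral_sites:
        ref_code = int(genome[chrom][pos0])
        alt_code = int(rng.choice([b for b in range(4) if b != ref_code]))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": BASE_ORDER[ref_code],
                "alt": BASE_ORDER[alt_code],
                "truth": "neutral",
                "motif_id": "",
                "cell_types": "",
            }
        )
    return pd.DataFrame(rows)


def _lowest_prob_base(column: np.ndarray) -> int:
    """Row code of the lowest-probability base; ties broken in A<C<G<T order."""
    best = int(_ALPHABETICAL_ROWS[0])
    for row in _ALPHABETICAL_ROWS[1:]:
        if column[row] < column[best]:
            best = int(row)
    return best


# ---------------------------------------------------------------------------
# Score track


def generate_score_track(
    genome: dict[str, np.ndarray],
    truth: GroundTruth,
    inside_mean: float = 0.8,
    outside_mean: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-base functionality proxy: high over planted motif bases, low elsewhere.

    Scores are Normal(outside_mean, noise_sd) genome-wide, overwritten with
    Normal(inside_mean, noise_sd) inside motif placements, clipped to [0, 1].
    A synthetic stand-in for a cross-species conservation track.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if not inside_mean > outside_mean >= 0:
        raise ValueError("require inside_mean > outside_mean >= 0")
    rng = np.random.default_rng([seed, 44])
    track = {}
    for chrom in sorted(genome):
        n = len(genome[chrom])
        track[chrom] = np.clip(rng.normal(outside_mean, noise_sd, size=n), 0.0, 1.0)
    for iv, _mid, _cts in truth.motif_placements:
        vals = np.clip(rng.normal(inside_mean, noise_sd, size=len(iv)), 0.0, 1.0)
        track[iv.chrom][iv.start : iv.end] = vals
    return track


# ---------------------------------------------------------------------------
# Full dataset written to disk


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    out_dir: str
    genome: dict[str, np.ndarray]
    truth: GroundTruth
    variants: pd.DataFrame
    fasta: str = ""
    chrom_sizes: str = ""
    peak_beds: dict[str, str] = field(default_factory=dict)
    label_table: str = ""
    variant_tsv: str = ""
    track_bedgraph: str = ""


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: str | os.PathLike,
    n_disrupting: int = 100,
    n_neutral: int = 100,
    write_track: bool = False,
    track_noise_sd: float = 0.1,
) -> SyntheticDataset:
    """Generate and write the full toy dataset (deterministic per spec.seed)."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    genome = generate_genome(spec)
    truth = generate_peaks_and_labels(spec, genome)
    variants = generate_variants(spec, genome, truth, n_disrupting, n_neutral)

    ds = SyntheticDataset(spec, out_dir, genome, truth, variants)
    ds.fasta = os.path.join(out_dir, "genome.fa")
    ds.chrom_sizes = os.path.join(out_dir, "genome.chrom.sizes")
    write_genome(genome, ds.fasta, ds.chrom_sizes)

    names = spec.cell_type_names
    for c, name in enumerate(names):
        path = os.path.join(out_dir, f"peaks_{name}.bed")
        keep = truth.peak_labels[:, c] == 1
        sio.write_bed(path, [p for p, k in zip(truth.peaks, keep) if k])
        ds.peak_beds[name] = path
    sio.write_bed(os.path.join(out_dir, "peaks.bed"), truth.peaks)
    ds.label_table = os.path.join(out_dir, "labels.tsv")
    sio.write_label_table(
        ds.label_table, [p.name for p in truth.peaks], truth.peak_labels, names
    )
    ds.variant_tsv = os.path.join(out_dir, "variants.tsv")
    sio.write_variant_tsv(ds.variant_tsv, variants)

    placements = pd.DataFrame(
        [
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "motif_id": mid,
                "cell_types": ",".join(str(c) for c in sorted(cts)),
                "peak_index": pk,
            }
            for (iv, mid, cts), pk in zip(truth.motif_placements, truth.placement_peak_index)
        ]
    )
    placements.to_csv(os.path.join(out_dir, "motif_placements.tsv"), sep="\t", index=False)

    if write_track:
        track = generate_score_track(genome, truth, noise_sd=track_noise_sd, seed=spec.seed)
        ds.track_bedgraph = os.path.join(out_dir, "track.bedgraph")
        sio.write_bedgraph(ds.track_bedgraph, track)
    return ds
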