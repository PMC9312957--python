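"""Unit tests for the synthetic benchmark generator."""

from __future__ import annotations

import numpy as np
import pytest

from scepilock import io as sio
from scepilock import synthetic as syn
from scepilock.seqdata import BASE_ORDER


def small_spec(**kw) -> syn.SyntheticSpec:
    base = dict(
        seed=7, n_chromosomes=2, chrom_length=50_000, n_cell_types=3,
        peaks_per_cell_type=10, peak_length=200, motifs_per_peak=2,
        shared_peak_fraction=0.0,
    )
    base.update(kw)
    return syn.SyntheticSpec(**base)


class TestMotifModel:
    def test_pwm_columns_must_be_stochastic(self):
        pwm = np.full((4, 6), 0.25)
        syn.MotifModel("ok", pwm, frozenset({0}))
        bad = pwm.copy()
        bad[0, 0] = 0.5
        with pytest.raises(ValueError):
            syn.MotifModel("bad", bad, frozenset({0}))

    def test_default_motifs_are_distinct_and_high_information(self):
        motifs = syn.default_motifs(3, seed=0)
        assert len({m.id for m in motifs}) == 3
        for m in motifs:
            assert m.width == 10
            assert (m.information_content() > 1.0).all()
        c0, c1 = motifs[0].consensus_codes(), motifs[1].consensus_codes()
        assert (c0 != c1).sum() >= 5

    def test_sampling_follows_the_pwm(self):
        pwm = np.zeros((4, 4))
        pwm[2] = 1.0  # all-C consensus
        m = syn.MotifModel("c", pwm, frozenset({0}))
        inst = m.sample_codes(np.random.default_rng(0))
        assert (inst == 2).all()


class TestGenerateGenome:
    def test_chromosome_count_and_length(self):
        genome = syn.generate_genome(small_spec())
        assert sorted(genome) == ["chr1", "chr2"]
        assert all(len(v) == 50_000 for v in genome.values())

    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        syn.write_genome(syn.generate_genome(small_spec()), p1)
        syn.write_genome(syn.generate_genome(small_spec()), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_extreme_gc_gives_only_g_and_c(self):
        genome = syn.generate_genome(small_spec(background_gc=1.0))
        for codes in genome.values():
            assert set(np.unique(codes)) <= {1, 2}  # G, C codes

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError, match="background_gc"):
            small_spec(background_gc=1.5)

    def test_gc_fraction_close_to_requested(self):
        genome = syn.generate_genome(small_spec(background_gc=0.41))
        codes = np.concatenate(list(genome.values()))
        gc = np.isin(codes, (1, 2)).mean()
        assert abs(gc - 0.41) < 0.01


class TestGeneratePeaksAndLabels:
    def test_placement_count_matches_closed_form(self):
        # motifs_per_peak x peaks_per_cell_type x m placements when nothing is shared
        spec = small_spec(peaks_per_cell_type=100, chrom_length=120_000,
                          n_chromosomes=2, motifs_per_peak=2, n_cell_types=2)
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        assert len(truth.motif_placements) == 2 * 100 * 2

    def test_no_sharing_gives_single_label_vectors(self):
        spec = small_spec()
        truth = syn.generate_peaks_and_labels(spec, syn.generate_genome(spec))
        assert (truth.peak_labels.sum(axis=1) == 1).all()
        assert truth.peak_labels.sum(axis=0).tolist() == [10, 10, 10]

    def test_full_sharing_with_universal_motifs_gives_all_ones(self):
        motifs = tuple(
            syn.MotifModel(m.id, m.pwm, frozenset({0, 1, 2}))
            for m in syn.default_motifs(3, seed=7)
        )
        spec = small_spec(shared_peak_fraction=1.0, motifs=motifs)
        truth = syn.generate_peaks_and_labels(spec, syn.generate_genome(spec))
        assert (truth.peak_labels == 1).all()

    def test_peaks_do_not_overlap_and_have_exact_length(self):
        spec = small_spec()
        truth = syn.generate_peaks_and_labels(spec, syn.generate_genome(spec))
        assert all(len(p) == 200 for p in truth.peaks)
        by_chrom: dict[str, list] = {}
        for p in truth.peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for peaks in by_chrom.values():
            peaks.sort()
            for a, b in zip(peaks, peaks[1:]):
                assert a.end <= b.start

    def test_placements_lie_strictly_inside_host_peaks(self):
        spec = small_spec(shared_peak_fraction=0.3)
        truth = syn.generate_peaks_and_labels(spec, syn.generate_genome(spec))
        for (iv, _mid, _cts), peak_i in zip(
            truth.motif_placements, truth.placement_peak_index
        ):
            peak = truth.peaks[peak_i]
            assert peak.start < iv.start and iv.end < peak.end

    def test_label_consistency_with_placements(self):
        spec = small_spec(shared_peak_fraction=0.4)
        truth = syn.generate_peaks_and_labels(spec, syn.generate_genome(spec))
        derived = np.zeros_like(truth.peak_labels)
        for (iv, _mid, cts), peak_i in zip(
            truth.motif_placements, truth.placement_peak_index
        ):
            for c in cts:
                derived[peak_i, c] = 1
        assert (derived == truth.peak_labels).all()

    def test_planted_instances_are_written_into_the_genome(self):
        spec = small_spec()
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        motif_by_id = {m.id: m for m in spec.resolved_motifs()}
        hits = 0
        for iv, mid, _cts in truth.motif_placements:
            planted = genome[iv.chrom][iv.start : iv.end]
            hits += (planted == motif_by_id[mid].consensus_codes()).mean()
        # consensus probability is 0.97 per column
        assert hits / len(truth.motif_placements) > 0.9


class TestGenerateVariants:
    def test_lowest_probability_base_tie_breaks_alphabetically(self):
        # rows A,G,C,T: A=0.97, others tied at 0.01 -> alt is C (A<C<G<T)
        column = np.array([0.97, 0.01, 0.01, 0.01])
        assert BASE_ORDER[syn._lowest_prob_base(column)] == "C"

    def test_disrupting_variants_fall_inside_placements(self, tiny_dataset):
        truth = tiny_dataset.truth
        disrupting = tiny_dataset.variants.query("truth == 'disrupting'")
        for row in disrupting.itertuples():
            pos0 = row.pos - 1
            assert any(
                iv.contains_point(row.chrom, pos0)
                for iv, _m, _c in truth.motif_placements
            )

    def test_neutral_variants_keep_their_distance_from_placements(self, tiny_dataset):
        truth = tiny_dataset.truth
        spec = tiny_dataset.spec
        w = max(m.width for m in spec.resolved_motifs())
        neutral = tiny_dataset.variants.query("truth == 'neutral'")
        assert len(neutral) == 30
        for row in neutral.itertuples():
            pos0 = row.pos - 1
            assert any(p.contains_point(row.chrom, pos0) for p in truth.peaks)
            for iv, _m, _c in truth.motif_placements:
                if iv.chrom == row.chrom:
                    assert iv.distance_to_point(pos0) >= 2 * w or \
                        not (iv.start - 2 * w <= pos0 < iv.end + 2 * w)

    def test_ref_matches_genome_and_alt_differs(self, tiny_dataset):
        genome = tiny_dataset.genome
        for row in tiny_dataset.variants.itertuples():
            assert BASE_ORDER[genome[row.chrom][row.pos - 1]] == row.ref
            assert row.ref != row.alt

    def test_shortfall_is_an_error(self):
        spec = small_spec()
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        with pytest.raises(ValueError, match="shortfall"):
            syn.generate_variants(spec, genome, truth, 10**6, 0)


class TestScoreTrack:
    def test_zero_noise_track_is_the_placement_indicator(self):
        spec = small_spec()
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        track = syn.generate_score_track(genome, truth, inside_mean=1.0,
                                         outside_mean=0.0, noise_sd=0.0, seed=1)
        indicator = {c: np.zeros(len(v)) for c, v in genome.items()}
        for iv, _m, _c in truth.motif_placements:
            indicator[iv.chrom][iv.start : iv.end] = 1.0
        for chrom in genome:
            assert np.array_equal(track[chrom], indicator[chrom])

    def test_seeded_determinism_of_bedgraph(self, tmp_path):
        spec = small_spec()
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        paths = []
        for name in ("a", "b"):
            track = syn.generate_score_track(genome, truth, noise_sd=0.1, seed=5)
            p = tmp_path / f"{name}.bedgraph"
            sio.write_bedgraph(p, track)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_negative_noise_rejected(self):
        spec = small_spec()
        genome = syn.generate_genome(spec)
        truth = syn.generate_peaks_and_labels(spec, genome)
        with pytest.raises(ValueError, match="noise_sd"):
            syn.generate_score_track(genome, truth, noise_sd=-0.1)


class TestRoundTrips:
    def test_bed_and_fasta_round_trip(self, tiny_dataset, tiny_genome):
        truth = tiny_dataset.truth
        reread = sio.read_bed(f"{tiny_dataset.out_dir}/peaks.bed")
        assert [(p.chrom, p.start, p.end) for p in reread] == [
            (p.chrom, p.start, p.end) for p in truth.peaks
        ]
        # FASTA round trip: in-memory codes == pyfaidx-read codes
        p = truth.peaks[0]
        from_genome = tiny_genome.fetch_codes(p.chrom, p.start, p.end)
        assert np.array_equal(from_genome, tiny_dataset.genome[p.chrom][p.start:p.end])

    def test_label_table_round_trip(self, tiny_dataset):
        ids, labels, names = sio.read_label_table(tiny_dataset.label_table)
        assert names == tiny_dataset.spec.cell_type_names
        assert np.array_equal(labels, tiny_dataset.truth.peak_labels)
        assert ids == [p.name for p in tiny_dataset.truth.peaks]
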