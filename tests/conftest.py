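"""Shared fixtures: a tiny synthetic study (small genome, short peaks) and a
small classifier trained on it, reused across saliency/variant unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from scepilock import model as mod
from scepilock import seqdata as sd
from scepilock import synthetic as syn


@pytest.fixture(scope="session")
def tiny_spec() -> syn.SyntheticSpec:
    return syn.SyntheticSpec(
        seed=11,
        n_chromosomes=2,
        chrom_length=40_000,
        n_cell_types=3,
        peaks_per_cell_type=30,
        peak_length=200,
        motifs_per_peak=2,
        shared_peak_fraction=0.2,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_ds")
    return syn.generate_dataset(
        tiny_spec, out, n_disrupting=30, n_neutral=30,
        write_track=True, track_noise_sd=0.05,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_dataset) -> sd.Genome:
    return sd.load_genome(tiny_dataset.fasta)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset, tiny_genome) -> sd.DatasetSplit:
    truth = tiny_dataset.truth
    examples = sd.encode_peaks(truth.peaks, truth.peak_labels, tiny_genome, 200)
    windows = [ex.source for ex in examples]
    negatives = sd.sample_negatives(tiny_genome, windows, n=60, length=200, seed=11)
    examples = examples + sd.encode_negatives(negatives, tiny_genome, 3)
    return sd.split_dataset(examples, seed=11)


@pytest.fixture(scope="session")
def tiny_config() -> mod.ModelConfig:
    return mod.ModelConfig(
        n_cell_types=3,
        input_length=200,
        conv_channels=(8, 8, 16, 16),
        dense1_units=32,
        learning_rate=1e-3,
        max_epochs=10,
        patience=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config, tiny_split) -> mod.ClassifierModel:
    model = mod.build_model(tiny_config)
    model, _history = mod.train(model, tiny_split)
    return model
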