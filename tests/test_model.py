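"""Unit tests for the classifier: architecture, training, prediction, checkpoints."""

from __future__ import annotations

import numpy as np
import pytest

from scepilock import model as mod
from scepilock import nn
from scepilock import seqdata as sd
from scepilock.intervals import GenomicInterval


def small_config(**kw) -> mod.ModelConfig:
    base = dict(
        n_cell_types=2, input_length=120, conv_channels=(4, 4, 8, 8),
        dense1_units=16, dropout_rates=(0.0, 0.0, 0.0), seed=0,
        max_epochs=5, patience=5,
    )
    base.update(kw)
    return mod.ModelConfig(**base)


def toy_examples(n, m=2, length=120, seed=0, motif="ACGTACGTA", labeller=None):
    """Random-background windows; positives carry a planted 9-mer."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        labels = np.zeros(m, np.int8)
        if labeller is not None:
            labels = labeller(i, codes, rng)
        out.append(
            sd.EncodedExample(codes, labels, GenomicInterval("chr1", i * length, (i + 1) * length))
        )
    return out


class TestArchitecture:
    def test_feature_map_length_formula(self):
        # 120 -> 112 -> 104 -> 26 -> 18 -> 10 -> 2
        assert small_config().feature_map_length == 2
        assert mod.ModelConfig(n_cell_types=3).feature_map_length == 57

    def test_invalid_geometry_reports_computed_length(self):
        with pytest.raises(ValueError, match="-3"):
            mod.ModelConfig(n_cell_types=2, input_length=40, dense1_units=8)

    def test_final_layer_width_equals_cell_type_count(self):
        m = mod.build_model(small_config(n_cell_types=2))
        x = np.zeros((3, 4, 120), np.float32)
        assert m.forward_logits(x).shape == (3, 2)

    def test_output_probabilities_strictly_inside_unit_interval(self):
        m = mod.build_model(small_config())
        x = mod.batch_one_hot(np.random.default_rng(0).integers(0, 4, (8, 120)).astype(np.uint8))
        p = m.predict_proba(x)
        assert (p > 0).all() and (p < 1).all()

    def test_wrong_input_length_rejected(self):
        m = mod.build_model(small_config())
        with pytest.raises(ValueError, match="expected input"):
            m.forward_logits(np.zeros((1, 4, 100), np.float32))


class TestGradients:
    def test_last_conv_gradient_matches_finite_differences(self):
        cfg = small_config(n_cell_types=2, input_length=100,
                           conv_channels=(2, 2, 2, 2), dense1_units=8, seed=3)
        m = mod.build_model(cfg)
        x = np.random.default_rng(5).random((1, 4, 100)).astype(np.float32)
        a = m.forward_feature_map(x, cache=True).astype(np.float64)
        logits = m.head_logits(a.astype(np.float32), cache=True)
        d = np.zeros_like(logits)
        d[0, 0] = 1.0
        da = m.head_input_grad(d)

        eps = 1e-3
        fd = np.zeros_like(da)
        for k in range(a.shape[1]):
            for i in range(a.shape[2]):
                ap, am = a.copy(), a.copy()
                ap[0, k, i] += eps
                am[0, k, i] -= eps
                fd[0, k, i] = (
                    m.head_logits(ap.astype(np.float32))[0, 0]
                    - m.head_logits(am.astype(np.float32))[0, 0]
                ) / (2 * eps)
        rel = np.abs(da - fd) / (np.abs(fd) + 1e-8)
        assert rel.max() < 1e-4

    def test_full_backprop_matches_loss_finite_differences(self):
        cfg = small_config(conv_channels=(2, 2, 2, 2), dense1_units=8,
                           input_length=100, seed=3)
        m = mod.build_model(cfg)
        x = np.random.default_rng(1).random((2, 4, 100)).astype(np.float32)
        y = np.array([[1.0, 0.0], [0.0, 1.0]], np.float32)
        logits = m.forward_logits(x, cache=True)
        _, dlog = nn.bce_with_logits(logits, y)
        m.features.backward(m.head.backward(dlog))
        grads = m.grad_arrays()
        params = m.param_arrays()
        for name in ("conv1.W", "conv4.W", "dense2.b"):
            p = params[name]
            idx = np.unravel_index(np.abs(grads[name]).argmax(), p.shape)
            orig = p[idx]
            p[idx] = orig + 1e-2
            lp, _ = nn.bce_with_logits(m.forward_logits(x), y)
            p[idx] = orig - 1e-2
            lm, _ = nn.bce_with_logits(m.forward_logits(x), y)
            p[idx] = orig
            fd = (lp - lm) / 2e-2
            assert abs(grads[name][idx] - fd) <= 1e-3 * max(abs(fd), 1e-3)


class TestTraining:
    def _separable_split(self):
        # positives carry one of two disjoint 8-mers, one per class
        kmers = {0: "AAAACCCC", 1: "GGGGTTTT"}

        def labeller(i, codes, rng):
            labels = np.zeros(2, np.int8)
            cls = i % 3
            if cls < 2:
                kmer = sd.encode_codes(kmers[cls])
                codes[40 : 40 + 8] = kmer
                labels[cls] = 1
            return labels

        examples = toy_examples(120, labeller=labeller)
        return sd.split_dataset(examples, seed=0)

    def test_loss_decreases_on_separable_toy_data(self):
        split = self._separable_split()
        m = mod.build_model(small_config(seed=1, learning_rate=1e-3))
        m, history = mod.train(m, split, max_epochs=5, patience=5)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_training_is_deterministic_per_seed(self):
        split = self._separable_split()
        h = []
        for _ in range(2):
            m = mod.build_model(small_config(seed=2))
            _, history = mod.train(m, split, max_epochs=2, patience=2)
            h.append([e["val_loss"] for e in history])
        assert h[0] == h[1]

    def test_all_zero_labels_drive_predictions_to_zero(self):
        examples = toy_examples(120)
        split = sd.split_dataset(examples, seed=0)
        m = mod.build_model(small_config(seed=0, learning_rate=5e-2))
        m, _ = mod.train(m, split, max_epochs=20, patience=20)
        probs = mod.predict(m, split.test)
        assert probs.mean() < 0.1

    def test_empty_validation_is_an_error(self):
        examples = toy_examples(20)
        split = sd.DatasetSplit(examples, [], [], 0)
        m = mod.build_model(small_config())
        with pytest.raises(ValueError, match="non-empty"):
            mod.train(m, split)

    def test_best_validation_snapshot_is_returned(self):
        split = self._separable_split()
        m = mod.build_model(small_config(seed=3))
        m, history = mod.train(m, split, max_epochs=4, patience=4)
        best = min(e["val_loss"] for e in history)
        fwd, rev = mod._both_strand_codes(split.validation)
        codes = np.concatenate([fwd, rev])
        labels = np.concatenate([np.stack([e.labels for e in split.validation])] * 2)
        current = mod._epoch_loss(m, codes, labels.astype(np.float32), 256)
        assert current == pytest.approx(best, rel=1e-5)


class TestPredict:
    def test_strand_max_dominates_each_strand(self, tiny_model, tiny_split):
        ex = tiny_split.test[0]
        p = mod.predict(tiny_model, [ex])[0]
        p_fwd, p_rev = mod.predict_strands(tiny_model, ex)
        assert (p >= p_fwd - 1e-7).all() and (p >= p_rev - 1e-7).all()
        assert np.allclose(p, np.maximum(p_fwd, p_rev))

    def test_palindromic_window_scores_equally_on_both_strands(self, tiny_model):
        half = np.random.default_rng(0).integers(0, 4, 100).astype(np.uint8)
        codes = np.concatenate([half, sd.reverse_complement_codes(half)])
        ex = sd.EncodedExample(codes, np.zeros(3, np.int8), GenomicInterval("chr1", 0, 200))
        p_fwd, p_rev = mod.predict_strands(tiny_model, ex)
        assert np.allclose(p_fwd, p_rev, atol=1e-6)

    def test_inference_is_deterministic(self, tiny_model, tiny_split):
        a = mod.predict(tiny_model, tiny_split.test[:4])
        b = mod.predict(tiny_model, tiny_split.test[:4])
        assert np.array_equal(a, b)

    def test_window_length_mismatch_errors(self, tiny_model):
        ex = sd.EncodedExample(np.zeros(100, np.uint8), np.zeros(3, np.int8),
                               GenomicInterval("chr1", 0, 100))
        with pytest.raises(ValueError, match="length"):
            mod.predict(tiny_model, [ex])


class TestCheckpoints:
    def test_round_trip_is_bit_exact(self, tmp_path, tiny_model, tiny_split):
        path = tmp_path / "model.npz"
        mod.save_checkpoint(tiny_model, path)
        back = mod.load_checkpoint(path)
        assert back.config == tiny_model.config
        a = mod.predict(tiny_model, tiny_split.test[:2])
        b = mod.predict(back, tiny_split.test[:2])
        assert np.array_equal(a, b)

    def test_corrupted_file_errors_and_leaves_model_unchanged(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        m = mod.build_model(small_config())
        before = {k: v.copy() for k, v in m.param_arrays().items()}
        with pytest.raises(ValueError, match="cannot read"):
            mod.warm_start(m, path)
        after = m.param_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_warm_start_same_architecture_loads_everything(self, tmp_path):
        src = mod.build_model(small_config(seed=10))
        path = tmp_path / "src.npz"
        mod.save_checkpoint(src, path)
        dst = mod.build_model(small_config(seed=11))
        manifest = mod.warm_start(dst, path)
        assert manifest["reinitialized"] == []
        assert set(manifest["loaded"]) == set(src.param_arrays())
        for k, v in src.param_arrays().items():
            assert np.array_equal(v, dst.param_arrays()[k])

    def test_warm_start_reinitializes_only_the_final_layer_on_m_mismatch(self, tmp_path):
        src = mod.build_model(small_config(n_cell_types=8, seed=10))
        path = tmp_path / "src.npz"
        mod.save_checkpoint(src, path)
        dst = mod.build_model(small_config(n_cell_types=2, seed=11))
        fresh_final = dst.param_arrays()["dense2.W"].copy()
        manifest = mod.warm_start(dst, path)
        assert sorted(manifest["reinitialized"]) == ["dense2.W", "dense2.b"]
        assert np.array_equal(dst.param_arrays()["dense2.W"], fresh_final)
        assert np.array_equal(dst.param_arrays()["conv1.W"], src.param_arrays()["conv1.W"])

    def test_incompatible_conv_stack_is_an_error(self, tmp_path):
        src = mod.build_model(small_config(conv_channels=(6, 6, 8, 8), seed=1))
        path = tmp_path / "src.npz"
        mod.save_checkpoint(src, path)
        dst = mod.build_model(small_config(conv_channels=(4, 4, 8, 8), seed=2))
        with pytest.raises(ValueError, match="conv1"):
            mod.warm_start(dst, path)
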