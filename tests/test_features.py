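"""Two-level recurrent extractor: windowing, encoding, differentiability."""

import numpy as np
import pytest

from microbeat.features import (
    ExtractorConfig,
    extract_features,
    extract_features_batch,
    forward_batch_with_input,
    init_extractor,
    level1_encode,
    level2_encode,
    n_params,
    window_split,
)
from microbeat.records import BeatSlice

SMALL = ExtractorConfig(omega=10, hidden1=6, hidden2=8, m=12, seed=3)


class TestWindowSplit:
    def test_single_window_when_r_equals_omega(self, rng):
        v = rng.normal(size=25)
        wins = window_split(v, 25)
        assert len(wins) == 1 and np.array_equal(wins[0], v)

    def test_concatenation_reproduces_slice(self, rng):
        v = rng.normal(size=250)
        wins = window_split(v, 25)
        assert len(wins) == 10
        assert np.array_equal(np.concatenate(wins), v)

    def test_final_window_edge_padded(self, rng):
        v = rng.normal(size=250)
        wins = window_split(v, 32)
        assert len(wins) == 8
        assert np.array_equal(np.concatenate(wins)[:250], v)
        assert np.all(wins[-1][-6:] == v[-1])


class TestLevelEncoders:
    def test_identical_windows_identical_summaries(self, rng):
        p = init_extractor(SMALL)
        w = rng.normal(size=10)
        s1, s2 = level1_encode([w, w], SMALL, p)
        assert np.array_equal(s1, s2)

    def test_level1_stateless_across_windows(self, rng):
        p = init_extractor(SMALL)
        w1, w2 = rng.normal(size=10), rng.normal(size=10)
        alone = level1_encode([w1], SMALL, p)[0]
        paired = level1_encode([w1, w2], SMALL, p)[0]
        assert np.array_equal(alone, paired)

    def test_zero_window_zero_bias_plain_rnn_fixed_point(self):
        cfg = ExtractorConfig(omega=10, cell_type="plainRNN", hidden1=6,
                              hidden2=8, m=12, seed=3)
        p = init_extractor(cfg)
        for k in p:
            if ".b" in k:
                p[k].data[:] = 0.0
        out = level1_encode([np.zeros(10)], cfg, p)[0]
        assert np.allclose(out, 0.0)

    def test_level2_output_length_and_determinism(self, rng):
        for m in (8, 64):
            cfg = ExtractorConfig(omega=10, hidden1=6, hidden2=8, m=m, seed=3)
            p = init_extractor(cfg)
            summaries = [rng.normal(size=cfg.l1_out) for _ in range(4)]
            a = level2_encode(summaries, cfg, p)
            b = level2_encode(summaries, cfg, p)
            assert len(a.values) == m
            assert np.array_equal(a.values, b.values)

    def test_level2_rejects_empty_input(self):
        with pytest.raises(ValueError):
            level2_encode([], SMALL, init_extractor(SMALL))

    def test_level2_order_sensitive(self, rng):
        p = init_extractor(SMALL)
        summaries = [rng.normal(size=SMALL.l1_out) for _ in range(5)]
        fwd = level2_encode(summaries, SMALL, p)
        rev = level2_encode(summaries[::-1], SMALL, p)
        assert np.linalg.norm(fwd.values - rev.values) > 0

    def test_window_length_mismatch_rejected(self, rng):
        p = init_extractor(SMALL)
        with pytest.raises(ValueError):
            level1_encode([rng.normal(size=7)], SMALL, p)


class TestExtractFeatures:
    def test_equals_manual_composition(self, rng):
        p = init_extractor(SMALL)
        v = rng.normal(size=50)
        composed = level2_encode(
            level1_encode(window_split(v, SMALL.omega), SMALL, p), SMALL, p
        )
        direct = extract_features(BeatSlice(v), SMALL, p)
        assert np.allclose(direct.values, composed.values, atol=1e-12)

    def test_batch_matches_single(self, rng):
        p = init_extractor(SMALL)
        X = rng.normal(size=(5, 50))
        F = extract_features_batch(X, SMALL, p)
        for i in range(5):
            assert np.allclose(
                F[i], extract_features(X[i], SMALL, p).values, atol=1e-12
            )

    def test_input_gradient_matches_finite_differences(self, rng):
        cfg = ExtractorConfig(omega=5, hidden1=4, hidden2=4, m=3, seed=0,
                              cell_type="GRU")
        p = init_extractor(cfg)
        x = rng.normal(size=(1, 20))
        y, xt = forward_batch_with_input(x, cfg, p)
        y[0, 1].backward()
        eps = 1e-6
        for j in range(0, 20, 7):
            xp, xm = x.copy(), x.copy()
            xp[0, j] += eps
            xm[0, j] -= eps
            fd = (
                extract_features_batch(xp, cfg, p)[0, 1]
                - extract_features_batch(xm, cfg, p)[0, 1]
            ) / (2 * eps)
            rel = abs(xt.grad[0, j] - fd) / max(abs(fd), 1e-8)
            assert rel < 1e-4

    @pytest.mark.parametrize("cell", ["plainRNN", "GRU", "LSTM", "BiLSTM"])
    def test_all_cells_produce_m_features(self, cell, rng):
        cfg = ExtractorConfig(omega=10, cell_type=cell, hidden1=5,
                              hidden2=6, m=7, seed=1)
        p = init_extractor(cfg)
        out = extract_features(rng.normal(size=30), cfg, p)
        assert out.values.shape == (7,)


class TestMicroFootprint:
    def test_parameter_count_independent_of_slice_length(self, rng):
        p = init_extractor(SMALL)
        count = n_params(p)
        # the same parameters encode slices of any length (weight sharing)
        for r in (30, 50, 120):
            extract_features(rng.normal(size=r), SMALL, p)
        assert n_params(p) == count

    def test_default_model_serializes_under_one_megabyte(self, tmp_path):
        from microbeat.ensemble import EnsembleHyper, EnsembleModel, MiniClassifier

        cfg = ExtractorConfig()
        ext = init_extractor(cfg)
        clfs = [MiniClassifier(i, cfg.m) for i in range(3)]
        model = EnsembleModel(cfg, ext, clfs, EnsembleHyper(), ("N", "S", "V"))
        path = tmp_path / "model.npz"
        model.save(path)
        assert path.stat().st_size < 1_000_000
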