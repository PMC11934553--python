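"""The boundary classifier: gradients, attention blocks, training, prediction."""

import numpy as np
import pytest

import hictad.nn as nn
from hictad.labeling import DatasetSplit, build_dataset
from hictad.metrics import boundary_prf
from hictad.model import (BoundaryClassifier, BoundaryNet, ModelConfig,
                          load_checkpoint, predict_boundaries, save_checkpoint)
from hictad.synth import SimConfig, simulate_hic

TINY = dict(conv1_filters=8, conv2_filters=8, transformer_dim=8,
            attention_heads=2, transformer_ff=16, cbam_reduction=4,
            fc_hidden=8, dropout_rate=0.0, seed=7)


def _bce_and_grad(net, x, y):
    logits = net.forward_logits(x)
    p = nn.sigmoid(logits)
    loss = -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
    return loss, (p - y) / len(y)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients through the whole network (conv, CBAM,
        transformer, heads) agree with central differences."""
        net = BoundaryNet(ModelConfig(**TINY))
        x = rng.random((3, 10, 10))
        y = np.array([1.0, 0.0, 1.0])
        loss, dlogits = _bce_and_grad(net, x, y)
        net.zero_grad()
        net.backward(dlogits)
        eps = 1e-6
        for par, grad in zip(net.params, net.grads):
            flat, gflat = par.ravel(), grad.ravel()
            for ix in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[ix]
                flat[ix] = old + eps
                lp, _ = _bce_and_grad(net, x, y)
                flat[ix] = old - eps
                lm, _ = _bce_and_grad(net, x, y)
                flat[ix] = old
                numeric = (lp - lm) / (2 * eps)
                assert gflat[ix] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestArchitecture:
    def test_untrained_probabilities_in_unit_interval(self, rng):
        net = BoundaryNet(ModelConfig(**TINY))
        p = net.predict_proba(rng.random((5, 10, 10)))
        assert np.all((p >= 0) & (p <= 1))

    def test_identical_seeds_identical_weights(self):
        a, b = BoundaryNet(ModelConfig(**TINY)), BoundaryNet(ModelConfig(**TINY))
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_parameter_count_matches_shape_arithmetic(self):
        cfg = ModelConfig(**TINY)
        net = BoundaryNet(cfg)
        k2 = cfg.kernel_size ** 2
        tokens = 25
        expected = (
            cfg.conv1_filters * k2 + cfg.conv1_filters              # conv1
            + cfg.conv2_filters * cfg.conv1_filters * k2 + cfg.conv2_filters
            + 2 * cfg.conv2_filters * (cfg.conv2_filters // cfg.cbam_reduction)
            + 2 * 49 + 1                                            # spatial 7x7
            + cfg.conv2_filters * cfg.transformer_dim + cfg.transformer_dim
            + tokens * cfg.transformer_dim                          # positions
            + cfg.transformer_layers * (
                4 * (cfg.transformer_dim ** 2 + cfg.transformer_dim)  # q,k,v,o
                + 2 * 2 * cfg.transformer_dim                         # ln1, ln2
                + cfg.transformer_dim * cfg.transformer_ff + cfg.transformer_ff
                + cfg.transformer_ff * cfg.transformer_dim + cfg.transformer_dim
            )
            + cfg.transformer_dim * cfg.fc_hidden + cfg.fc_hidden
            + cfg.fc_hidden + 1
        )
        assert net.n_parameters() == expected > 0

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(decision_threshold=1.0)
        with pytest.raises(ValueError):
            ModelConfig(attention_heads=3, transformer_dim=64)
        with pytest.raises(ValueError):
            ModelConfig(conv2_filters=60, cbam_reduction=8)


class TestChannelAttention:
    def test_zero_input_zero_output_half_gate(self):
        rng = np.random.default_rng(0)
        ca = nn.ChannelAttention(4, 2, rng)
        x = np.zeros((2, 4, 5, 5))
        assert np.all(ca.forward(x) == 0)
        # with the MLP zeroed the pre-sigmoid is 0, so the gate is exactly 0.5
        ca.W1[...] = 0
        ones = np.ones((1, 4, 5, 5))
        np.testing.assert_allclose(ca.forward(ones), 0.5 * ones)

    def test_gate_shrinks_magnitude(self, rng):
        ca = nn.ChannelAttention(8, 4, np.random.default_rng(1))
        x = rng.random((2, 8, 5, 5))
        out = ca.forward(x)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_monotone_in_channel_energy_with_identity_mlp(self):
        ca = nn.ChannelAttention(2, 1, np.random.default_rng(2))
        ca.W1[...] = 0.1 * np.eye(2)
        ca.W2[...] = 0.1 * np.eye(2)
        x = np.zeros((1, 2, 4, 4))
        x[0, 0] = 5.0   # high-energy channel
        x[0, 1] = 0.5   # low-energy channel
        out = ca.forward(x)
        gate = out[0, :, 0, 0] / x[0, :, 0, 0]
        assert gate[0] >= gate[1]

    def test_bad_reduction(self):
        with pytest.raises(ValueError):
            nn.ChannelAttention(6, 4, np.random.default_rng(0))


class TestSpatialAttention:
    def test_zero_conv_gives_half_gate(self):
        sa = nn.SpatialAttention(np.random.default_rng(0))
        sa.conv.W[...] = 0
        sa.conv.b[...] = 0
        x = np.ones((2, 3, 5, 5))
        np.testing.assert_allclose(sa.forward(x), 0.5 * x)

    def test_output_shape_matches_input(self, rng):
        sa = nn.SpatialAttention(np.random.default_rng(0))
        x = rng.random((2, 6, 5, 5))
        assert sa.forward(x).shape == x.shape

    def test_gate_invariant_to_channel_permutation(self, rng):
        sa = nn.SpatialAttention(np.random.default_rng(0))
        x = rng.random((1, 6, 5, 5))
        perm = np.array([3, 0, 5, 1, 4, 2])
        out, out_p = sa.forward(x), sa.forward(x[:, perm])
        np.testing.assert_allclose(out_p, out[:, perm])


def _tiny_split(seed=0):
    m, truth = simulate_hic(SimConfig(n_bins=200, tad_size_range=(10, 16),
                                      nest_prob=0.0, noise_sigma=0.0,
                                      seed=seed))
    samples = build_dataset(m, truth.boundaries, seed=seed)
    k = len(samples) // 2
    return DatasetSplit(train=samples, validation=samples[:k]), m, truth


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self):
        split, _, _ = _tiny_split()
        res = BoundaryClassifier(ModelConfig(**TINY, epochs=0)).fit(split)
        assert len(res.log) == 0 and res.best_epoch == 0
        init = BoundaryNet(ModelConfig(**TINY))
        for a, b in zip(res.net.params, init.params):
            np.testing.assert_array_equal(a, b)

    def test_seeded_training_is_reproducible(self):
        split, _, _ = _tiny_split()
        cfg = ModelConfig(**{**TINY, "dropout_rate": 0.3}, epochs=2)
        r1 = BoundaryClassifier(cfg).fit(split)
        r2 = BoundaryClassifier(cfg).fit(split)
        assert r1.log["train_loss"].tolist() == r2.log["train_loss"].tolist()
        for a, b in zip(r1.net.params, r2.net.params):
            np.testing.assert_array_equal(a, b)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            BoundaryClassifier(ModelConfig(**TINY)).fit(DatasetSplit())

    def test_summary_mentions_fit(self):
        split, _, _ = _tiny_split()
        res = BoundaryClassifier(ModelConfig(**TINY, epochs=1)).fit(split)
        text = res.summary()
        assert "parameters" in text and "val loss" in text


class TestTrainedRecovery:
    def test_separable_training_data_fit_tightly(self, recovery_run):
        """On noise-free planted boundaries the classifier should nearly
        interpolate its training data (F1 >= 0.95 at threshold 0.5)."""
        fit = recovery_run.fit
        x = np.stack([s.window.values for s in recovery_run.split.train])
        y = np.array([s.label for s in recovery_run.split.train])
        pred = (fit.net.predict_proba(x) > 0.5).astype(int)
        tp = np.sum((pred == 1) & (y == 1))
        prec = tp / max(pred.sum(), 1)
        rec = tp / y.sum()
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        assert f1 >= 0.95

    def test_held_out_recall_on_planted_boundaries(self, recovery_run):
        """Several hundred training boundaries, zero noise: the classifier
        must re-find >= 80% of held-out planted boundaries at threshold 0.5."""
        assert sum(len(t.boundaries) for c, (m, t) in recovery_run.sims.items()
                   if c in ("chrS0", "chrS1", "chrS2")) >= 200
        assert len(recovery_run.truth.boundaries) >= 50
        _, recall, _ = boundary_prf(recovery_run.result.candidate_boundaries,
                                    recovery_run.truth.boundaries, tol_bins=1)
        assert recall >= 0.8


class TestPrediction:
    def test_score_count_and_strict_threshold(self, monkeypatch):
        m, _ = simulate_hic(SimConfig(n_bins=30, tad_size_range=(5, 8), seed=1))
        net = BoundaryNet(ModelConfig(**TINY))
        fixed = np.full(m.n_bins, 0.2)
        fixed[7] = 0.6
        monkeypatch.setattr(BoundaryNet, "predict_proba",
                            lambda self, x, batch_size=256: fixed[:len(x)])
        scores, bset = predict_boundaries(net, m, threshold=0.5)
        assert len(scores) == m.n_bins
        assert bset == [7]
        # strict ">": a score exactly at the threshold is not a boundary
        _, at = predict_boundaries(net, m, threshold=0.6)
        assert at == []

    def test_threshold_one_gives_empty_set(self):
        m, _ = simulate_hic(SimConfig(n_bins=30, tad_size_range=(5, 8), seed=1))
        net = BoundaryNet(ModelConfig(**TINY))
        _, bset = predict_boundaries(net, m, threshold=1.0)
        assert bset == []

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = BoundaryNet(ModelConfig(**TINY))
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path)
        assert back.cfg == net.cfg
        x = rng.random((4, 10, 10))
        np.testing.assert_array_equal(back.predict_proba(x), net.predict_proba(x))


def test_resolution_mismatch_warns_but_predicts():
    m, _ = simulate_hic(SimConfig(n_bins=30, tad_size_range=(5, 8),
                                  resolution=10_000, seed=1))
    net = BoundaryNet(ModelConfig(**TINY))
    with pytest.warns(UserWarning, match="resolution"):
        scores, _ = predict_boundaries(net, m)
    assert len(scores) == m.n_bins
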