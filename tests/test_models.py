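import numpy as np
import pytest

from emgrecal import (
    ModelConfig, TrainConfig, build_backbone, build_calibrator, forward,
    load_checkpoint, save_checkpoint,
)
from emgrecal.models import softmax_cross_entropy
from emgrecal.training import _fit

TINY = ModelConfig(n_channels=8, win_len=24, n_classes=3, bilstm_hidden=2,
                   fc_hidden=3, bottleneck_dim=4, dropout=0.0)


def _params_bytes(model):
    return {k: v.tobytes() for k, v in model.params.items()}


class TestConstruction:
    def test_seeded_init_is_bitwise_reproducible(self):
        a, b = build_backbone(TINY, seed=42), build_backbone(TINY, seed=42)
        assert _params_bytes(a) == _params_bytes(b)
        c = build_backbone(TINY, seed=43)
        assert _params_bytes(a) != _params_bytes(c)

    def test_default_bottleneck_width_is_four(self):
        bb = build_backbone(ModelConfig(), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 8, 24)).astype(np.float32)
        _, bott = forward(bb, None, x)
        assert bott.shape == (2, 4)

    def test_parameter_count_matches_closed_form(self):
        # independent closed-form sum: per LSTM direction 4H(D+H+1),
        # doubled for bidirectionality; D+1 -> D weights + bias per linear unit
        H, F, K, C = 2, 3, 3, 8

        def bilstm(d):
            return 2 * 4 * H * (d + H + 1)

        def linear(d_in, d_out):
            return d_in * d_out + d_out

        expected = (
            bilstm(C) + bilstm(2 * H)            # encoder recurrent stack
            + linear(2 * H, F) + linear(F, 4)    # encoder fc -> bottleneck
            + linear(4, F) + linear(F, 2 * H)    # decoder fc mirror
            + bilstm(2 * H) + bilstm(2 * H)      # decoder recurrent stack
            + linear(2 * H, K)                   # classification head
        )
        assert build_backbone(TINY, seed=0).n_params() == expected

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError, match="invalid architecture"):
            ModelConfig(bottleneck_dim=0).validate()
        with pytest.raises(ValueError, match="invalid architecture"):
            ModelConfig(dropout=1.0).validate()

    def test_mirror_symmetry_of_encoder_and_decoder(self):
        bb = build_backbone(ModelConfig(), seed=0)
        enc, dec = bb.encoder_structure(), bb.decoder_structure()
        enc_fc = [l for l in enc if l[0] == "fc"]
        dec_fc = [l for l in dec if l[0] == "fc"]
        assert dec_fc == [("fc", o, i) for (_, i, o) in reversed(enc_fc)]
        enc_lstm = [l for l in enc if l[0] == "bilstm"]
        dec_lstm = [l for l in dec if l[0] == "bilstm"]
        assert len(enc_lstm) == len(dec_lstm)
        assert all(l[2] == enc_lstm[0][2] for l in enc_lstm + dec_lstm)


class TestCalibrator:
    def test_identity_init_is_passthrough(self):
        cal = build_calibrator(ModelConfig(), seed=0, init="identity")
        x = np.random.default_rng(1).normal(size=(16, 8, 24)).astype(np.float32)
        y, _ = cal.forward(x)
        assert np.max(np.abs(y - x)) <= 1e-6

    def test_output_shape_preserved_for_any_init(self):
        cal = build_calibrator(ModelConfig(), seed=3, init="random")
        x = np.random.default_rng(2).normal(size=(5, 8, 24)).astype(np.float32)
        y, _ = cal.forward(x)
        assert y.shape == x.shape

    def test_random_init_reproducible_bitwise(self):
        a = build_calibrator(ModelConfig(), seed=9, init="random")
        b = build_calibrator(ModelConfig(), seed=9, init="random")
        assert _params_bytes(a) == _params_bytes(b)

    def test_unknown_init_rejected(self):
        with pytest.raises(ValueError, match="unknown calibrator init"):
            build_calibrator(ModelConfig(), init="zeros")


class TestForward:
    def test_probabilities_normalized(self):
        bb = build_backbone(TINY, seed=0)
        x = np.random.default_rng(3).normal(size=(100, 8, 24)).astype(np.float32)
        probs, bott = forward(bb, None, x)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert bott.shape == (100, 4)

    def test_identity_calibrator_matches_bare_forward(self):
        bb = build_backbone(TINY, seed=1)
        cal = build_calibrator(TINY, seed=2, init="identity")
        x = np.random.default_rng(4).normal(size=(8, 8, 24)).astype(np.float32)
        p0, b0 = forward(bb, None, x)
        p1, b1 = forward(bb, cal, x)
        np.testing.assert_allclose(p1, p0, atol=1e-5)
        np.testing.assert_allclose(b1, b0, atol=1e-5)

    def test_inference_is_deterministic(self):
        bb = build_backbone(ModelConfig(dropout=0.5), seed=5)
        x = np.random.default_rng(5).normal(size=(4, 8, 24)).astype(np.float32)
        p0, _ = forward(bb, None, x)
        p1, _ = forward(bb, None, x)
        np.testing.assert_array_equal(p0, p1)

    def test_bad_window_shape_rejected(self):
        bb = build_backbone(TINY, seed=0)
        with pytest.raises(ValueError, match="bad window"):
            bb.forward(np.zeros((2, 8, 23), dtype=np.float32))


class TestGradients:
    def test_directional_derivative_matches_backprop(self):
        """Finite-difference check of the full backward pass (backbone +
        calibrator) along a random parameter direction."""
        cfg = ModelConfig(n_channels=8, win_len=6, n_classes=3, bilstm_hidden=4,
                          fc_hidden=5, dropout=0.0)
        bb = build_backbone(cfg, seed=1)
        cal = build_calibrator(cfg, seed=2, init="random")
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 8, 6)).astype(np.float32)
        y = np.array([0, 1, 2, 0])

        def loss_and_grads():
            xc, cc = cal.forward(x)
            _, _, cache = bb.forward(xc, train=False)
            loss, d_log = softmax_cross_entropy(cache["logits"], y)
            gb, gc = bb.zero_grads(), cal.zero_grads()
            dx = bb.backward(gb, d_log, cache)
            cal.backward(gc, dx, cc)
            return loss, (gb, gc)

        _, (gb, gc) = loss_and_grads()
        direction = {m: {k: rng.normal(size=v.shape).astype(np.float32)
                         for k, v in model.params.items()}
                     for m, model in (("bb", bb), ("cal", cal))}
        analytic = sum(float(np.vdot(g[k], direction[m][k]))
                       for m, g in (("bb", gb), ("cal", gc)) for k in g)
        eps = 5e-3
        for sgn in (1, -1):
            for m, model in (("bb", bb), ("cal", cal)):
                for k in model.params:
                    model.params[k] = model.params[k] + np.float32(sgn * eps) * direction[m][k]
            if sgn == 1:
                loss_plus, _ = loss_and_grads()
                # step back to center, then to minus
                for m, model in (("bb", bb), ("cal", cal)):
                    for k in model.params:
                        model.params[k] = model.params[k] - np.float32(eps) * direction[m][k]
        loss_minus, _ = loss_and_grads()
        numeric = (loss_plus - loss_minus) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=0.05, abs=1e-4)


class TestFreezing:
    def test_frozen_model_is_bitwise_untouched_by_training(self):
        cfg = ModelConfig(n_classes=3, bilstm_hidden=4, fc_hidden=4, dropout=0.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 8, 24)).astype(np.float32)
        y = rng.integers(0, 3, 80)
        tc = TrainConfig(learning_rate=0.01, max_epochs_per_session=2,
                         early_stopping_patience=2, batch_size=32)

        bb = build_backbone(cfg, seed=0)
        cal = build_calibrator(cfg, seed=1, init="identity")
        bb.frozen, cal.frozen = True, False
        before = _params_bytes(bb)
        cal_before = _params_bytes(cal)
        _fit(bb, cal, x, y, x[:16], y[:16], tc, np.random.default_rng(0))
        assert _params_bytes(bb) == before
        assert _params_bytes(cal) != cal_before

        bb.frozen, cal.frozen = False, True
        cal_before = _params_bytes(cal)
        before = _params_bytes(bb)
        _fit(bb, cal, x, y, x[:16], y[:16], tc, np.random.default_rng(0))
        assert _params_bytes(cal) == cal_before
        assert _params_bytes(bb) != before


def test_checkpoint_round_trip(tmp_path):
    bb = build_backbone(TINY, seed=7)
    bb.input_scale = 123.5
    bb.class_labels = ["a", "b", "c"]
    cal = build_calibrator(TINY, seed=8, init="random")
    save_checkpoint(tmp_path / "ck.npz", bb, {"sess1": cal})
    bb2, cals = load_checkpoint(tmp_path / "ck.npz")
    assert _params_bytes(bb) == _params_bytes(bb2)
    assert bb2.input_scale == 123.5
    assert bb2.class_labels == ["a", "b", "c"]
    assert _params_bytes(cals["sess1"]) == _params_bytes(cal)
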