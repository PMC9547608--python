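"""Fluence-correction networks: contracts, loss, training behaviour."""

import numpy as np
import pytest

from oaflux.errors import ConfigurationError, DegenerateInputError, ShapeError
from oaflux.models import (ARCHITECTURES, NetConfig, PairedSample,
                           build_network, denormalize, normalize, nrmse_loss,
                           predict_and_denormalize, train)

rng = np.random.default_rng(0)


def test_nrmse_hand_values():
    """Direct arithmetic: identical -> 0; zero estimate -> 1;
    [3,4] vs [3,0] -> sqrt(16/2)/sqrt(25/2) = 0.8."""
    y = np.array([3.0, 4.0])
    assert nrmse_loss(y, y) == pytest.approx(0.0)
    assert nrmse_loss(y, np.zeros(2)) == pytest.approx(1.0)
    assert nrmse_loss(y, np.array([3.0, 0.0])) == pytest.approx(0.8)


def test_nrmse_zero_reference_rejected():
    with pytest.raises(DegenerateInputError):
        nrmse_loss(np.zeros(4), np.ones(4))


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_output_shape_matches_input(arch):
    """Image-to-image contract on 64x64 inputs at depth 4 for all six."""
    cfg = NetConfig(arch=arch, depth=4, base_channels=4, seed=0)
    model = build_network(cfg)
    x = rng.random((64, 64)).astype(np.float32)
    s = rng.random((64, 64)).astype(np.float32)
    out = model.predict(x, s if arch in ("ynet", "fd_ynet") else None)
    assert out.shape == (64, 64)


def test_output_shape_128():
    cfg = NetConfig(arch="unet", depth=4, base_channels=4, seed=0)
    x = rng.random((128, 128)).astype(np.float32)
    assert build_network(cfg).predict(x).shape == (128, 128)


def test_indivisible_shape_rejected_with_hint():
    cfg = NetConfig(arch="unet", depth=4, base_channels=4, seed=0)
    with pytest.raises(ShapeError, match="pad"):
        build_network(cfg).predict(rng.random((60, 60)).astype(np.float32))


def test_seeded_builds_identical():
    cfg = NetConfig(arch="fd_unet", depth=2, base_channels=4, seed=9)
    a = build_network(cfg)
    b = build_network(cfg)
    for pa, pb in zip(a.net.parameters(), b.net.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


def test_ynet_without_sinogram_rejected():
    cfg = NetConfig(arch="ynet", depth=2, base_channels=4, seed=0)
    with pytest.raises(ConfigurationError):
        build_network(cfg).predict(rng.random((32, 32)).astype(np.float32))


def _toy_samples(n, size=32, seed=0):
    r = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        y = (r.random((size, size)) > 0.92).astype(np.float32)
        x = (y + 0.1 * r.standard_normal((size, size))).astype(np.float32)
        out.append(PairedSample(x=x, y=y))
    return out


def test_single_sample_overfit():
    """Capacity sanity: one pair, patience off -> training NRMSE < 0.05."""
    cfg = NetConfig(arch="unet", depth=2, base_channels=8, batch_size=1,
                    lr=3e-3, max_epochs=200, patience=0, seed=0)
    model = build_network(cfg)
    sample = _toy_samples(1)[0]
    train(model, [sample])
    assert model.history[-1]["train_loss"] < 0.05
    assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]


def test_training_is_seeded_and_early_stops():
    samples = _toy_samples(8)
    val = _toy_samples(2, seed=5)

    def run():
        cfg = NetConfig(arch="unet", depth=2, base_channels=4, batch_size=4,
                        lr=1e-3, max_epochs=4, patience=2, seed=3)
        model = build_network(cfg)
        train(model, samples, val)
        return model

    h1 = run().history
    h2 = run().history
    assert h1 == h2  # bitwise-reproducible loss history
    assert len(h1) <= 4


def test_empty_dataset_rejected():
    cfg = NetConfig(arch="unet", depth=2, base_channels=4, seed=0)
    with pytest.raises(DegenerateInputError):
        train(build_network(cfg), [])


def test_gan_trains_one_epoch():
    cfg = NetConfig(arch="gan", depth=2, base_channels=4, batch_size=2,
                    lr=1e-3, max_epochs=1, seed=0)
    model = build_network(cfg)
    train(model, _toy_samples(4), _toy_samples(2, seed=9))
    assert len(model.history) == 1
    assert np.isfinite(model.history[0]["val_loss"])


def test_normalize_round_trip():
    v = rng.random((16, 16)) * 0.004
    n = normalize(v, 0.0, 0.005)
    np.testing.assert_allclose(denormalize(n, 0.0, 0.005), v, atol=1e-9)


def test_predict_and_denormalize_identity_affine():
    """A constant-zero network output maps back to the stored minimum."""
    cfg = NetConfig(arch="unet", depth=2, base_channels=4, seed=0)
    model = build_network(cfg)
    model.norm_params = {"x": (0.0, 1.0), "y": (0.002, 0.006)}
    for p in model.net.final.weight, model.net.final.bias:
        p.data[...] = 0.0
    out = predict_and_denormalize(model, rng.random((32, 32)))
    np.testing.assert_allclose(out, 0.002, atol=1e-7)


def test_predict_without_norm_params_rejected():
    cfg = NetConfig(arch="unet", depth=2, base_channels=4, seed=0)
    with pytest.raises(ConfigurationError):
        predict_and_denormalize(build_network(cfg), rng.random((32, 32)))


def test_checkpoint_round_trip(tmp_path):
    from oaflux.io import load_checkpoint, save_checkpoint
    cfg = NetConfig(arch="fd_unet", depth=2, base_channels=4, seed=1,
                    max_epochs=1, batch_size=2, lr=1e-3)
    model = build_network(cfg)
    model.norm_params = {"x": (0.0, 1.0), "y": (0.0, 0.004)}
    train(model, _toy_samples(2), None)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model)
    loaded = load_checkpoint(path)
    x = rng.random((32, 32)).astype(np.float32)
    np.testing.assert_allclose(loaded.predict(x), model.predict(x), atol=1e-6)
    assert loaded.norm_params == model.norm_params
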