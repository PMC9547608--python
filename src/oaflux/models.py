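"""Image-to-image fluence-correction networks.

Six convolutional architectures map a normalized time-reversal
reconstruction (plus, for the Y-variants, the normalized sinogram) to the
normalized absorption map: U-Net, fully dense (FD) U-Net, Y-Net, FD Y-Net,
deep residual U-Net, and a least-squares GAN whose generator is a U-Net.
All are encoder/decoder networks with skip concatenation, batch
normalization and ReLU, trained with Adam on the NRMSE loss

    NRMSE(y, yhat) = sqrt(mean((y - yhat)^2)) / sqrt(mean(y^2))

with early stopping on the validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, DegenerateInputError, ShapeError

ARCHITECTURES = ("unet", "fd_unet", "ynet", "fd_ynet", "resunet", "gan")


@dataclass
class NetConfig:
    """Hyperparameters of a fluence-correction network."""

    arch: str = "fd_unet"
    depth: int = 4
    base_channels: int = 32
    batch_size: int = 6
    lr: float = 1e-4
    max_epochs: int = 150
    patience: int = 12
    seed: int = 0
    dense_layers: int = 2
    gan_lambda: float = 100.0

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ConfigurationError(f"unknown arch {self.arch!r}; choose from {ARCHITECTURES}")
        if self.depth < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ConfigurationError("depth >= 1, batch_size >= 1, lr > 0 required")


@dataclass
class PairedSample:
    """One normalized training pair (plus optional normalized sinogram)."""

    x: np.ndarray
    y: np.ndarray
    s: np.ndarray | None = None
    norm_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.x.shape != self.y.shape:
            raise ShapeError(f"x {self.x.shape} and y {self.y.shape} must match")


def normalize(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise DegenerateInputError("normalization range must have hi > lo")
    return (v - lo) / (hi - lo)


def denormalize(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return v * (hi - lo) + lo


def nrmse_loss(y_ref: np.ndarray, y_hat: np.ndarray) -> float:
    """NRMSE of an estimate against a reference (reference in denominator)."""
    y_ref = np.asarray(y_ref, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y_ref.shape != y_hat.shape:
        raise ShapeError("shapes must match")
    denom = np.sqrt(np.mean(y_ref ** 2))
    if denom == 0:
        raise DegenerateInputError("NRMSE undefined for an all-zero reference")
    return float(np.sqrt(np.mean((y_ref - y_hat) ** 2)) / denom)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class ConvBlock(nn.Module):
    """Two 3x3 conv + BN + ReLU stages."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, rng=rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, rng=rng)
        self.b2 = nn.BatchNorm2d(cout)

    def __call__(self, x):
        x = nn.relu(self.b1(self.c1(x)))
        return nn.relu(self.b2(self.c2(x)))


class DenseBlock(nn.Module):
    """Dense block: each conv sees the concatenation of all previous outputs."""

    def __init__(self, cin, cout, rng, n_layers=2):
        if cout % n_layers:
            raise ConfigurationError("dense block output channels must divide n_layers")
        g = cout // n_layers
        self.convs, self.bns = [], []
        ch = cin
        for _ in range(n_layers):
            self.convs.append(nn.Conv2d(ch, g, rng=rng))
            self.bns.append(nn.BatchNorm2d(g))
            ch += g

    def __call__(self, x):
        feats = []
        inp = x
        for conv, bn in zip(self.convs, self.bns):
            out = nn.relu(bn(conv(inp)))
            feats.append(out)
            inp = nn.concat([inp, out]) if len(feats) < len(self.convs) else None
        return nn.concat(feats) if len(feats) > 1 else feats[0]


class ResBlock(nn.Module):
    """Residual unit: conv-BN-ReLU-conv-BN plus (projected) identity."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, rng=rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, rng=rng)
        self.b2 = nn.BatchNorm2d(cout)
        self.proj = nn.Conv2d(cin, cout, k=1, pad=0, rng=rng) if cin != cout else None

    def __call__(self, x):
        h = nn.relu(self.b1(self.c1(x)))
        h = self.b2(self.c2(h))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.relu(nn.add(h, shortcut))


class SinoEncoder(nn.Module):
    """Strided-conv encoder reducing the sinogram to the image bottleneck."""

    def __init__(self, depth, base, rng):
        self.convs, self.bns = [], []
        ch = 1
        for i in range(depth):
            cout = base * 2 ** i
            self.convs.append(nn.Conv2d(ch, cout, stride=2, rng=rng))
            self.bns.append(nn.BatchNorm2d(cout))
            ch = cout
        self.out_channels = ch

    def __call__(self, s):
        for conv, bn in zip(self.convs, self.bns):
            s = nn.relu(bn(conv(s)))
        return s


class UNet(nn.Module):
    """Generic encoder/decoder with skip concatenation.

    ``block`` selects the per-level feature block (plain, dense, residual);
    ``with_sino`` adds a second strided-conv encoder fused at the bottleneck.
    """

    def __init__(self, cfg: NetConfig, block: str = "plain", with_sino: bool = False):
        rng = np.random.default_rng([cfg.seed, 707])
        self.depth = cfg.depth
        self.with_sino = with_sino

        def make(cin, cout):
            if block == "dense":
                return DenseBlock(cin, cout, rng, n_layers=cfg.dense_layers)
            if block == "res":
                return ResBlock(cin, cout, rng)
            return ConvBlock(cin, cout, rng)

        chans = [cfg.base_channels * 2 ** i for i in range(cfg.depth + 1)]
        self.enc = []
        cin = 1
        for i in range(cfg.depth):
            self.enc.append(make(cin, chans[i]))
            cin = chans[i]
        if with_sino:
            self.sino_enc = SinoEncoder(cfg.depth, cfg.base_channels, rng)
            cin += self.sino_enc.out_channels
        self.bottleneck = make(cin, chans[cfg.depth])
        self.ups, self.dec = [], []
        for i in reversed(range(cfg.depth)):
            self.ups.append(nn.ConvTranspose2d(chans[i + 1], chans[i], rng=rng))
            self.dec.append(make(2 * chans[i], chans[i]))
        self.final = nn.Conv2d(chans[0], 1, k=1, pad=0, rng=rng)

    def __call__(self, x, s=None):
        skips = []
        h = x
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = nn.maxpool2d(h)
        if self.with_sino:
            if s is None:
                raise ConfigurationError("this architecture requires a sinogram input")
            h = nn.concat([h, self.sino_enc(s)])
        h = self.bottleneck(h)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up(h)
            h = blk(nn.concat([skip, h]))
        return self.final(h)


class PatchDiscriminator(nn.Module):
    """Small strided-conv least-squares patch discriminator on (x, y) pairs."""

    def __init__(self, cfg: NetConfig):
        rng = np.random.default_rng([cfg.seed, 808])
        base = cfg.base_channels
        self.c1 = nn.Conv2d(2, base, stride=2, rng=rng)
        self.c2 = nn.Conv2d(base, 2 * base, stride=2, rng=rng)
        self.b2 = nn.BatchNorm2d(2 * base)
        self.c3 = nn.Conv2d(2 * base, 1, k=3, rng=rng)

    def __call__(self, x, y):
        h = nn.relu(self.c1(nn.concat([x, y])), slope=0.2)
        h = nn.relu(self.b2(self.c2(h)), slope=0.2)
        return self.c3(h)


@dataclass
class TrainedModel:
    """A network plus its config, normalization convention and history."""

    config: NetConfig
    net: UNet
    discriminator: PatchDiscriminator | None = None
    history: list = field(default_factory=list)
    norm_params: dict = field(default_factory=dict)

    @property
    def arch(self) -> str:
        return self.config.arch

    def predict(self, x: np.ndarray, s: np.ndarray | None = None) -> np.ndarray:
        """Forward pass in eval mode on a batch or single normalized image."""
        single = x.ndim == 2
        xb = x[None] if single else x
        _check_divisible(xb.shape[-2:], self.config.depth)
        self.net.set_training(False)
        xt = nn.Tensor(xb[:, None].astype(np.float32))
        st = None
        if self.net.with_sino:
            sb = s[None] if (s is not None and s.ndim == 2) else s
            if sb is None:
                raise ConfigurationError("Y-variant prediction requires a sinogram")
            st = nn.Tensor(sb[:, None].astype(np.float32))
        out = self.net(xt, st).data[:, 0]
        return out[0] if single else out


def _check_divisible(shape, depth):
    for d in shape:
        if d % (2 ** depth):
            raise ShapeError(
                f"input shape {shape} not divisible by 2^{depth}; pad to a multiple "
                f"of {2 ** depth}")


def build_network(cfg: NetConfig) -> TrainedModel:
    """Instantiate an untrained model with seeded weight initialization."""
    block = {"unet": "plain", "fd_unet": "dense", "ynet": "plain",
             "fd_ynet": "dense", "resunet": "res", "gan": "plain"}[cfg.arch]
    with_sino = cfg.arch in ("ynet", "fd_ynet")
    net = UNet(cfg, block=block, with_sino=with_sino)
    disc = PatchDiscriminator(cfg) if cfg.arch == "gan" else None
    return TrainedModel(config=cfg, net=net, discriminator=disc)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _stack(samples, idx, with_sino):
    x = np.stack([samples[i].x for i in idx])[:, None].astype(np.float32)
    y = np.stack([samples[i].y for i in idx])[:, None].astype(np.float32)
    s = None
    if with_sino:
        s = np.stack([samples[i].s for i in idx])[:, None].astype(np.float32)
    return x, y, s


def _eval_loss(model, samples):
    model.net.set_training(False)
    losses = []
    bs = model.config.batch_size
    for i in range(0, len(samples), bs):
        idx = range(i, min(i + bs, len(samples)))
        x, y, s = _stack(samples, idx, model.net.with_sino)
        out = model.net(nn.Tensor(x), nn.Tensor(s) if s is not None else None)
        losses.append(nrmse_loss(y, out.data) * len(x))
    return float(np.sum(losses) / len(samples))


def train(model: TrainedModel, train_samples, val_samples=None,
          verbose: bool = False) -> TrainedModel:
    """Train a model in place with Adam + NRMSE and early stopping.

    Stops when the validation loss has not improved for ``patience`` epochs
    (or at ``max_epochs``); the best-validation weights are restored.  With
    no validation set the training loss drives the stopping rule.
    """
    if not train_samples:
        raise DegenerateInputError("empty training set")
    cfg = model.config
    _check_divisible(train_samples[0].x.shape, cfg.depth)
    rng = np.random.default_rng([cfg.seed, 909])
    opt = nn.Adam(model.net.parameters(), lr=cfg.lr)
    is_gan = cfg.arch == "gan"
    if is_gan:
        opt_d = nn.Adam(model.discriminator.parameters(), lr=cfg.lr)
    best_loss, best_state, best_epoch = np.inf, None, 0

    for epoch in range(cfg.max_epochs):
        model.net.set_training(True)
        epoch_losses = []
        for idx in _batches(len(train_samples), cfg.batch_size, rng):
            x, y, s = _stack(train_samples, idx, model.net.with_sino)
            xt = nn.Tensor(x)
            st = nn.Tensor(s) if s is not None else None
            if is_gan:
                # discriminator: real pairs -> 1, generated pairs -> 0
                model.discriminator.set_training(True)
                fake = model.net(xt, st)
                d_real = model.discriminator(xt, nn.Tensor(y))
                loss_dr = nn.mse_loss(d_real, np.ones_like(d_real.data))
                opt_d.zero_grad()
                loss_dr.backward()
                d_fake = model.discriminator(xt, nn.Tensor(fake.data))
                loss_df = nn.mse_loss(d_fake, np.zeros_like(d_fake.data))
                loss_df.backward()
                opt_d.step()
                # generator: fool the discriminator + NRMSE fidelity
                fake = model.net(xt, st)
                d_out = model.discriminator(xt, fake)
                adv = nn.mse_loss(d_out, np.ones_like(d_out.data))
                fid = nn.nrmse_loss_t(fake, y)
                loss = nn.Tensor(adv.data + cfg.gan_lambda * fid.data,
                                 parents=(adv, fid))
                a, f = adv, fid

                def gan_grad(g, a=a, f=f, lam=cfg.gan_lambda):
                    a._accum(g)
                    f._accum(lam * g)

                loss.grad_fn = gan_grad
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(fid.item())
            else:
                out = model.net(xt, st)
                loss = nn.nrmse_loss_t(out, y)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            if np.isnan(epoch_losses[-1]):
                raise ConfigurationError("training diverged (NaN loss)")
        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(model, val_samples) if val_samples else train_loss
        model.history.append({"epoch": epoch, "train_loss": train_loss,
                              "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch = val_loss, epoch
            best_state = [a.copy() for a in model.net.state_arrays()]
        elif cfg.patience and epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.net.load_state_arrays(best_state)
    return model


def predict_and_denormalize(model: TrainedModel, x: np.ndarray,
                            norm: dict | None = None,
                            s: np.ndarray | None = None) -> np.ndarray:
    """Apply a trained model to a raw (unnormalized) image and map the output
    back to physical absorption units through the stored (min, max)."""
    norm = norm or model.norm_params
    if not norm or "x" not in norm or "y" not in norm:
        raise ConfigurationError("normalization parameters missing")
    xn = normalize(np.asarray(x, dtype=np.float64), *norm["x"])
    sn = None
    if model.net.with_sino:
        if s is None:
            raise ConfigurationError("Y-variant prediction requires a sinogram")
        sn = normalize(np.asarray(s, dtype=np.float64), *norm["s"])
    out = model.predict(xn.astype(np.float32), sn.astype(np.float32) if sn is not None else None)
    return denormalize(out.astype(np.float64), *norm["y"])
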