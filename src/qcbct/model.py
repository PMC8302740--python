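"""Network architectures and loss functions of the hybrid mapping model.

The model family: a cycle-consistent adversarial pair (two ResNet
generators with nine residual blocks, two 70x70 patch discriminators) that
learns the CBCT<->QCT intensity mapping, followed by a two-channel U-Net
that fuses the raw CBCT slice with the generator output (CYC_CBCT) into the
final BMD image. Losses:

    L_ADV(G)  = mean(D(real)^2) + mean((D(G(x)) - 1)^2)
    L_CYC     = |G_yx(G_xy(x)) - x| + |G_xy(G_yx(y)) - y|      (means)
    L_GAN     = L_ADV(G_xy) + L_ADV(G_yx) + lambda * L_CYC,    lambda = 10
    L_UNet    = (1 - alpha) * MAD + alpha * (1 - SSIM),        alpha = 0.6

with SSIM computed globally (single window) from masked means, variances
and covariance. Images are normalized from a fixed intensity window to
[-1, 1] before entering the networks.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    LeakyReLU,
    MaxPool2d,
    ReLU,
    ResidualBlock,
    Sequential,
    Tanh,
)

#: fixed intensity window mapped linearly onto [-1, 1]
DEFAULT_WINDOW = (-1000.0, 3000.0)


def normalize(v: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    return 2.0 * (np.asarray(v, dtype=np.float64) - lo) / (hi - lo) - 1.0


def denormalize(v: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    return (np.asarray(v, dtype=np.float64) + 1.0) * (hi - lo) / 2.0 + lo


@dataclasses.dataclass
class LossWeights:
    """Loss hyperparameters; stabilizers follow C1=(0.01 L)^2, C2=(0.03 L)^2
    with L the dynamic range of the normalized scale (2)."""

    lambda_cyc: float = 10.0
    alpha_ssim: float = 0.6
    c1: float = (0.01 * 2.0) ** 2
    c2: float = (0.03 * 2.0) ** 2
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.lambda_cyc <= 0:
            raise ValueError("lambda_cyc must be > 0")
        if not (0.0 <= self.alpha_ssim <= 1.0):
            raise ValueError("alpha_ssim must be in [0, 1]")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM stabilizers must be > 0")


@dataclasses.dataclass
class GeneratorSpec:
    """ResNet generator: 7x7 stem, two stride-2 3x3 downsampling convs,
    ``n_residual_blocks`` channel-preserving blocks, two transposed-conv
    upsamplings, 7x7 head, tanh output; batch norm + ReLU throughout."""

    n_residual_blocks: int = 9
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_residual_blocks < 1 or self.base_channels < 1:
            raise ValueError("invalid generator spec")


@dataclasses.dataclass
class DiscriminatorSpec:
    """PatchGAN with a 70x70 receptive field: 4x4 convs, three stride-2 and
    two stride-1 stages, batch norm + leaky ReLU, scalar score map out."""

    base_channels: int = 64
    in_channels: int = 1


@dataclasses.dataclass
class UNetSpec:
    """Two-channel U-Net: 4 resolution levels with skip connections,
    3x3 convs + batch norm + ReLU, max-pool down, transposed-conv up."""

    in_channels: int = 2
    base_channels: int = 64
    levels: int = 4
    out_channels: int = 1


def build_generator(spec: GeneratorSpec, rng: Optional[np.random.Generator] = None) -> Sequential:
    rng = rng or np.random.default_rng(0)
    b = spec.base_channels
    layers: list[Layer] = [
        Conv2d(spec.in_channels, b, 7, pad=3, rng=rng), BatchNorm2d(b), ReLU(),
        Conv2d(b, 2 * b, 3, stride=2, pad=1, rng=rng), BatchNorm2d(2 * b), ReLU(),
        Conv2d(2 * b, 4 * b, 3, stride=2, pad=1, rng=rng), BatchNorm2d(4 * b), ReLU(),
    ]
    layers += [ResidualBlock(4 * b, rng=rng) for _ in range(spec.n_residual_blocks)]
    layers += [
        ConvTranspose2d(4 * b, 2 * b, 3, stride=2, pad=1, output_padding=1, rng=rng),
        BatchNorm2d(2 * b), ReLU(),
        ConvTranspose2d(2 * b, b, 3, stride=2, pad=1, output_padding=1, rng=rng),
        BatchNorm2d(b), ReLU(),
        Conv2d(b, spec.out_channels, 7, pad=3, rng=rng), Tanh(),
    ]
    return Sequential(*layers)


def build_discriminator(spec: DiscriminatorSpec, rng: Optional[np.random.Generator] = None) -> Sequential:
    rng = rng or np.random.default_rng(0)
    b = spec.base_channels
    return Sequential(
        Conv2d(spec.in_channels, b, 4, stride=2, pad=1, rng=rng), LeakyReLU(0.2),
        Conv2d(b, 2 * b, 4, stride=2, pad=1, rng=rng), BatchNorm2d(2 * b), LeakyReLU(0.2),
        Conv2d(2 * b, 4 * b, 4, stride=2, pad=1, rng=rng), BatchNorm2d(4 * b), LeakyReLU(0.2),
        Conv2d(4 * b, 8 * b, 4, stride=1, pad=1, rng=rng), BatchNorm2d(8 * b), LeakyReLU(0.2),
        Conv2d(8 * b, 1, 4, stride=1, pad=1, rng=rng),
    )


class UNet(Layer):
    """U-shaped encoder-decoder with skip concatenation at every level."""

    def __init__(self, spec: UNetSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        b = spec.base_channels

        def block(cin, cout):
            return Sequential(
                Conv2d(cin, cout, 3, pad=1, rng=rng), BatchNorm2d(cout), ReLU(),
                Conv2d(cout, cout, 3, pad=1, rng=rng), BatchNorm2d(cout), ReLU(),
            )

        chans = [b * 2**i for i in range(spec.levels)]  # encoder widths
        self.enc = []
        cin = spec.in_channels
        for c in chans:
            self.enc.append(block(cin, c))
            cin = c
        self.pools = [MaxPool2d() for _ in chans]
        self.bottleneck = block(chans[-1], 2 * chans[-1])
        self.ups = []
        self.dec = []
        cin = 2 * chans[-1]
        for c in reversed(chans):
            self.ups.append(ConvTranspose2d(cin, c, 3, stride=2, pad=1, output_padding=1, rng=rng))
            self.dec.append(block(2 * c, c))
            cin = c
        self.head = Conv2d(chans[0], spec.out_channels, 3, pad=1, rng=rng)
        self._all = self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.head]

    def forward(self, x, train=True):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"U-Net expects {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        if x.shape[2] % 2**self.spec.levels or x.shape[3] % 2**self.spec.levels:
            raise ValueError(f"spatial dims must be divisible by {2**self.spec.levels}")
        skips, ecaches, pcaches = [], [], []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h, c = enc.forward(h, train)
            skips.append(h)
            ecaches.append(c)
            h, pc = pool.forward(h, train)
            pcaches.append(pc)
        h, bcache = self.bottleneck.forward(h, train)
        ucaches, dcaches, splits = [], [], []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h, uc = up.forward(h, train)
            ucaches.append(uc)
            splits.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h, dc = dec.forward(h, train)
            dcaches.append(dc)
        y, hcache = self.head.forward(h, train)
        return y, (ecaches, pcaches, bcache, ucaches, dcaches, hcache)

    def backward(self, dy, cache):
        ecaches, pcaches, bcache, ucaches, dcaches, hcache = cache
        dh = self.head.backward(dy, hcache)
        dskips = []
        for up, dec, uc, dc, nskip in zip(
            reversed(self.ups), reversed(self.dec), reversed(ucaches), reversed(dcaches),
            [self.enc[i].children[-3].out_ch for i in range(len(self.enc))],
        ):
            dcat = dec.backward(dh, dc)
            dskip, dup = dcat[:, :nskip], dcat[:, nskip:]
            dskips.append(dskip)
            dh = up.backward(dup, uc)
        dh = self.bottleneck.backward(dh, bcache)
        # dskips[i] is the gradient for enc[i]'s skip (collected bottom-up)
        dx = dh
        for enc, pool, ec, pc, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(ecaches), reversed(pcaches),
            reversed(dskips),
        ):
            dx = pool.backward(dx, pc)
            dx = dx + dskip
            dx = enc.backward(dx, ec)
        return dx

    def zero_grad(self):
        for lay in self._all:
            lay.zero_grad()

    def layers(self):
        out = []
        for lay in self._all:
            out.extend(lay.layers())
        return out


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------

def adversarial_loss_g(d_real_out: np.ndarray, d_fake_out: np.ndarray) -> float:
    """Composite least-squares adversarial loss, in its published composite form:
    mean(D(real)^2) + mean((D(fake) - 1)^2)."""
    dr = np.asarray(d_real_out, dtype=np.float64)
    df = np.asarray(d_fake_out, dtype=np.float64)
    return float(np.mean(dr**2) + np.mean((df - 1.0) ** 2))


def cycle_consistency_loss(
    x: np.ndarray,
    y: np.ndarray,
    g_xy: Callable[[np.ndarray], np.ndarray],
    g_yx: Callable[[np.ndarray], np.ndarray],
) -> float:
    """Mean absolute reconstruction error of both cycles."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(np.abs(g_yx(g_xy(x)) - x)) + np.mean(np.abs(g_xy(g_yx(y)) - y)))


def total_gan_loss(l_adv_fwd: float, l_adv_bwd: float, l_cyc: float, weights: LossWeights) -> float:
    for v in (l_adv_fwd, l_adv_bwd, l_cyc):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return float(l_adv_fwd + l_adv_bwd + weights.lambda_cyc * l_cyc)


def _masked_flat(pred, target, mask):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred/target shapes differ")
    if mask is None:
        m = np.ones(pred.shape, dtype=bool)
    else:
        m = np.asarray(mask).astype(bool)
    return pred, target, m


def _ssim_terms(p, t, c1, c2):
    n = p.size
    mu_p, mu_t = p.mean(), t.mean()
    var_p, var_t = p.var(), t.var()
    cov = ((p - mu_p) * (t - mu_t)).mean()
    a1 = 2 * mu_p * mu_t + c1
    a2 = 2 * cov + c2
    b1 = mu_p**2 + mu_t**2 + c1
    b2 = var_p + var_t + c2
    return n, mu_p, mu_t, a1, a2, b1, b2


def unet_combined_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: LossWeights = LossWeights(),
    mask: Optional[np.ndarray] = None,
) -> float:
    """(1 - alpha) * MAD + alpha * (1 - SSIM) over in-mask pixels,
    on whatever scale pred/target are supplied in."""
    pred, target, m = _masked_flat(pred, target, mask)
    p, t = pred[m], target[m]
    mad = np.mean(np.abs(p - t))
    _, _, _, a1, a2, b1, b2 = _ssim_terms(p, t, weights.c1, weights.c2)
    ssim = (a1 * a2) / (b1 * b2)
    a = weights.alpha_ssim
    return float((1 - a) * mad + a * (1 - ssim))


def unet_loss_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    weights: LossWeights = LossWeights(),
    mask: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Combined loss plus its analytic gradient w.r.t. ``pred``
    (zero outside the mask); drives the U-Net training step."""
    pred, target, m = _masked_flat(pred, target, mask)
    p, t = pred[m], target[m]
    n, mu_p, mu_t, a1, a2, b1, b2 = _ssim_terms(p, t, weights.c1, weights.c2)
    ssim = (a1 * a2) / (b1 * b2)
    mad = np.mean(np.abs(p - t))
    a = weights.alpha_ssim
    loss = (1 - a) * mad + a * (1 - ssim)
    dmad = np.sign(p - t) / n
    # dSSIM/dp_i from the partials of means/variances/covariance
    dssim = ((2 * mu_t / n) * a2 + a1 * (2 * (t - mu_t) / n)) / (b1 * b2) - ssim * (
        (2 * mu_p / n) * b2 + b1 * (2 * (p - mu_p) / n)
    ) / (b1 * b2)
    gflat = (1 - a) * dmad - a * dssim
    grad = np.zeros_like(pred)
    grad[m] = gflat
    return float(loss), grad


# thin forward wrappers --------------------------------------------------

def generator_forward(net: Sequential, x: np.ndarray, train: bool = False) -> np.ndarray:
    y, _ = net.forward(_check_4d(x, 1), train)
    return y


def discriminator_forward(net: Sequential, x: np.ndarray, train: bool = False) -> np.ndarray:
    y, _ = net.forward(_check_4d(x, 1), train)
    return y


def unet_forward(net: UNet, x: np.ndarray, train: bool = False) -> np.ndarray:
    y, _ = net.forward(_check_4d(x, net.spec.in_channels), train)
    return y


def _check_4d(x: np.ndarray, channels: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("expected (batch, channels, H, W)")
    if x.shape[1] != channels:
        raise ValueError(f"expected {channels} channels, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return x
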