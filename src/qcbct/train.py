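"""Two-stage training of the hybrid mapping model, plus baselines.

Stage 1 trains the cycle-consistent adversarial pair on paired, masked,
normalized axial slices (aligned batches). Stage 2 freezes the
CBCT->QCT generator, synthesizes its output (CYC_CBCT) for every slice,
and trains the two-channel U-Net on (CBCT, CYC_CBCT) -> QCT with the
combined MAD+SSIM loss. Baselines share the same settings: the
generator alone (Cycle-GAN-only) and a single-channel U-Net.

All randomness flows from ``TrainConfig.seed``; training is fully
deterministic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import nn
from .model import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossWeights,
    UNet,
    UNetSpec,
    adversarial_loss_g,
    build_discriminator,
    build_generator,
    denormalize,
    normalize,
    total_gan_loss,
    unet_loss_and_grad,
)


@dataclasses.dataclass
class TrainConfig:
    """Published defaults: Adam, batch 8, 200 epochs per stage; generator
    lr 2e-4 (constant 100 epochs then linear decay to 0), U-Net lr 1e-4
    with beta1 = 0.9. Reduced-scale runs override epochs, widths and
    learning rates (see docs/methods.md)."""

    batch_size: int = 8
    epochs: int = 200
    unet_epochs: Optional[int] = None
    cyclegan_lr: float = 2e-4
    unet_lr: float = 1e-4
    adam_beta1: float = 0.9
    seed: int = 0
    val_fraction: float = 0.2
    device: str = "cpu"
    generator_base_channels: int = 64
    discriminator_base_channels: int = 64
    unet_base_channels: int = 64
    n_residual_blocks: int = 9
    adv_loss: str = "lsgan"  # "lsgan" (optimization split) or "composite" (published form)
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.cyclegan_lr <= 0 or self.unet_lr <= 0:
            raise ValueError("learning rates must be > 0")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val fraction must be in (0, 1)")
        if self.adv_loss not in ("lsgan", "composite"):
            raise ValueError("adv_loss must be 'lsgan' or 'composite'")
        if self.unet_epochs is None:
            self.unet_epochs = self.epochs


@dataclasses.dataclass
class NetworkBundle:
    """Trained parameter sets of the full hybrid model."""

    g_cbct_to_qct: nn.Sequential
    g_qct_to_cbct: nn.Sequential
    d_qct: nn.Sequential
    d_cbct: nn.Sequential
    unet: UNet
    window: tuple[float, float]

    def validate(self) -> None:
        for name in ("g_cbct_to_qct", "g_qct_to_cbct", "unet"):
            if getattr(self, name) is None:
                raise ValueError(f"incomplete bundle: missing {name}")


def lr_schedule_cyclegan(epoch: int, config: TrainConfig) -> float:
    """Constant for the first half of training, then linear decay to zero."""
    if not (1 <= epoch <= config.epochs):
        raise ValueError(f"epoch {epoch} outside [1, {config.epochs}]")
    half = config.epochs // 2
    if epoch <= half or half == config.epochs:
        return config.cyclegan_lr
    return config.cyclegan_lr * (config.epochs - epoch) / (config.epochs - half)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _mean_sq(x: np.ndarray) -> float:
    return float(np.mean(x**2))


def train_cyclegan(
    cbct_slices: np.ndarray,
    qct_slices: np.ndarray,
    config: TrainConfig,
) -> tuple[nn.Sequential, nn.Sequential, dict]:
    """Train the adversarial pair on aligned (CBCT, QCT) normalized slices.

    Inputs are (N, 1, H, W) arrays on the [-1, 1] scale. Returns both
    generators and a per-epoch history of every loss component, including
    the published composite adversarial/total losses.
    """
    cbct = np.asarray(cbct_slices, dtype=np.float64)
    qct = np.asarray(qct_slices, dtype=np.float64)
    if cbct.ndim != 4 or cbct.shape != qct.shape:
        raise ValueError("expected matching (N,1,H,W) slice arrays")
    if cbct.shape[0] == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    g_spec = GeneratorSpec(
        n_residual_blocks=config.n_residual_blocks, base_channels=config.generator_base_channels
    )
    d_spec = DiscriminatorSpec(base_channels=config.discriminator_base_channels)
    g_c2q = build_generator(g_spec, rng)
    g_q2c = build_generator(g_spec, rng)
    d_q = build_discriminator(d_spec, rng)
    d_c = build_discriminator(d_spec, rng)
    opt_g = nn.Adam([g_c2q, g_q2c], lr=config.cyclegan_lr, beta1=config.adam_beta1)
    opt_dq = nn.Adam([d_q], lr=config.cyclegan_lr, beta1=config.adam_beta1)
    opt_dc = nn.Adam([d_c], lr=config.cyclegan_lr, beta1=config.adam_beta1)
    lam = config.weights.lambda_cyc
    history: dict[str, list[float]] = {
        "lr": [], "l_adv_fwd": [], "l_adv_bwd": [], "l_cyc": [], "total_gan_loss": [],
        "d_qct_loss": [], "d_cbct_loss": [],
    }
    for epoch in range(1, config.epochs + 1):
        lr = lr_schedule_cyclegan(epoch, config)
        opt_g.lr = opt_dq.lr = opt_dc.lr = lr
        acc = {k: 0.0 for k in history}
        nb = 0
        for idx in _batches(cbct.shape[0], config.batch_size, rng):
            x, y = cbct[idx], qct[idx]
            # ---- generator update -------------------------------------
            opt_g.zero_grad()
            fake_q, c_g1 = g_c2q.forward(x, True)
            rec_c, c_g2 = g_q2c.forward(fake_q, True)
            fake_c, c_g3 = g_q2c.forward(y, True)
            rec_q, c_g4 = g_c2q.forward(fake_c, True)

            dq_fake, c_dq = d_q.forward(fake_q, True)
            dc_fake, c_dc = d_c.forward(fake_c, True)
            # generator gradient of the least-squares fake term (identical
            # under both adv_loss conventions)
            d_fake_q = d_q.backward(2.0 * (dq_fake - 1.0) / dq_fake.size, c_dq)
            d_fake_c = d_c.backward(2.0 * (dc_fake - 1.0) / dc_fake.size, c_dc)
            d_q.zero_grad()  # discriminators are not stepped here
            d_c.zero_grad()

            d_fake_q = d_fake_q + g_q2c.backward(lam * np.sign(rec_c - x) / rec_c.size, c_g2)
            g_c2q.backward(d_fake_q, c_g1)
            d_fake_c = d_fake_c + g_c2q.backward(lam * np.sign(rec_q - y) / rec_q.size, c_g4)
            g_q2c.backward(d_fake_c, c_g3)
            opt_g.step()

            # ---- discriminator updates --------------------------------
            fq, fc = fake_q, fake_c  # detached: plain arrays
            for disc, opt, real, fake, key in (
                (d_q, opt_dq, y, fq, "d_qct_loss"),
                (d_c, opt_dc, x, fc, "d_cbct_loss"),
            ):
                opt.zero_grad()
                out_r, c_r = disc.forward(real, True)
                out_f, c_f = disc.forward(fake, True)
                if config.adv_loss == "lsgan":
                    d_loss = 0.5 * (_mean_sq(out_r - 1.0) + _mean_sq(out_f))
                    disc.backward((out_r - 1.0) / out_r.size, c_r)
                    disc.backward(out_f / out_f.size, c_f)
                else:  # the published composite, taken literally
                    d_loss = _mean_sq(out_r) + _mean_sq(out_f - 1.0)
                    disc.backward(2.0 * out_r / out_r.size, c_r)
                    disc.backward(2.0 * (out_f - 1.0) / out_f.size, c_f)
                opt.step()
                acc[key] += d_loss
                if key == "d_qct_loss":
                    out_r_q, out_f_q = out_r, out_f
                else:
                    out_r_c, out_f_c = out_r, out_f

            # published composite losses, logged verbatim
            l_adv_fwd = adversarial_loss_g(out_r_q, out_f_q)
            l_adv_bwd = adversarial_loss_g(out_r_c, out_f_c)
            l_cyc = float(np.mean(np.abs(rec_c - x)) + np.mean(np.abs(rec_q - y)))
            acc["l_adv_fwd"] += l_adv_fwd
            acc["l_adv_bwd"] += l_adv_bwd
            acc["l_cyc"] += l_cyc
            acc["total_gan_loss"] += total_gan_loss(l_adv_fwd, l_adv_bwd, l_cyc, config.weights)
            nb += 1
        for k in acc:
            history[k].append(acc[k] / nb if k != "lr" else lr)
    _recalibrate_batchnorm([g_c2q, g_q2c], [cbct, qct], config.batch_size)
    return g_c2q, g_q2c, history


def _recalibrate_batchnorm(nets, datasets, batch_size: int) -> None:
    """Replace batch-norm running stats by the exact average of batch
    statistics over the training data (cumulative-average momentum)."""
    for net, data in zip(nets, datasets):
        bns = [lay for lay in net.layers() if isinstance(lay, nn.BatchNorm2d)]
        for i, start in enumerate(range(0, data.shape[0], batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            net.forward(data[start : start + batch_size], True)
        for bn in bns:
            bn.momentum = 0.1


def _infer_forward(net, x: np.ndarray, batch_size: int, feature_stats: str) -> np.ndarray:
    """Inference forward pass.

    ``feature_stats="image"`` (default for the translation networks)
    normalizes every batch-norm layer by the statistics of the single slice
    being mapped — the usual convention for image-translation models, and
    robust when the test intensity distribution drifts from training.
    ``"running"`` uses the frozen running averages instead. Both are
    deterministic and leave the network state untouched.
    """
    if feature_stats not in ("image", "running"):
        raise ValueError("feature_stats must be 'image' or 'running'")
    outs = []
    if feature_stats == "running":
        for i in range(0, x.shape[0], batch_size):
            y, _ = net.forward(x[i : i + batch_size], False)
            outs.append(y)
        return np.concatenate(outs, axis=0)
    bns = [lay for lay in net.layers() if isinstance(lay, nn.BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.0  # use per-image stats without touching running ones
    try:
        for i in range(x.shape[0]):
            y, _ = net.forward(x[i : i + 1], True)
            outs.append(y)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m
    return np.concatenate(outs, axis=0)


def synthesize_cyc(
    cbct_slices: np.ndarray,
    g_cbct_to_qct: nn.Sequential,
    window: tuple[float, float] | None = None,
    batch_size: int = 8,
    feature_stats: str = "image",
) -> np.ndarray:
    """Run the CBCT->QCT generator over slices.

    If ``window`` is given, slices are in intensity units and the output is
    denormalized back to intensity units; otherwise slices are assumed
    already normalized and the output stays normalized.
    """
    x = np.asarray(cbct_slices, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[:, None]
    xin = normalize(x, window) if window is not None else x
    out = _infer_forward(g_cbct_to_qct, xin, batch_size, feature_stats)
    if window is not None:
        out = denormalize(out, window)
    return out[:, 0] if squeeze else out


def train_unet(
    two_channel_slices: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig,
    masks: Optional[np.ndarray] = None,
    in_channels: int = 2,
) -> tuple[UNet, dict]:
    """Train the restoration U-Net with the combined MAD+SSIM loss.

    ``two_channel_slices`` is (N, C, H, W) normalized input (C must match
    ``in_channels``), ``targets`` is (N, 1, H, W) normalized QCT, ``masks``
    an optional (N, 1, H, W) binary anatomy mask restricting the loss.
    """
    x = np.asarray(two_channel_slices, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if x.ndim != 4 or x.shape[1] != in_channels:
        raise ValueError(f"expected (N,{in_channels},H,W) input")
    if y.shape != (x.shape[0], 1, x.shape[2], x.shape[3]):
        raise ValueError("targets incongruent with inputs")
    if masks is not None:
        masks = np.asarray(masks).astype(bool)
        if masks.shape != y.shape:
            raise ValueError("masks incongruent with targets")
    rng = np.random.default_rng(config.seed + 1)
    net = UNet(UNetSpec(in_channels=in_channels, base_channels=config.unet_base_channels), rng)
    opt = nn.Adam([net], lr=config.unet_lr, beta1=config.adam_beta1)
    history: dict[str, list[float]] = {"unet_loss": []}
    epochs = config.unet_epochs or config.epochs
    for _epoch in range(epochs):
        acc, nb = 0.0, 0
        for idx in _batches(x.shape[0], config.batch_size, rng):
            xb, yb = x[idx], y[idx]
            mb = masks[idx] if masks is not None else None
            opt.zero_grad()
            pred, cache = net.forward(xb, True)
            loss, grad = unet_loss_and_grad(pred, yb, config.weights, mb)
            net.backward(grad, cache)
            opt.step()
            acc += loss
            nb += 1
        history["unet_loss"].append(acc / nb)
    # recalibrate running stats for eval-mode inference
    bns = [lay for lay in net.layers() if isinstance(lay, nn.BatchNorm2d)]
    for i, start in enumerate(range(0, x.shape[0], config.batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        net.forward(x[start : start + config.batch_size], True)
    for bn in bns:
        bn.momentum = 0.1
    return net, history


def run_qcbctnet(
    cbct_slices: np.ndarray,
    bundle: NetworkBundle,
    batch_size: int = 8,
    feature_stats: str = "image",
) -> np.ndarray:
    """Full hybrid inference: CBCT slices (intensity units) -> BMD slices.

    The U-Net receives the normalized CBCT slice and the generator output
    as its two channels; the result is denormalized to mg/cm3.
    """
    bundle.validate()
    x = np.asarray(cbct_slices, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[:, None]
    xn = normalize(x, bundle.window)
    cyc = synthesize_cyc(
        xn, bundle.g_cbct_to_qct, window=None, batch_size=batch_size, feature_stats=feature_stats
    )
    inp = np.concatenate([xn, cyc], axis=1)
    out = denormalize(_infer_forward(bundle.unet, inp, batch_size, feature_stats), bundle.window)
    return out[:, 0] if squeeze else out


# --- checkpointing ---------------------------------------------------------

def save_bundle(bundle: NetworkBundle, out_dir: str | Path, config: TrainConfig) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nets = [bundle.g_cbct_to_qct, bundle.g_qct_to_cbct, bundle.d_qct, bundle.d_cbct, bundle.unet]
    flat = {}
    counts = {}
    for ni, net in enumerate(nets):
        if net is None:
            continue
        states = nn.get_state([net])
        counts[ni] = len(states)
        for li, d in enumerate(states):
            for k, v in d.items():
                flat[f"n{ni}_l{li}_{k}"] = v
    np.savez(out_dir / "weights.npz", **flat)
    sidecar = {
        "present": [net is not None for net in nets],
        "layer_counts": {str(k): v for k, v in counts.items()},
        "window": list(bundle.window),
        "generator_base_channels": config.generator_base_channels,
        "discriminator_base_channels": config.discriminator_base_channels,
        "unet_base_channels": config.unet_base_channels,
        "n_residual_blocks": config.n_residual_blocks,
    }
    with open(out_dir / "bundle.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_bundle(out_dir: str | Path) -> NetworkBundle:
    out_dir = Path(out_dir)
    with open(out_dir / "bundle.yaml") as fh:
        side = yaml.safe_load(fh)
    rng = np.random.default_rng(0)
    g_spec = GeneratorSpec(
        n_residual_blocks=side["n_residual_blocks"],
        base_channels=side["generator_base_channels"],
    )
    d_spec = DiscriminatorSpec(base_channels=side["discriminator_base_channels"])
    nets = [
        build_generator(g_spec, rng),
        build_generator(g_spec, rng),
        build_discriminator(d_spec, rng),
        build_discriminator(d_spec, rng),
        UNet(UNetSpec(base_channels=side["unet_base_channels"]), rng),
    ]
    data = np.load(out_dir / "weights.npz")
    present = side.get("present", [True] * 5)
    for ni, net in enumerate(nets):
        if not present[ni]:
            nets[ni] = None
            continue
        state = []
        for li in range(side["layer_counts"][str(ni)]):
            prefix = f"n{ni}_l{li}_"
            state.append({k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)})
        nn.set_state([net], state)
    return NetworkBundle(*nets, window=tuple(side["window"]))
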