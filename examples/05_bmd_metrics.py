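"""The BMD evaluation suite on a degraded/reference volume pair.

Computes every agreement measure used to judge a quantitative CBCT: MAD,
PSNR, global SSIM, NCC, SNU over reference ROIs, the voxel-intensity
regression slope, Bland-Altman limits, and a dental-arch profile
correlation.
"""

import numpy as np

from qcbct import evaluate as ev
from qcbct.phantom import DegradationSpec, build_skull_phantom_spec, generate_qct_volume, degrade

vol = generate_qct_volume(build_skull_phantom_spec(n_slices=8, size=64, seed=9))
test = degrade(vol.copy_with(unit="HU"), DegradationSpec(gain=1.05, offset=20.0, noise_sigma=30.0,
                                                         nonlinearity_gamma=1.0, n_streaks=0,
                                                         shading_amplitude=0.08, seed=4))
mask = vol.data > 0

print(f"MAD   {ev.mad(vol.data, test.data, mask):8.2f} mg/cm3   (0 = perfect)")
print(f"PSNR  {ev.psnr(vol.data, test.data, mask):8.2f} dB       (higher = better)")
print(f"SSIM  {ev.ssim(vol.data, test.data, mask):8.3f}          (1 = identical structure)")
print(f"NCC   {ev.ncc(vol.data, test.data, mask):8.3f}          (1 = perfectly correlated)")
slope, intercept, r2 = ev.linearity_slope(vol.data, test.data, mask)
print(f"Slope {slope:8.3f}          (1 = intensities on the identity line; r2={r2:.3f})")
rois = [(0, 8, 28, 36, 20, 28), (0, 8, 28, 36, 36, 44)]
print(f"SNU   {ev.snu(test.data, rois):8.2f} mg/cm3   (spread of ROI means; 0 = uniform)")
ba = ev.bland_altman(vol.data, test.data, mask)
print(f"Bland-Altman bias {ba.bias:+.2f}, 95% limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
arch = np.array([[44.0, 16.0], [20.0, 32.0], [44.0, 48.0]])
prof = ev.arch_profile_correlation(vol.data[4], test.data[4], arch)
print(f"arch-profile Pearson r = {prof.pearson_r:.3f} over {prof.ref_values.size} samples")
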