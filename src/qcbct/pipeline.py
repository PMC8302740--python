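"""End-to-end synthetic experiment: phantoms -> calibration -> masks ->
training -> hybrid inference -> BMD metrics.

Mirrors the full measurement chain on generated data: one jaw phantom
(no metal) provides training slices, a second (with metal restorations)
provides held-out test slices; both are rendered to HU, degraded to
CBCT-like volumes, calibrated via the three-insert phantom on each
modality (yielding ground-truth QCT and the CAL_CBCT baseline), masked to
the anatomy, and fed through the two-stage training. The headline numbers
are MAD and regression slope of the network output (QCBCT) versus the
CAL_CBCT baseline against ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .calibration import apply_calibration, extract_insert_means, fit_calibration
from .evaluate import bland_altman, linearity_slope, mad, metric_report, ncc, psnr, snu, ssim
from .model import DEFAULT_WINDOW, LossWeights, normalize
from .phantom import (
    CalibrationPhantomLayout,
    DegradationSpec,
    PhantomSpec,
    build_skull_phantom_spec,
    bmd_to_hu,
    degrade,
    generate_calibration_volume,
    generate_qct_volume,
    streak_centers_from_spec,
)
from .preprocess import make_mask, mask_pair
from .train import NetworkBundle, TrainConfig, run_qcbctnet, synthesize_cyc, train_cyclegan, train_unet
from .volume import VolumeImage

#: linear HU response of the simulated CT scanner (HU = slope*BMD + intercept)
CT_HU_SLOPE = 0.9
CT_HU_INTERCEPT = 30.0


@dataclasses.dataclass
class ExperimentConfig:
    """Reduced-scale study conditions for the synthetic end-to-end run."""

    n_train_slices: int = 64
    n_test_slices: int = 16
    slice_size: int = 64
    cyclegan_epochs: int = 5
    unet_epochs: int = 15
    base_channels: int = 8
    unet_base_channels: int = 16  # the restoration U-Net carries the accuracy budget
    n_residual_blocks: int = 9
    batch_size: int = 8
    cyclegan_lr: float = 1e-3  # reduced-scale schedule; published default is 2e-4
    unet_lr: float = 2e-3  # reduced-scale schedule; published default is 1e-4
    seed: int = 0
    degradation: DegradationSpec = dataclasses.field(default_factory=DegradationSpec)


def prepare_paired_volumes(
    phantom_spec: PhantomSpec,
    degradation: DegradationSpec,
    seed: int,
) -> dict:
    """Simulate one scanning session: ground-truth QCT and CAL_CBCT
    baseline for a skull phantom, plus the intersection anatomy mask."""
    truth = generate_qct_volume(phantom_spec)
    ct_hu = truth.copy_with(data=bmd_to_hu(truth.data, CT_HU_SLOPE, CT_HU_INTERCEPT), unit="HU",
                            modality="CT")
    layout = CalibrationPhantomLayout()
    cal_ct, _ = generate_calibration_volume(
        layout, noise_sigma=0.0, hu_slope=CT_HU_SLOPE, hu_intercept=CT_HU_INTERCEPT, seed=seed
    )
    ct_model = fit_calibration(extract_insert_means(cal_ct, layout, roi_radius=4.0))
    qct = apply_calibration(ct_hu, ct_model, modality="QCT")

    streaks = streak_centers_from_spec(phantom_spec)
    deg = dataclasses.replace(degradation, seed=seed + 101)
    cbct_raw = degrade(ct_hu, deg, streak_centers=streaks)
    deg_cal = dataclasses.replace(degradation, seed=seed + 202)
    cal_cbct_phantom = degrade(cal_ct, deg_cal)
    cbct_model = fit_calibration(extract_insert_means(cal_cbct_phantom, layout, roi_radius=4.0))
    cal_cbct = apply_calibration(cbct_raw, cbct_model, modality="CAL_CBCT")

    m_qct = make_mask(qct)
    m_cbct = make_mask(cal_cbct)
    qct_m, cal_cbct_m, inter = mask_pair(qct, cal_cbct, m_qct, m_cbct)
    return {
        "truth": truth,
        "qct": qct_m,
        "cal_cbct": cal_cbct_m,
        "mask": inter,
        "ct_model": ct_model,
        "cbct_model": cbct_model,
    }


def _to_slices(vol: VolumeImage) -> np.ndarray:
    return vol.data[:, None, :, :]


def run_synthetic_experiment(
    config: Optional[ExperimentConfig] = None,
    compute_baselines: bool = False,
) -> dict:
    """Full reduced-scale study; returns metrics and the trained bundle.

    With ``compute_baselines`` the Cycle-GAN-only and single-channel
    U-Net-only outputs are also evaluated under the same settings.
    """
    cfg = config or ExperimentConfig()
    base_seed = int(cfg.seed) % (2**31 - 1)

    train_spec = build_skull_phantom_spec(
        n_slices=cfg.n_train_slices, size=cfg.slice_size, seed=base_seed + 11, with_metal=False
    )
    test_spec = build_skull_phantom_spec(
        n_slices=cfg.n_test_slices, size=cfg.slice_size, seed=base_seed + 22, with_metal=True
    )
    train_data = prepare_paired_volumes(train_spec, cfg.degradation, seed=base_seed + 1000)
    test_data = prepare_paired_volumes(test_spec, cfg.degradation, seed=base_seed + 2000)

    window = DEFAULT_WINDOW
    tcfg = TrainConfig(
        batch_size=cfg.batch_size,
        epochs=cfg.cyclegan_epochs,
        unet_epochs=cfg.unet_epochs,
        cyclegan_lr=cfg.cyclegan_lr,
        unet_lr=cfg.unet_lr,
        seed=base_seed + 7,
        generator_base_channels=cfg.base_channels,
        discriminator_base_channels=cfg.base_channels,
        unet_base_channels=cfg.unet_base_channels,
        n_residual_blocks=cfg.n_residual_blocks,
        weights=LossWeights(window=window),
    )
    cbct_n = normalize(_to_slices(train_data["cal_cbct"]), window)
    qct_n = normalize(_to_slices(train_data["qct"]), window)
    masks = train_data["mask"].data[:, None].astype(bool)

    g_c2q, g_q2c, gan_history = train_cyclegan(cbct_n, qct_n, tcfg)
    cyc_n = synthesize_cyc(cbct_n, g_c2q, window=None, batch_size=cfg.batch_size)
    unet, unet_history = train_unet(
        np.concatenate([cbct_n, cyc_n], axis=1), qct_n, tcfg, masks=masks
    )
    bundle = NetworkBundle(g_c2q, g_q2c, None, None, unet, window)

    qct_t = test_data["qct"]
    cal_t = test_data["cal_cbct"]
    mask_t = test_data["mask"].data.astype(bool)
    qcbct = run_qcbctnet(cal_t.data, bundle, batch_size=cfg.batch_size)

    def _metrics(test_arr):
        slope, intercept, r2 = linearity_slope(qct_t.data, test_arr, mask_t)
        ba = bland_altman(qct_t.data, test_arr, mask_t)
        return {
            "mad": mad(qct_t.data, test_arr, mask_t),
            "psnr": psnr(qct_t.data, test_arr, mask_t),
            "ssim": ssim(qct_t.data, test_arr, mask_t),
            "ncc": ncc(qct_t.data, test_arr, mask_t),
            "slope": slope,
            "intercept": intercept,
            "r2": r2,
            "bland_altman_bias": ba.bias,
            "bland_altman_loa": (ba.loa_low, ba.loa_high),
        }

    results = {
        "qcbct": _metrics(qcbct),
        "cal_cbct": _metrics(cal_t.data),
        "gan_history": gan_history,
        "unet_history": unet_history,
        "bundle": bundle,
        "test": {"qct": qct_t, "cal_cbct": cal_t, "qcbct": qcbct, "mask": mask_t},
        "report_qcbct": metric_report(qct_t.data, qcbct, mask_t),
        "report_cal_cbct": metric_report(qct_t.data, cal_t.data, mask_t),
    }
    # SNU over two rectangular reference ROIs in the trabecular region
    c = cfg.slice_size // 2
    rois = [
        (0, cfg.n_test_slices, c - 4, c + 4, c - 10, c - 2),
        (0, cfg.n_test_slices, c - 4, c + 4, c + 2, c + 10),
    ]
    results["qcbct"]["snu"] = snu(qcbct, rois)
    results["cal_cbct"]["snu"] = snu(cal_t.data, rois)

    if compute_baselines:
        cyc_t = synthesize_cyc(cal_t.data, g_c2q, window=window, batch_size=cfg.batch_size)
        results["cyc_cbct"] = _metrics(cyc_t)
        unet1, _ = train_unet(cbct_n, qct_n, tcfg, masks=masks, in_channels=1)
        cal_t_n = normalize(_to_slices(cal_t), window)
        from .model import denormalize
        from .train import _infer_forward

        u_cbct = denormalize(_infer_forward(unet1, cal_t_n, cfg.batch_size, "image"), window)[:, 0]
        results["u_cbct"] = _metrics(u_cbct)
    return results
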