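"""Diagnostic plots: voxel-intensity regression, Bland-Altman, arch profiles.

All functions take plain arrays plus a path and write PNG/SVG via the Agg
backend; large voxel sets are subsampled for plotting only (the statistics
are always computed on the full data).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ArchProfile, bland_altman, linearity_slope

_MAX_POINTS = 100_000


def _masked_pair(ref, test, mask, rng):
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    m = np.ones(ref.shape, bool) if mask is None else np.asarray(mask).astype(bool)
    r, t = ref[m], test[m]
    if r.size > _MAX_POINTS:
        idx = rng.choice(r.size, _MAX_POINTS, replace=False)
        return r[idx], t[idx], r, t
    return r, t, r, t


def plot_regression(ref, test, mask=None, path: str | Path = "regression.png", seed: int = 0):
    """Scatter of test vs reference intensity with the fitted OLS line."""
    rng = np.random.default_rng(seed)
    rs, ts, r_all, t_all = _masked_pair(ref, test, mask, rng)
    slope, intercept, r2 = linearity_slope(r_all, t_all)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(rs, ts, ".", ms=1, alpha=0.3, color="tab:blue")
    xs = np.linspace(r_all.min(), r_all.max(), 2)
    ax.plot(xs, slope * xs + intercept, "r-", lw=1.5,
            label=f"y = {slope:.2f}x {intercept:+.1f} (r²={r2:.2f})")
    ax.plot(xs, xs, "k--", lw=0.8, label="identity")
    ax.set_xlabel("reference BMD (mg/cm³)")
    ax.set_ylabel("test BMD (mg/cm³)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return slope, intercept, r2


def plot_bland_altman(ref, test, mask=None, path: str | Path = "bland_altman.png", seed: int = 0):
    """Difference vs mean with bias and 95% limits of agreement."""
    rng = np.random.default_rng(seed)
    rs, ts, r_all, t_all = _masked_pair(ref, test, mask, rng)
    ba = bland_altman(r_all, t_all)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot((rs + ts) / 2, ts - rs, ".", ms=1, alpha=0.3)
    for y, style, lab in ((ba.bias, "r-", f"bias {ba.bias:+.1f}"),
                          (ba.loa_low, "r--", f"LoA {ba.loa_low:+.1f}"),
                          (ba.loa_high, "r--", f"LoA {ba.loa_high:+.1f}")):
        ax.axhline(y, color=style[0], ls=style[1:], lw=1, label=lab)
    ax.set_xlabel("mean BMD (mg/cm³)")
    ax.set_ylabel("difference (mg/cm³)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ba


def plot_arch_profiles(profiles: dict[str, ArchProfile], path: str | Path = "profiles.png"):
    """Overlay intensity profiles along the dental arch for several volumes."""
    fig, ax = plt.subplots(figsize=(5, 3))
    first = next(iter(profiles.values()))
    ax.plot(first.arc_positions, first.ref_values, "k-", lw=1.5, label="reference")
    for name, prof in profiles.items():
        ax.plot(prof.arc_positions, prof.test_values, lw=1,
                label=f"{name} (r={prof.pearson_r:.2f})")
    ax.set_xlabel("normalized arc length along dental arch")
    ax.set_ylabel("BMD (mg/cm³)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
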