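"""Reference skull-phantom benchmark of the four BMD reconstruction methods.

Published mean per-slice metric values (MAD, PSNR, SSIM, NCC, SNU, slope)
for the hybrid network (QCBCT-NET), plain Cycle-GAN, plain U-Net and the
calibration-only baseline, measured against ground-truth QCT on a
metal-restoration skull phantom at two scanning conditions, split into
maxilla (axial slices 1-81) and mandible (82-200). The reported
percentage-improvement table is recomputable from these means with
:func:`qcbct.evaluate.percent_improvement`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .evaluate import percent_improvement

METRICS = ("mad", "psnr", "ssim", "ncc", "snu", "slope")
CONDITIONS = ("80kVp_8mA", "90kVp_10mA")
REGIONS = ("maxilla", "mandible")
METHODS = ("qcbct", "cyclegan", "unet", "cal_cbct")

#: direction of improvement per metric
METRIC_DIRECTIONS = {
    "mad": "lower_better",
    "psnr": "higher_better",
    "ssim": "higher_better",
    "ncc": "higher_better",
    "snu": "lower_better",
    "slope": "higher_better",
}

# benchmark means, keyed (condition, region, method); values in METRICS order
BENCHMARK_MEANS: dict[tuple[str, str, str], tuple[float, ...]] = {
    ("80kVp_8mA", "maxilla", "qcbct"): (203.45, 23.87, 0.87, 0.87, 15.60, 0.83),
    ("80kVp_8mA", "maxilla", "cyclegan"): (328.91, 19.94, 0.60, 0.62, 79.04, 0.45),
    ("80kVp_8mA", "maxilla", "unet"): (493.91, 16.93, 0.41, 0.55, 13.39, 0.31),
    ("80kVp_8mA", "maxilla", "cal_cbct"): (592.40, 15.63, 0.31, 0.61, 69.30, 0.26),
    ("80kVp_8mA", "mandible", "qcbct"): (190.79, 24.58, 0.87, 0.88, 21.85, 0.85),
    ("80kVp_8mA", "mandible", "cyclegan"): (313.14, 20.52, 0.58, 0.63, 41.59, 0.42),
    ("80kVp_8mA", "mandible", "unet"): (371.00, 18.54, 0.48, 0.57, 17.54, 0.35),
    ("80kVp_8mA", "mandible", "cal_cbct"): (491.44, 17.33, 0.40, 0.62, 39.19, 0.30),
    ("90kVp_10mA", "maxilla", "qcbct"): (265.4, 21.92, 0.79, 0.84, 27.09, 0.62),
    ("90kVp_10mA", "maxilla", "cyclegan"): (296.82, 21.08, 0.72, 0.76, 68.91, 0.55),
    ("90kVp_10mA", "maxilla", "unet"): (474.15, 17.40, 0.50, 0.68, 16.02, 0.38),
    ("90kVp_10mA", "maxilla", "cal_cbct"): (661.48, 14.87, 0.29, 0.75, 52.71, 0.31),
    ("90kVp_10mA", "mandible", "qcbct"): (236.25, 22.98, 0.79, 0.80, 15.87, 0.66),
    ("90kVp_10mA", "mandible", "cyclegan"): (288.28, 21.38, 0.69, 0.71, 36.22, 0.53),
    ("90kVp_10mA", "mandible", "unet"): (370.59, 19.66, 0.57, 0.67, 12.80, 0.40),
    ("90kVp_10mA", "mandible", "cal_cbct"): (573.25, 16.15, 0.37, 0.72, 72.44, 0.31),
}

# published percentage increases of the hybrid network over each comparator,
# keyed (condition, region, comparator); values in METRICS order
REPORTED_IMPROVEMENTS: dict[tuple[str, str, str], tuple[float, ...]] = {
    ("80kVp_8mA", "maxilla", "cyclegan"): (38.14, 19.71, 45.00, 40.32, 80.26, 84.44),
    ("80kVp_8mA", "mandible", "cyclegan"): (39.07, 19.79, 50.00, 39.68, 47.46, 102.38),
    ("80kVp_8mA", "maxilla", "unet"): (58.81, 40.99, 112.20, 58.18, -16.50, 167.74),
    ("80kVp_8mA", "mandible", "unet"): (48.57, 32.58, 81.25, 54.39, -24.57, 142.86),
    ("90kVp_10mA", "maxilla", "cyclegan"): (10.59, 3.98, 9.72, 10.53, 59.10, 12.73),
    ("90kVp_10mA", "mandible", "cyclegan"): (17.69, 7.48, 14.49, 12.68, 56.18, 24.53),
    ("90kVp_10mA", "maxilla", "unet"): (44.03, 25.98, 58.00, 23.53, -73.47, 63.16),
    ("90kVp_10mA", "mandible", "unet"): (36.40, 16.89, 38.60, 19.40, -23.98, 65.00),
}

#: the four reported cells (all at 90 kVp / 10 mA) that do not follow from the
#: published means themselves — recomputation gives 60.69, -69.10, 18.05 and
#: 36.25 for these keys; they were presumably derived from unrounded values.
KNOWN_INCONSISTENT_CELLS = frozenset(
    {
        ("90kVp_10mA", "maxilla", "cyclegan", "snu"),
        ("90kVp_10mA", "maxilla", "unet", "snu"),
        ("90kVp_10mA", "mandible", "cyclegan", "mad"),
        ("90kVp_10mA", "mandible", "unet", "mad"),
    }
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Table-style rounding: 2 decimals, ties away from zero."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_improvement_table() -> dict[tuple[str, str, str, str], float]:
    """Percentage improvement of the hybrid network over Cycle-GAN and
    U-Net for every benchmark cell, rounded to 2 decimals.

    Keys are (condition, region, comparator, metric).
    """
    out: dict[tuple[str, str, str, str], float] = {}
    for cond in CONDITIONS:
        for region in REGIONS:
            q = BENCHMARK_MEANS[(cond, region, "qcbct")]
            for comparator in ("cyclegan", "unet"):
                other = BENCHMARK_MEANS[(cond, region, comparator)]
                for i, metric in enumerate(METRICS):
                    val = percent_improvement(q[i], other[i], METRIC_DIRECTIONS[metric])
                    out[(cond, region, comparator, metric)] = round_half_up(val)
    return out


def reported_improvement_table() -> dict[tuple[str, str, str, str], float]:
    """The published improvement table in the same keyed layout."""
    out: dict[tuple[str, str, str, str], float] = {}
    for (cond, region, comparator), vals in REPORTED_IMPROVEMENTS.items():
        for metric, v in zip(METRICS, vals):
            out[(cond, region, comparator, metric)] = v
    return out
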