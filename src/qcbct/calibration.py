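"""Phantom-based linear intensity -> BMD calibration.

A CT (or CBCT) scan of a three-insert hydroxyapatite phantom gives three
ROI mean intensities at known densities (0, 100, 200 mg/cm3). Ordinary
least squares of density on mean intensity yields the line that converts a
whole volume to BMD: QCT from CT, and the CAL_CBCT baseline from CBCT.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import yaml

from .phantom import CalibrationPhantomLayout
from .volume import BACKGROUND_SENTINEL, VolumeImage

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CalibrationModel:
    """Linear map BMD = slope * intensity + intercept.

    ``rms_residual`` (mg/cm3) is the root-mean-square misfit of the three
    insert points about the fitted line — a QC number that is 0 for an
    exactly linear scanner response.
    """

    slope: float
    intercept: float
    insert_means: tuple[float, ...]
    insert_densities: tuple[float, ...]
    rms_residual: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def __call__(self, intensity):
        return self.slope * np.asarray(intensity, dtype=np.float64) + self.intercept

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "slope": float(self.slope),
                    "intercept": float(self.intercept),
                    "insert_means": [float(m) for m in self.insert_means],
                    "insert_densities": [float(d) for d in self.insert_densities],
                    "rms_residual": float(self.rms_residual),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["insert_means"] = tuple(d["insert_means"])
        d["insert_densities"] = tuple(d["insert_densities"])
        return cls(**d)


def extract_insert_means(
    vol: VolumeImage,
    layout: CalibrationPhantomLayout,
    roi_radius: Optional[float] = None,
    slices: Optional[tuple[int, int]] = None,
) -> tuple[float, float, float]:
    """Mean intensity over each cylindrical insert ROI.

    ``roi_radius`` defaults to the full insert radius; a smaller value
    avoids partial-volume voxels at the insert rim. Order matches
    ``layout.insert_densities``.
    """
    nz, nr, nc = vol.shape
    radius = layout.insert_radius if roi_radius is None else float(roi_radius)
    if radius <= 0:
        raise ValueError("ROI radius must be > 0")
    z0, z1 = (0, nz) if slices is None else slices
    if not (0 <= z0 < z1 <= nz):
        raise ValueError("slice range outside volume")
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    means = []
    for r0, c0 in layout.insert_centers:
        if r0 - radius < 0 or c0 - radius < 0 or r0 + radius >= nr or c0 + radius >= nc:
            raise ValueError("ROI extends outside the grid")
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        if not disk.any():
            raise ValueError("empty ROI")
        means.append(float(vol.data[z0:z1, disk].mean()))
    return tuple(means)  # type: ignore[return-value]


def fit_calibration(
    means: Sequence[float],
    densities: Sequence[float] = (0.0, 100.0, 200.0),
) -> CalibrationModel:
    """OLS of density (y) on mean ROI intensity (x)."""
    x = np.asarray(means, dtype=np.float64)
    y = np.asarray(densities, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 (mean, density) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all insert means equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        insert_means=tuple(float(m) for m in x),
        insert_densities=tuple(float(d) for d in y),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def apply_calibration(
    vol: VolumeImage,
    model: CalibrationModel,
    modality: Optional[str] = None,
) -> VolumeImage:
    """Voxelwise slope*v + intercept, tagged mg/cm3.

    Voxels equal to the background sentinel (-1000, set by masking) pass
    through unchanged so non-anatomy never acquires a fabricated BMD.
    """
    if vol.unit == "mg/cm3":
        log.warning("applying calibration to an already-calibrated volume")
    out = model(vol.data)
    sentinel = vol.data == BACKGROUND_SENTINEL
    out[sentinel] = BACKGROUND_SENTINEL
    return vol.copy_with(data=out, unit="mg/cm3", modality=modality or f"CAL_{vol.modality or 'CBCT'}")
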