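"""3D scalar volumes with voxel spacing, intensity-unit and modality tags.

The pipeline's interchange container. Axis convention is (slice, row, col),
i.e. axis 0 indexes axial slices; world coordinates (mm) of a voxel index
``i`` are ``i * spacing`` (0-based indices, no origin offset).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

#: Hounsfield unit assigned to voxels outside the anatomy mask (air).
BACKGROUND_SENTINEL = -1000.0

_VALID_UNITS = ("raw", "HU", "mg/cm3")


@dataclasses.dataclass
class VolumeImage:
    """A 3D scalar grid plus the metadata the pipeline needs.

    Parameters
    ----------
    data:
        Array of shape (n_slices, n_rows, n_cols), float.
    spacing_mm:
        Voxel size along each axis, millimetres.
    unit:
        One of ``raw`` (uncalibrated scanner intensities), ``HU``
        (Hounsfield units) or ``mg/cm3`` (calibrated BMD).
    modality:
        Free-form tag, e.g. ``"QCT"``, ``"CBCT"``, ``"CAL_CBCT"``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    unit: str = "raw"
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_mm}")
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray | None = None, **meta) -> "VolumeImage":
        """Return a copy, optionally replacing the array and/or metadata."""
        kw = dict(
            data=self.data.copy() if data is None else np.asarray(data, dtype=np.float64),
            spacing_mm=self.spacing_mm,
            unit=self.unit,
            modality=self.modality,
        )
        kw.update(meta)
        return VolumeImage(**kw)


def save_nifti(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI with voxel spacing in the header.

    The (slice, row, col) array is stored transposed to NIfTI's
    (col, row, slice) fastest-first layout so spacings land on the
    matching header axes.
    """
    arr = np.ascontiguousarray(vol.data.transpose(2, 1, 0))
    affine = np.diag(list(vol.spacing_mm[::-1]) + [1.0])
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing_mm[::-1])
    img.header["descrip"] = f"unit={vol.unit};modality={vol.modality}".encode()[:80]
    nib.save(img, str(path))


def load_nifti(path: str | Path, unit: str | None = None, modality: str | None = None) -> VolumeImage:
    """Read a NIfTI volume written by :func:`save_nifti` (or any axial NIfTI)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
    meta = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
    return VolumeImage(
        data=arr.transpose(2, 1, 0),
        spacing_mm=tuple(float(z) for z in zooms[::-1]),
        unit=unit or meta.get("unit", "raw"),
        modality=modality or meta.get("modality", ""),
    )


def load_dicom_series(paths: Sequence[str | Path], unit: str = "HU", modality: str = "") -> VolumeImage:
    """Assemble an axial DICOM series into a volume.

    Slices are ordered by ImagePositionPatient z (falling back to
    InstanceNumber); RescaleSlope/Intercept are applied when present.
    """
    import pydicom

    if not paths:
        raise ValueError("empty DICOM series")
    datasets = [pydicom.dcmread(str(p)) for p in paths]

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    for ds in datasets:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(a * slope + intercept)
    first = datasets[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(first, "SliceThickness", 1.0))
    return VolumeImage(
        data=np.stack(slices, axis=0),
        spacing_mm=(dz, float(px[0]), float(px[1])),
        unit=unit,
        modality=modality or str(getattr(first, "Modality", "")),
    )
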