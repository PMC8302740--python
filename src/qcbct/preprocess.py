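"""Landmark-based rigid registration, grid harmonization and anatomy masks.

Paired CT/CBCT volumes are aligned from six dental landmarks (closed-form
least-squares rigid fit), resampled onto a common grid, center-cropped and
resized to the network geometry, and masked to the maxillomandibular
anatomy; everything outside the intersection mask is set to -1000 HU.

Conventions: voxel indices are 0-based; world mm coordinates are
``index * spacing`` per axis in (z, y, x) = (slice, row, col) order.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.transform import resize as _sk_resize

from .volume import BACKGROUND_SENTINEL, VolumeImage

LANDMARK_NAMES = (
    "left_lateral_incisor_vertex",
    "right_lateral_incisor_vertex",
    "left_first_premolar_buccal_cusp",
    "right_first_premolar_buccal_cusp",
    "left_first_molar_distobuccal_cusp",
    "right_first_molar_distobuccal_cusp",
)


@dataclasses.dataclass
class LandmarkSet:
    """Six named dental landmarks, mm coordinates (z, y, x)."""

    points: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if set(self.points) != set(LANDMARK_NAMES):
            raise ValueError(f"landmark names must be exactly {LANDMARK_NAMES}")
        for name, p in self.points.items():
            if len(p) != 3 or not np.all(np.isfinite(p)):
                raise ValueError(f"bad coordinates for {name}: {p}")

    def as_array(self) -> np.ndarray:
        """(6, 3) array in canonical name order."""
        return np.array([self.points[n] for n in LANDMARK_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (6, 3):
            raise ValueError("expected a (6, 3) array")
        return cls({n: tuple(p) for n, p in zip(LANDMARK_NAMES, arr)})

    def transformed(self, xform: "RigidTransform") -> "LandmarkSet":
        return LandmarkSet.from_array(xform.apply(self.as_array()))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(v) for k, v in self.points.items()}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "LandmarkSet":
        """Read landmarks from JSON ({name: [z,y,x]}) or CSV (name,z,y,x)."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            with open(path) as fh:
                d = json.load(fh)
            return cls({k: tuple(float(c) for c in v) for k, v in d.items()})
        with open(path) as fh:
            rows = list(csv.reader(fh))
        pts = {}
        for row in rows:
            if not row or row[0].strip().lower() in ("name", ""):
                continue
            pts[row[0].strip()] = tuple(float(c) for c in row[1:4])
        return cls(pts)


@dataclasses.dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation (mm coordinates)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        R = self.rotation
        if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be 3x3 orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_rigid_from_landmarks(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Closed-form least-squares rigid fit (Kabsch, SVD) so that
    R * moving + t best matches fixed over the six paired landmarks."""
    m = moving.as_array()
    f = fixed.as_array()
    mc, fc = m.mean(axis=0), f.mean(axis=0)
    m0, f0 = m - mc, f - fc
    # degenerate configurations cannot pin down a rotation
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2:
        raise ValueError("landmarks are collinear or coincident")
    H = m0.T @ f0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    return RigidTransform(R, t)


def resample(
    vol: VolumeImage,
    xform: RigidTransform,
    target_shape: tuple[int, int, int] | None = None,
    target_spacing: tuple[float, float, float] | None = None,
    fill_value: float = BACKGROUND_SENTINEL,
) -> VolumeImage:
    """Trilinearly resample ``vol`` under ``xform`` onto a target grid.

    ``xform`` maps moving-world -> fixed-world mm coordinates; the output
    grid is the fixed grid (defaults: same shape/spacing as input).
    Out-of-field voxels get ``fill_value``.
    """
    tshape = tuple(int(s) for s in (target_shape or vol.shape))
    tspacing = tuple(float(s) for s in (target_spacing or vol.spacing_mm))
    inv = xform.inverse()
    idx = np.indices(tshape, dtype=np.float64).reshape(3, -1).T
    world = idx * np.asarray(tspacing)
    src_world = inv.apply(world)
    src_idx = (src_world / np.asarray(vol.spacing_mm)).T.reshape(3, *tshape)
    out = ndimage.map_coordinates(vol.data, src_idx, order=1, mode="constant", cval=fill_value)
    return VolumeImage(out, spacing_mm=tspacing, unit=vol.unit, modality=vol.modality)


def crop_resize(
    vol: VolumeImage,
    crop_to: tuple[int, int, int] = (200, 559, 559),
    resize_to: tuple[int, int, int] = (200, 256, 256),
) -> VolumeImage:
    """Center crop in-plane and in z, then bilinearly resize each axial
    slice to the network geometry; the slice count must be preserved."""
    if crop_to[0] != resize_to[0]:
        raise ValueError("slice count must be preserved by crop_resize")
    nz, nr, nc = vol.shape
    cz, cr, cc = (int(v) for v in crop_to)
    if cz > nz or cr > nr or cc > nc:
        raise ValueError(f"crop {crop_to} larger than volume {vol.shape}")
    z0 = (nz - cz) // 2
    r0 = (nr - cr) // 2
    c0 = (nc - cc) // 2
    cropped = vol.data[z0 : z0 + cz, r0 : r0 + cr, c0 : c0 + cc]
    if (cr, cc) == tuple(resize_to[1:]):
        out = cropped.copy()
    else:
        out = np.empty(tuple(resize_to), dtype=np.float64)
        for k in range(cz):
            out[k] = _sk_resize(
                cropped[k], resize_to[1:], order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            )
    scale_r = cr / resize_to[1]
    scale_c = cc / resize_to[2]
    spacing = (vol.spacing_mm[0], vol.spacing_mm[1] * scale_r, vol.spacing_mm[2] * scale_c)
    return VolumeImage(out, spacing_mm=spacing, unit=vol.unit, modality=vol.modality)


@dataclasses.dataclass
class MaskVolume:
    """Binary anatomy mask congruent with a volume (1 = anatomy)."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self):
        return self.data.shape

    def intersect(self, other: "MaskVolume") -> "MaskVolume":
        if self.shape != other.shape:
            raise ValueError("mask shapes differ")
        return MaskVolume(self.data & other.data, provenance="intersection")


def make_mask(
    vol: VolumeImage,
    range_window: int = 3,
    threshold: float = 0.10,
    opening_radius: int = 2,
) -> MaskVolume:
    """Anatomy mask per axial slice: local range filter -> binarize ->
    border flood fill of the enclosed interior -> morphological opening.

    ``threshold`` is a fraction of each slice's dynamic range; a uniform
    slice yields an empty mask. The interior fill is a 4-connected flood
    fill from the slice border: everything it cannot reach through the
    background becomes anatomy. The opening (disk element) then removes
    small noise blobs; it runs after the fill because the range-filter
    edge band is only ~2 px thick and would not itself survive opening.
    """
    if range_window % 2 == 0 or range_window < 1:
        raise ValueError("range window must be odd")
    selem = morphology.disk(opening_radius) if opening_radius > 0 else None
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    out = np.zeros(vol.shape, dtype=np.uint8)
    for k in range(vol.shape[0]):
        sl = vol.data[k]
        rng_img = ndimage.maximum_filter(sl, size=range_window) - ndimage.minimum_filter(
            sl, size=range_window
        )
        dyn = np.ptp(sl)
        if dyn <= 0:
            continue
        edges = rng_img > threshold * dyn
        filled = ndimage.binary_fill_holes(edges, structure=four)
        # the range band extends (w-1)/2 px beyond the true edge; erode the
        # filled region by that half-width to recenter the boundary
        half = (range_window - 1) // 2
        if half > 0:
            filled = ndimage.binary_erosion(filled, structure=morphology.disk(half))
        if selem is not None:
            filled = ndimage.binary_opening(filled, structure=selem)
        out[k] = filled
    return MaskVolume(out, provenance=f"range{range_window}/thr{threshold}/open{opening_radius}")


def mask_pair(
    ct: VolumeImage,
    cbct: VolumeImage,
    m_ct: MaskVolume,
    m_cbct: MaskVolume,
) -> tuple[VolumeImage, VolumeImage, MaskVolume]:
    """Apply the intersection of both anatomy masks to both volumes;
    voxels outside become exactly -1000."""
    if not (ct.shape == cbct.shape == m_ct.shape == m_cbct.shape):
        raise ValueError("volumes and masks must be congruent")
    inter = m_ct.intersect(m_cbct)
    keep = inter.data.astype(bool)
    ct_out = np.where(keep, ct.data, BACKGROUND_SENTINEL)
    cbct_out = np.where(keep, cbct.data, BACKGROUND_SENTINEL)
    return (
        ct.copy_with(data=ct_out),
        cbct.copy_with(data=cbct_out),
        inter,
    )


def save_mask_nifti(mask: MaskVolume, path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    arr = np.ascontiguousarray(mask.data.transpose(2, 1, 0)).astype(np.uint8)
    img = nib.Nifti1Image(arr, np.diag(list(spacing_mm[::-1]) + [1.0]))
    nib.save(img, str(path))


def default_landmarks(spacing_scale: float = 1.0) -> LandmarkSet:
    """A plausible dental-arch landmark template (mm), used by the
    synthetic pipeline and registration tests."""
    base: Mapping[str, tuple[float, float, float]] = {
        "left_lateral_incisor_vertex": (60.0, 28.0, 44.0),
        "right_lateral_incisor_vertex": (60.0, 28.0, 36.0),
        "left_first_premolar_buccal_cusp": (58.5, 40.0, 52.0),
        "right_first_premolar_buccal_cusp": (58.5, 40.0, 28.0),
        "left_first_molar_distobuccal_cusp": (57.0, 52.0, 55.0),
        "right_first_molar_distobuccal_cusp": (57.0, 52.0, 25.0),
    }
    return LandmarkSet({k: tuple(c * spacing_scale for c in v) for k, v in base.items()})
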