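"""Synthetic skull/calibration phantoms and a CBCT-like degradation model.

Everything downstream (calibration, preprocessing, network training, metric
evaluation) is exercisable on volumes produced here, with no external data.
The skull phantom is piecewise-constant in BMD (mg/cm3) with trabecular,
cortical, tooth and metal compartments embedded in an acrylic-like
background; the degradation model turns its HU rendering into a CBCT-like
volume with a nonlinear intensity response, low-frequency shading, metal
streaks and noise — the corruption the intensity-mapping network learns to
invert.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .volume import VolumeImage

# Intensity window shared with the network normalization: air .. dense metal.
WINDOW_LO = -1000.0
WINDOW_HI = 3000.0

COMPARTMENT_LABELS = ("background", "trabecular", "cortical", "tooth", "metal")


@dataclasses.dataclass
class Compartment:
    """One piecewise-constant region: a 2D primitive extruded over slices.

    shape: "disk" (size = radius), "ellipse" (size = (semi_r, semi_c)) or
    "rect" (size = (half_r, half_c)); center is (row, col) in voxels;
    z_range is the half-open slice interval [z0, z1).
    """

    shape: str
    center: tuple[float, float]
    size: float | tuple[float, float]
    value: float
    label: str = "trabecular"
    z_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse", "rect"):
            raise ValueError(f"unknown primitive {self.shape!r}")
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not np.isfinite(self.value):
            raise ValueError("compartment value must be finite")

    def rasterize(self, n_rows: int, n_cols: int) -> np.ndarray:
        """Boolean in-plane footprint of the primitive."""
        rr, cc = np.mgrid[0:n_rows, 0:n_cols].astype(np.float64)
        r0, c0 = self.center
        if self.shape == "disk":
            rad = float(self.size)  # type: ignore[arg-type]
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        if self.shape == "ellipse":
            ar, ac = self.size  # type: ignore[misc]
            return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        hr, hc = self.size  # type: ignore[misc]
        return (np.abs(rr - r0) <= hr) & (np.abs(cc - c0) <= hc)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and composition of a synthetic skull phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)
    compartments: list[Compartment] = dataclasses.field(default_factory=list)
    background_value: float = 0.0
    n_slices_maxilla: int = 0
    n_slices_mandible: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.n_slices_maxilla == 0 and self.n_slices_mandible == 0:
            # default split mirrors the axial maxilla/mandible partition
            self.n_slices_maxilla = int(round(self.grid_shape[0] * 81 / 200))
            self.n_slices_mandible = self.grid_shape[0] - self.n_slices_maxilla
        if self.n_slices_maxilla + self.n_slices_mandible != self.grid_shape[0]:
            raise ValueError("maxilla + mandible slice counts must equal total slices")


@dataclasses.dataclass
class DegradationSpec:
    """Knobs of the CBCT-like corruption, applied in a fixed order.

    Order: power-law nonlinearity (gamma on the window-normalized
    intensity) -> gain/offset -> multiplicative low-frequency shading
    -> additive streaks -> additive Gaussian noise. The defaults are the
    package's standard study conditions; ``identity()`` is an exact
    fixed point of :func:`degrade`.
    """

    shading_amplitude: float = 0.15
    shading_scale_voxels: float = 12.0
    gain: float = 1.3
    offset: float = 80.0
    nonlinearity_gamma: float = 0.7
    noise_sigma: float = 20.0
    n_streaks: int = 2
    streak_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.shading_amplitude < 1):
            raise ValueError("shading_amplitude must be in [0, 1)")
        if self.nonlinearity_gamma <= 0:
            raise ValueError("nonlinearity_gamma must be > 0")

    @classmethod
    def identity(cls) -> "DegradationSpec":
        return cls(
            shading_amplitude=0.0,
            gain=1.0,
            offset=0.0,
            nonlinearity_gamma=1.0,
            noise_sigma=0.0,
            n_streaks=0,
            streak_amplitude=0.0,
        )


@dataclasses.dataclass
class CalibrationPhantomLayout:
    """Three cylindrical hydroxyapatite inserts of known density.

    Densities default to 0 (water), 100 and 200 mg/cm3 and must be strictly
    increasing; inserts must be disjoint and inside the grid.
    """

    insert_centers: tuple[tuple[float, float], ...] = ((32.0, 32.0), (32.0, 14.0), (32.0, 50.0))
    insert_radius: float = 6.0
    insert_densities: tuple[float, float, float] = (0.0, 100.0, 200.0)
    background_hu: float = 120.0  # acrylic body

    def __post_init__(self) -> None:
        if len(self.insert_centers) != 3 or len(self.insert_densities) != 3:
            raise ValueError("layout requires exactly three inserts")
        if self.insert_radius <= 0:
            raise ValueError("insert_radius must be > 0")
        d = self.insert_densities
        if not (d[0] < d[1] < d[2]):
            raise ValueError("insert densities must be strictly increasing")
        centers = np.asarray(self.insert_centers, dtype=float)
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        if np.any(dists[np.triu_indices(3, 1)] < 2 * self.insert_radius):
            raise ValueError("inserts overlap")


def generate_qct_volume(spec: PhantomSpec) -> VolumeImage:
    """Rasterize a phantom spec into a piecewise-constant BMD volume.

    Overlapping compartments resolve last-listed-wins.
    """
    nz, nr, nc = spec.grid_shape
    vol = np.full((nz, nr, nc), float(spec.background_value))
    for comp in spec.compartments:
        z0, z1 = comp.z_range if comp.z_range is not None else (0, nz)
        z0, z1 = max(0, int(z0)), min(nz, int(z1))
        if z1 <= z0:
            continue
        footprint = comp.rasterize(nr, nc)
        vol[z0:z1, footprint] = comp.value
    return VolumeImage(vol, spacing_mm=spec.voxel_size_mm, unit="mg/cm3", modality="QCT")


def bmd_to_hu(bmd: np.ndarray, slope: float = 1.0, intercept: float = 0.0) -> np.ndarray:
    """Linear HU rendering of a BMD map: hu = slope * bmd + intercept."""
    return slope * np.asarray(bmd, dtype=np.float64) + intercept


def generate_calibration_volume(
    layout: CalibrationPhantomLayout,
    noise_sigma: float = 0.0,
    grid_shape: tuple[int, int, int] = (8, 64, 64),
    hu_slope: float = 1.0,
    hu_intercept: float = 0.0,
    seed: int = 0,
) -> tuple[VolumeImage, CalibrationPhantomLayout]:
    """Render the three-insert calibration phantom in HU.

    Insert HU values follow the linear model ``hu_slope * density +
    hu_intercept``; Gaussian noise of ``noise_sigma`` HU is added when
    nonzero. The layout is returned alongside for ROI extraction.
    """
    nz, nr, nc = grid_shape
    centers = np.asarray(layout.insert_centers, dtype=float)
    if np.any(centers - layout.insert_radius < 0) or np.any(
        centers + layout.insert_radius >= [[nr, nc]] * 3
    ):
        raise ValueError("inserts extend outside the grid")
    vol = np.full(grid_shape, float(layout.background_hu))
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    for (r0, c0), dens in zip(layout.insert_centers, layout.insert_densities):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= layout.insert_radius**2
        vol[:, disk] = hu_slope * dens + hu_intercept
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape)
    return VolumeImage(vol, unit="HU", modality="CT"), layout


def _shading_field(shape: tuple[int, int, int], amplitude: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field rescaled exactly to [1-a, 1+a]."""
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=(scale / 2.0, scale, scale), mode="nearest")
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.ones(shape)
    return 1.0 - amplitude + (field - lo) * (2.0 * amplitude / (hi - lo))


def _streak_field(
    shape: tuple[int, int, int],
    n_streaks: int,
    amplitude: float,
    rng: np.random.Generator,
    centers: Optional[Sequence[tuple[float, float]]] = None,
) -> np.ndarray:
    """Additive streak pattern: thin lines at random angles through centers."""
    nz, nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    plane = np.zeros((nr, nc))
    if centers is None or len(centers) == 0:
        centers = [((nr - 1) / 2.0, (nc - 1) / 2.0)]
    width = 1.0  # voxels, Gaussian cross-profile
    for k in range(n_streaks):
        r0, c0 = centers[k % len(centers)]
        theta = rng.uniform(0, np.pi)
        # signed distance to the line through (r0, c0) at angle theta
        d = (rr - r0) * np.sin(theta) - (cc - c0) * np.cos(theta)
        sign = 1.0 if k % 2 == 0 else -1.0
        plane += sign * amplitude * np.exp(-(d**2) / (2 * width**2))
    return np.broadcast_to(plane, shape)


def degrade(
    vol: VolumeImage,
    spec: DegradationSpec,
    streak_centers: Optional[Sequence[tuple[float, float]]] = None,
) -> VolumeImage:
    """Apply the CBCT-like corruption to an HU volume.

    Deterministic given ``spec.seed``. ``streak_centers`` should be the
    in-plane centers of metal/tooth compartments when known; otherwise
    streaks pass through the grid center.
    """
    v = np.asarray(vol.data, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("input volume must be finite")
    rng = np.random.default_rng(spec.seed)
    out = v.copy()
    if spec.nonlinearity_gamma != 1.0:
        span = WINDOW_HI - WINDOW_LO
        t = np.clip((out - WINDOW_LO) / span, 0.0, None)
        out = span * t**spec.nonlinearity_gamma + WINDOW_LO
    out = spec.gain * out + spec.offset
    if spec.shading_amplitude > 0:
        out = out * _shading_field(out.shape, spec.shading_amplitude, spec.shading_scale_voxels, rng)
    if spec.n_streaks > 0 and spec.streak_amplitude != 0:
        out = out + _streak_field(out.shape, spec.n_streaks, spec.streak_amplitude, rng, streak_centers)
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return vol.copy_with(data=out, unit="raw", modality="CBCT")


# ---------------------------------------------------------------------------
# A ready-made jaw-like phantom for demos and end-to-end runs.
# ---------------------------------------------------------------------------

def build_skull_phantom_spec(
    n_slices: int = 20,
    size: int = 64,
    seed: int = 0,
    with_metal: bool = True,
) -> PhantomSpec:
    """A jaw-like phantom: acrylic head, cortical arch, trabecular core,
    teeth along the arch, optional metal restorations.

    Per-slice-band jitter of positions and BMD values (seeded) gives each
    phantom individual anatomy so train/test phantoms differ, mirroring the
    two-skull train/test design.
    """
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    comps: list[Compartment] = []
    # soft-tissue/acrylic head
    comps.append(
        Compartment("ellipse", (c, c), (size * 0.42, size * 0.45), 30.0, "background")
    )
    n_max = int(round(n_slices * 81 / 200)) or 1
    n_bands = max(2, n_slices // 4)
    edges = np.linspace(0, n_slices, n_bands + 1).astype(int)
    for b in range(n_bands):
        z0, z1 = int(edges[b]), int(edges[b + 1])
        if z1 <= z0:
            continue
        jr = rng.uniform(-1.5, 1.5)
        jc = rng.uniform(-1.5, 1.5)
        arch_r = size * rng.uniform(0.28, 0.33)
        cort = rng.uniform(850.0, 1000.0)
        trab = rng.uniform(150.0, 260.0)
        # cortical ring: outer ellipse then trabecular interior overrides it
        comps.append(
            Compartment("ellipse", (c + jr, c + jc), (arch_r, arch_r * 1.1), cort, "cortical", (z0, z1))
        )
        comps.append(
            Compartment(
                "ellipse", (c + jr, c + jc), (arch_r - size * 0.06, arch_r * 1.1 - size * 0.06),
                trab, "trabecular", (z0, z1),
            )
        )
        # teeth along the anterior arch
        n_teeth = 4
        for k in range(n_teeth):
            theta = np.pi * (0.25 + 0.5 * k / (n_teeth - 1)) + rng.uniform(-0.05, 0.05)
            tr = c + jr - arch_r * 0.85 * np.sin(theta)
            tc = c + jc + arch_r * 1.0 * np.cos(theta)
            comps.append(
                Compartment("disk", (tr, tc), size * 0.035, rng.uniform(1100.0, 1350.0), "tooth", (z0, z1))
            )
    if with_metal:
        zm = (0, max(1, n_max // 2))
        comps.append(
            Compartment("disk", (c - size * 0.22, c + size * 0.12), size * 0.02, 2800.0, "metal", zm)
        )
    return PhantomSpec(
        grid_shape=(n_slices, size, size),
        compartments=comps,
        background_value=0.0,
        n_slices_maxilla=n_max,
        n_slices_mandible=n_slices - n_max,
        seed=seed,
    )


def streak_centers_from_spec(spec: PhantomSpec) -> list[tuple[float, float]]:
    """In-plane centers of metal (preferred) or tooth compartments."""
    metal = [comp.center for comp in spec.compartments if comp.label == "metal"]
    if metal:
        return metal
    return [comp.center for comp in spec.compartments if comp.label == "tooth"]


# --- YAML round-trips -------------------------------------------------------

def spec_to_yaml(obj, path) -> None:
    """Serialize any of the phantom dataclasses to YAML."""
    d = dataclasses.asdict(obj)
    d["__type__"] = type(obj).__name__
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(d), fh, sort_keys=False)


def spec_from_yaml(path):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kind = d.pop("__type__")
    cls = {
        "PhantomSpec": PhantomSpec,
        "DegradationSpec": DegradationSpec,
        "CalibrationPhantomLayout": CalibrationPhantomLayout,
    }[kind]
    if cls is PhantomSpec:
        d["compartments"] = [Compartment(**_tuplify(c)) for c in d.get("compartments", [])]
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
    if cls is CalibrationPhantomLayout:
        d["insert_centers"] = tuple(tuple(cc) for cc in d["insert_centers"])
        d["insert_densities"] = tuple(d["insert_densities"])
    return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _tuplify(c: dict) -> dict:
    c = dict(c)
    c["center"] = tuple(c["center"])
    if isinstance(c.get("size"), list):
        c["size"] = tuple(c["size"])
    if c.get("z_range") is not None:
        c["z_range"] = tuple(c["z_range"])
    return c
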