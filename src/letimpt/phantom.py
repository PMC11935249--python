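"""Synthetic pelvis phantom: voxel grid, ROI masks, STV expansion, beams.

The phantom emulates a localized-prostate planning geometry at desk scale:
a mostly water-equivalent elliptic body, an ellipsoidal CTV at the
isocenter, a bladder abutting anteriorly, a rectum (cylinder along the
superior-inferior axis) abutting posteriorly, and two lateral bone-like
ellipsoids sitting on the 270/90-degree beam paths so that lateral beams
traverse heterogeneity.

Coordinate conventions
----------------------
World axes in mm: +x = patient left, +y = posterior, +z = superior.
Arrays are indexed ``[ix, iy, iz]``; world coordinates refer to voxel
centers; a voxel belongs to an ROI iff its center satisfies the shape
predicate.  Gantry angles are IEC-style coplanar: 0 deg enters from
anterior (travels +y), 90 deg from the patient's left (travels -x),
270 deg from the right (travels +x).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """ROI placement incompatible with the grid or the body."""


class ValidationError(ValueError):
    """Structure-set invariant violated."""


# ---------------------------------------------------------------------------
# grid and volumes


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: dims (nx, ny, nz), spacing and origin in mm.

    ``origin`` is the world coordinate of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError("dims must be three integers >= 1")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive numbers")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis, mm."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        return np.meshgrid(xs, ys, zs, indexing="ij")

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corner of the voxelized volume (voxel faces)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.dims) * np.asarray(self.spacing)
        return lo, hi

    def contains_point(self, point_mm) -> bool:
        lo, hi = self.world_bounds()
        p = np.asarray(point_mm, float)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass
class DensityMap:
    """Per-voxel mass density in g/cc (water = 1.0), strictly positive."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError("density shape does not match grid dims")
        if not np.all(self.values > 0):
            raise ValueError("densities must be strictly positive")


ROI_NAMES = ("body", "ctv", "stv", "rectum", "bladder", "bone_left", "bone_right")


@dataclass
class StructureSet:
    """Named binary ROI masks sharing one grid."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def validate(self) -> None:
        for name, mask in self.masks.items():
            if mask.shape != tuple(self.grid.dims):
                raise ValidationError(f"mask {name!r} shape mismatch")
            if mask.dtype != bool:
                raise ValidationError(f"mask {name!r} must be boolean")
        for name in ("body", "ctv", "stv", "rectum", "bladder"):
            if name in self.masks and not self.masks[name].any():
                raise ValidationError(f"mask {name!r} is empty")
        ctv, stv, body = self.masks["ctv"], self.masks["stv"], self.masks["body"]
        if np.any(ctv & ~stv):
            raise ValidationError("CTV must be contained in STV")
        if np.any(stv & ~body):
            raise ValidationError("STV must be contained in body")
        if np.any(ctv & self.masks["rectum"]):
            raise ValidationError("CTV overlaps rectum")
        if np.any(ctv & self.masks["bladder"]):
            raise ValidationError("CTV overlaps bladder")

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_cc

    def centroid(self, name: str) -> np.ndarray:
        """World-coordinate centroid of a mask, mm."""
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValidationError(f"mask {name!r} is empty")
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(
            self.grid.spacing
        )


# ---------------------------------------------------------------------------
# beams and prescription


@dataclass(frozen=True)
class BeamConfig:
    """One coplanar beam: IEC gantry angle, isocenter (mm), source distance."""

    gantry_angle_deg: float
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_distance_mm: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.gantry_angle_deg < 360.0:
            raise ValueError("gantry angle must lie in [0, 360)")

    @property
    def direction(self) -> np.ndarray:
        """Unit beam travel direction in world coordinates."""
        th = np.deg2rad(self.gantry_angle_deg)
        return np.array([-np.sin(th), np.cos(th), 0.0])

    @property
    def bev_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Beam's-eye-view lateral unit axes (u in transverse plane, v = SI)."""
        th = np.deg2rad(self.gantry_angle_deg)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return u, v


@dataclass(frozen=True)
class PrescriptionSpec:
    """Prescribed RBE-weighted dose: 78 Gy(RBE) in 39 fractions, RBE 1.1."""

    total_dose_gy_rbe: float = 78.0
    n_fractions: int = 39
    rbe_constant: float = 1.1

    def __post_init__(self):
        if self.total_dose_gy_rbe <= 0:
            raise ValueError("total dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("need at least one fraction")
        if self.rbe_constant <= 0:
            raise ValueError("RBE must be positive")


#: Coplanar gantry angles per plan id (2, 4, 6 and 9 beams).
PLAN_BEAM_ANGLES = {
    1: (270.0, 90.0),
    2: (270.0, 90.0, 140.0, 220.0),
    3: (270.0, 90.0, 140.0, 220.0, 35.0, 325.0),
    4: (20.0, 60.0, 100.0, 140.0, 180.0, 220.0, 260.0, 300.0, 340.0),
}


def beam_arrangement(plan_id: int, isocenter_mm=(0.0, 0.0, 0.0)) -> list[BeamConfig]:
    """The four standard beam arrangements (2/4/6/9 coplanar fields)."""
    if plan_id not in PLAN_BEAM_ANGLES:
        raise ValueError(f"plan_id must be one of {sorted(PLAN_BEAM_ANGLES)}")
    iso = tuple(float(c) for c in isocenter_mm)
    return [BeamConfig(a, iso) for a in PLAN_BEAM_ANGLES[plan_id]]


# ---------------------------------------------------------------------------
# anisotropic expansion

#: margin key applicable to a positive / negative offset along each axis
_MARGIN_KEYS = (("left", "right"), ("posterior", "anterior"), ("superior", "inferior"))


def expand_structure(mask: np.ndarray, margins_mm: dict, grid: VoxelGrid) -> np.ndarray:
    """Anisotropically expand a binary mask by per-direction margins (mm).

    A voxel v belongs to the expansion iff some source voxel u satisfies
    sum_axis (delta_axis / m_axis)^2 <= 1, where delta is the world offset
    v - u and m_axis is the margin applicable to the sign of delta along
    that axis (octant-wise asymmetric ellipsoid, the common TPS
    convention).  Margin keys: left/right (+x/-x), anterior/posterior
    (-y/+y), superior/inferior (+z/-z).  The result always contains the
    input.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("cannot expand an empty mask")
    missing = {k for pair in _MARGIN_KEYS for k in pair} - set(margins_mm)
    if missing:
        raise ValueError(f"missing margins: {sorted(missing)}")
    if any(margins_mm[k] < 0 for pair in _MARGIN_KEYS for k in pair):
        raise ValueError("margins must be nonnegative")

    spacing = np.asarray(grid.spacing, float)
    half = [int(np.floor(max(margins_mm[pos], margins_mm[neg]) / spacing[a]))
            for a, (pos, neg) in enumerate(_MARGIN_KEYS)]
    offsets = np.meshgrid(
        *(np.arange(-h, h + 1) for h in half), indexing="ij", sparse=False
    )
    total = np.zeros(offsets[0].shape, float)
    for a, (pos_key, neg_key) in enumerate(_MARGIN_KEYS):
        delta_mm = offsets[a] * spacing[a]
        m = np.where(delta_mm > 0, margins_mm[pos_key], margins_mm[neg_key])
        term = np.zeros_like(delta_mm, dtype=float)
        nz = delta_mm != 0
        with np.errstate(divide="ignore", invalid="ignore"):
            term[nz] = np.where(
                m[nz] > 0, (delta_mm[nz] / np.where(m[nz] > 0, m[nz], 1.0)) ** 2, np.inf
            )
        total += term
    struct = total <= 1.0 + 1e-12
    return ndimage.binary_dilation(mask, structure=struct)


# ---------------------------------------------------------------------------
# phantom construction

#: STV-CTV expansion margins, mm: 1.2 cm laterally, 0.5 cm superior and
#: inferior, 0.6 cm anterior, 0.4 cm posterior.
DEFAULT_STV_MARGINS_MM = {
    "left": 12.0,
    "right": 12.0,
    "anterior": 6.0,
    "posterior": 4.0,
    "superior": 5.0,
    "inferior": 5.0,
}


@dataclass
class PhantomConfig:
    """Parameters of the synthetic pelvis phantom (all lengths in mm)."""

    dims: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_semiaxes_mm: tuple[float, float] = (75.0, 65.0)  # elliptic cylinder, x/y
    water_density: float = 1.0
    outside_density: float = 0.001
    ctv_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ctv_semiaxes_mm: tuple[float, float, float] = (20.0, 18.0, 18.0)
    bladder_semiaxes_mm: tuple[float, float, float] = (25.0, 20.0, 20.0)
    bladder_gap_mm: float = 1.0
    rectum_radius_mm: float = 12.0
    rectum_length_mm: float = 90.0
    rectum_gap_mm: float = 1.0
    bones: bool = True
    bone_center_x_mm: float = 55.0
    bone_semiaxes_mm: tuple[float, float, float] = (15.0, 25.0, 45.0)
    bone_density: float = 1.5
    stv_margins_mm: dict = field(default_factory=lambda: dict(DEFAULT_STV_MARGINS_MM))
    prescription: PrescriptionSpec = field(default_factory=PrescriptionSpec)

    def grid(self) -> VoxelGrid:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(-(d - 1) * s / 2.0 for d, s in zip(dims, spacing))
        return VoxelGrid(dims, spacing, origin)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stv_margins_mm"] = dict(self.stv_margins_mm)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "prescription" in d and isinstance(d["prescription"], dict):
            d["prescription"] = PrescriptionSpec(**d["prescription"])
        for key in ("dims", "spacing_mm", "body_semiaxes_mm", "ctv_center_mm",
                    "ctv_semiaxes_mm", "bladder_semiaxes_mm", "bone_semiaxes_mm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _ellipsoid_mask(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    q = (
        ((xs[:, None, None] - cx) / ax) ** 2
        + ((ys[None, :, None] - cy) / ay) ** 2
        + ((zs[None, None, :] - cz) / az) ** 2
    )
    return q <= 1.0


def _check_inside_grid(grid: VoxelGrid, center_mm, halfwidths_mm, name: str) -> None:
    lo, hi = grid.world_bounds()
    c = np.asarray(center_mm, float)
    h = np.asarray(halfwidths_mm, float)
    if np.any(c - h < lo) or np.any(c + h > hi):
        raise GeometryError(f"{name} extends outside the grid")


def build_phantom(config: PhantomConfig | None = None):
    """Construct (VoxelGrid, DensityMap, StructureSet) from a config.

    Deterministic: identical configs give bitwise-identical masks.
    """
    cfg = config or PhantomConfig()
    grid = cfg.grid()
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))

    # body: elliptic cylinder along z
    bx, by = cfg.body_semiaxes_mm
    body = (
        (xs[:, None, None] / bx) ** 2 + (ys[None, :, None] / by) ** 2
        <= 1.0 + 0.0 * zs[None, None, :]
    )
    _check_inside_grid(grid, (0, 0, 0), (bx, by, 0.0), "body")

    ctv_c = np.asarray(cfg.ctv_center_mm, float)
    _check_inside_grid(grid, ctv_c, cfg.ctv_semiaxes_mm, "CTV")
    ctv = _ellipsoid_mask(grid, ctv_c, cfg.ctv_semiaxes_mm)

    bl_c = ctv_c + np.array(
        [0.0, -(cfg.ctv_semiaxes_mm[1] + cfg.bladder_semiaxes_mm[1] + cfg.bladder_gap_mm), 0.0]
    )
    _check_inside_grid(grid, bl_c, cfg.bladder_semiaxes_mm, "bladder")
    bladder = _ellipsoid_mask(grid, bl_c, cfg.bladder_semiaxes_mm)

    re_c = ctv_c + np.array(
        [0.0, cfg.ctv_semiaxes_mm[1] + cfg.rectum_radius_mm + cfg.rectum_gap_mm, 0.0]
    )
    _check_inside_grid(
        grid, re_c, (cfg.rectum_radius_mm, cfg.rectum_radius_mm, 0.0), "rectum"
    )
    half_len = cfg.rectum_length_mm / 2.0
    rectum = (
        ((xs[:, None, None] - re_c[0]) / cfg.rectum_radius_mm) ** 2
        + ((ys[None, :, None] - re_c[1]) / cfg.rectum_radius_mm) ** 2
        <= 1.0
    ) & (np.abs(zs[None, None, :] - re_c[2]) <= half_len)

    if np.any(ctv & rectum):
        raise ValidationError("rectum placement overlaps the CTV")
    if np.any(ctv & bladder):
        raise ValidationError("bladder placement overlaps the CTV")

    density = np.where(body, cfg.water_density, cfg.outside_density)
    masks = {"body": body, "ctv": ctv, "rectum": rectum & body, "bladder": bladder & body}

    if cfg.bones:
        for sign, name in ((-1.0, "bone_right"), (1.0, "bone_left")):
            c = ctv_c + np.array([sign * cfg.bone_center_x_mm, 0.0, 0.0])
            _check_inside_grid(grid, c, cfg.bone_semiaxes_mm, name)
            bone = _ellipsoid_mask(grid, c, cfg.bone_semiaxes_mm) & body
            if np.any(bone & ctv):
                raise ValidationError(f"{name} overlaps the CTV")
            density = np.where(bone, cfg.bone_density, density)
            masks[name] = bone
    else:
        masks["bone_left"] = np.zeros(grid.dims, bool)
        masks["bone_right"] = np.zeros(grid.dims, bool)

    masks["stv"] = expand_structure(ctv, cfg.stv_margins_mm, grid) & body
    structures = StructureSet(grid, masks)
    structures.validate()
    return grid, DensityMap(grid, density), structures


# ---------------------------------------------------------------------------
# volume I/O (NRRD via SimpleITK; arrays are [x, y, z], ITK wants [z, y, x])


def write_volume(path, grid: VoxelGrid, values: np.ndarray) -> None:
    import SimpleITK as sitk

    arr = np.ascontiguousarray(np.transpose(np.asarray(values), (2, 1, 0)))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    grid = VoxelGrid(tuple(int(d) for d in img.GetSize()),
                     tuple(float(s) for s in img.GetSpacing()),
                     tuple(float(o) for o in img.GetOrigin()))
    return grid, values
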