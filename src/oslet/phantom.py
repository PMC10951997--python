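"""Synthetic head-and-neck voxel phantom and inter-fraction change scenarios.

The anthropomorphic phantom is reduced to parametric primitives on a regular
voxel grid: an ellipsoidal soft-tissue body, two box-shaped nasal cavities that
can be filled with mucus-equivalent material or drained to air, a cylindrical
tissue-equivalent rod channel carrying seven 3-mm OSL detector disks, and an
optional fat shell around the neck.  Densities are authored directly in g/cm3
(no CT/HU calibration); everything downstream consumes only the density grid
and the named structure masks.

Axes: x = lateral (left-right), y = anterior->posterior (beam axis of the 0
degree field), z = inferior->superior.  The axial plane is an (x, y) plane.
Voxel (0,0,0) has its center at ``origin``; world positions are voxel centers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

AIR_DENSITY = 0.0012  # g/cm3
SOFT_TISSUE_DENSITY = 1.00  # g/cm3, also mucus-equivalent filling
FAT_DENSITY = 0.92  # g/cm3

SCENARIO_KINDS = ("nominal", "fat_layer", "lateral_shift", "half_cavities", "empty_cavities")


@dataclass
class OsldLayout:
    """Placement of the seven detector disks on one axial plane.

    ``area_weights`` holds, per disk, the fractional in-plane overlap of each
    grid voxel (same 2-D shape as an axial slice) with the physical 3-mm disk,
    obtained by supersampling; detector readouts are area means over these
    weights while the boolean masks are used for geometry checks.
    """

    centers: np.ndarray  # (n, 3) world mm
    disk_radius_mm: float
    slice_index: int
    area_weights: list = field(default_factory=list)  # per disk: (idx_x, idx_y, frac)


@dataclass
class VoxelPhantom:
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, center of voxel (0,0,0)
    density: np.ndarray  # (nx,ny,nz) g/cm3
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    osld_layout: OsldLayout | None = None

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative everywhere")
        for name, m in self.masks.items():
            if m.shape != self.density.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != grid {self.density.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (…,3) -> world positions of voxel centers (mm)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            density=self.density.copy(),
            masks={k: v.copy() for k, v in self.masks.items()},
            osld_layout=dataclasses.replace(self.osld_layout) if self.osld_layout else None,
        )


@dataclass
class Scenario:
    """One Table-style fraction geometry change relative to the reference.

    nominal        identity
    fat_layer      10 mm fat shell around the neck slab + a rigid offset and
                   roll of the whole phantom (the head pivots on the neck
                   when the shell is added, displacing the detector plane)
    lateral_shift  rigid 10 mm translation along x
    half_cavities  posterior half of the nasal cavity fillings drained to air
    empty_cavities all cavity fillings drained to air
    """

    kind: str = "nominal"
    shift_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    layer_thickness_mm: float = 10.0
    # repositioning error induced by the fat shell: lateral + anterior offset
    # and a roll about the neck, comparable to the 1 cm shift fraction
    offset_mm: np.ndarray = field(default_factory=lambda: np.array([6.0, 4.0, 0.0]))
    tilt_deg: float = 3.0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        self.shift_mm = np.asarray(self.shift_mm, dtype=float)
        self.offset_mm = np.asarray(self.offset_mm, dtype=float)
        if self.kind == "lateral_shift" and not np.any(self.shift_mm):
            self.shift_mm = np.array([10.0, 0.0, 0.0])


@dataclass
class GridConfig:
    spacing_mm: float = 2.0
    extent_mm: tuple[float, float, float] = (200.0, 220.0, 160.0)
    body_center: tuple[float, float, float] = (100.0, 120.0, 85.0)
    body_semiaxes: tuple[float, float, float] = (72.0, 82.0, 68.0)
    # two nasal cavities (boxes) on either side of a septum, along the beam path
    cavity_x = ((86.0, 97.0), (103.0, 114.0))
    cavity_y = (60.0, 90.0)
    cavity_z = (70.0, 100.0)
    ctv_box: tuple = ((86.0, 114.0), (100.0, 124.0), (71.0, 99.0))
    ptv_margin_mm: float = 2.0
    rod_center_xy: tuple[float, float] = (100.0, 112.0)
    rod_radius_mm: float = 8.0
    rod_z: tuple[float, float] = (17.0, 86.0)


@dataclass
class OsldLayoutConfig:
    circle_radius_mm: float = 6.0
    disk_radius_mm: float = 1.5
    n_ring: int = 6
    plane_z_mm: float = 85.0
    roi_radius_mm: float | None = None  # None: tight enclosing radius

    def effective_roi_radius(self) -> float:
        """Radius of the single-slice evaluation contour: the smallest circle
        encompassing all seven disks (7.5 mm for the default layout)."""
        if self.roi_radius_mm is not None:
            return self.roi_radius_mm
        return self.circle_radius_mm + self.disk_radius_mm


def _grid_axes(cfg: GridConfig):
    spacing = np.full(3, cfg.spacing_mm)
    shape = tuple(int(round(e / cfg.spacing_mm)) for e in cfg.extent_mm)
    origin = spacing / 2.0
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return spacing, origin, shape, axes


def dilate_mask(mask: np.ndarray, margin_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Isotropic dilation by a euclidean margin (mm), exact on voxel centers."""
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm + 1e-9


def build_phantom(grid_config: GridConfig | None = None) -> VoxelPhantom:
    """Build the nominal phantom: body, filled cavities, rod channel, CTV/PTV."""
    cfg = grid_config or GridConfig()
    if not (1.0 <= cfg.spacing_mm <= 3.0):
        raise ValueError("grid spacing must be between 1 and 3 mm (3-mm disks must be resolvable)")
    if min(cfg.extent_mm) < 160.0:
        raise ValueError("grid extent must be at least 160 mm per axis")

    spacing, origin, shape, (xs, ys, zs) = _grid_axes(cfg)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    cx, cy, cz = cfg.body_center
    ax, ay, az = cfg.body_semiaxes
    body = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    cavities = np.zeros(shape, dtype=bool)
    for x0, x1 in cfg.cavity_x:
        cavities |= (
            (X >= x0) & (X <= x1)
            & (Y >= cfg.cavity_y[0]) & (Y <= cfg.cavity_y[1])
            & (Z >= cfg.cavity_z[0]) & (Z <= cfg.cavity_z[1])
        )
    cavities &= body

    rx, ry = cfg.rod_center_xy
    rod = ((X - rx) ** 2 + (Y - ry) ** 2 <= cfg.rod_radius_mm**2) & (Z >= cfg.rod_z[0]) & (Z <= cfg.rod_z[1])
    rod &= body

    (x0, x1), (y0, y1), (z0, z1) = cfg.ctv_box
    ctv = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & (Z >= z0) & (Z <= z1)
    ctv &= body
    ptv = dilate_mask(ctv, cfg.ptv_margin_mm, spacing)
    ptv &= body

    density = np.where(body, SOFT_TISSUE_DENSITY, AIR_DENSITY).astype(np.float32)
    # nominal anatomy: cavities filled with mucus-equivalent material (= soft tissue)

    masks = {
        "body": body,
        "cavities": cavities,
        "rod_channel": rod,
        "ctv": ctv,
        "ptv": ptv,
        "fat_layer": np.zeros(shape, dtype=bool),
    }
    return VoxelPhantom(spacing=spacing, origin=origin, density=density, masks=masks)


def _rigid_transform(phantom: VoxelPhantom, translation_mm: np.ndarray,
                     tilt_deg: float = 0.0, pivot_mm: np.ndarray | None = None) -> VoxelPhantom:
    """Rigid move of density and all masks: linear interpolation for density,
    nearest neighbor for masks (keeps masks crisp, approximately conserves mass)."""
    t = np.asarray(translation_mm, dtype=float)
    out = phantom.copy()
    if tilt_deg == 0.0 and pivot_mm is None:
        shift_vox = t / phantom.spacing
        out.density = ndimage.shift(phantom.density, shift_vox, order=1, cval=AIR_DENSITY,
                                    prefilter=False).astype(np.float32)
        for k, m in phantom.masks.items():
            out.masks[k] = ndimage.shift(m.astype(np.uint8), shift_vox, order=0, cval=0).astype(bool)
    else:
        th = np.deg2rad(tilt_deg)
        # roll about the anterior-posterior (y) axis
        R = np.array([[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]])
        Rinv = R.T
        c = np.asarray(pivot_mm, dtype=float)
        sp, o = phantom.spacing, phantom.origin
        A = np.diag(1.0 / sp) @ Rinv @ np.diag(sp)
        b = (Rinv @ (o - c - t) + c - o) / sp
        out.density = ndimage.affine_transform(phantom.density, A, offset=b, order=1,
                                               cval=AIR_DENSITY, prefilter=False).astype(np.float32)
        for k, m in phantom.masks.items():
            out.masks[k] = ndimage.affine_transform(m.astype(np.uint8), A, offset=b,
                                                    order=0, cval=0).astype(bool)
    if out.osld_layout is not None:
        lay = out.osld_layout
        if tilt_deg == 0.0 and pivot_mm is None:
            lay.centers = lay.centers + t
        else:
            th = np.deg2rad(tilt_deg)
            R = np.array([[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]])
            c = np.asarray(pivot_mm, dtype=float)
            lay.centers = (R @ (lay.centers - c).T).T + c + t
        _attach_area_weights(out, lay)
    return out


def _check_body_inside(phantom: VoxelPhantom, shift_mm: np.ndarray) -> None:
    body = phantom.masks["body"]
    idx = np.argwhere(body)
    lo = phantom.world_coords(idx.min(axis=0)) + shift_mm
    hi = phantom.world_coords(idx.max(axis=0)) + shift_mm
    gmin = phantom.origin - phantom.spacing / 2
    gmax = phantom.world_coords(np.array(phantom.shape) - 1) + phantom.spacing / 2
    if np.any(lo < gmin) or np.any(hi > gmax):
        raise ValueError("scenario shift pushes the body outside the grid")


def apply_scenario(phantom: VoxelPhantom, scenario: Scenario) -> VoxelPhantom:
    """Apply one fraction scenario; the input phantom is left untouched."""
    kind = scenario.kind
    if kind == "nominal":
        return phantom.copy()

    if kind == "lateral_shift":
        _check_body_inside(phantom, scenario.shift_mm)
        return _rigid_transform(phantom, scenario.shift_mm)

    if kind in ("half_cavities", "empty_cavities"):
        out = phantom.copy()
        cav = phantom.masks["cavities"]
        if kind == "half_cavities":
            # drain starting from the most posterior section (largest y)
            ys = np.unique(np.argwhere(cav)[:, 1])
            y_cut = ys[len(ys) // 2]
            drained = cav & (np.arange(phantom.shape[1])[None, :, None] >= y_cut)
        else:
            drained = cav
        out.density[drained] = AIR_DENSITY
        return out

    if kind == "fat_layer":
        out = phantom.copy()
        body = phantom.masks["body"]
        shell = dilate_mask(body, scenario.layer_thickness_mm, phantom.spacing) & ~body
        zs = phantom.origin[2] + phantom.spacing[2] * np.arange(phantom.shape[2])
        cfg_lo, cfg_hi = _neck_slab_from_body(phantom)
        slab = (zs >= cfg_lo) & (zs <= cfg_hi)
        shell &= slab[None, None, :]
        out.density[shell] = FAT_DENSITY
        out.masks["fat_layer"] = shell
        out.masks["body"] = body | shell
        # the added shell pivots the phantom on the neck: small offset + roll
        idx = np.argwhere(body)
        pivot = phantom.world_coords(idx.mean(axis=0))
        pivot[2] = phantom.world_coords(idx.min(axis=0))[2]  # inferior end
        _check_body_inside(out, scenario.offset_mm)
        return _rigid_transform(out, scenario.offset_mm, tilt_deg=scenario.tilt_deg, pivot_mm=pivot)

    raise ValueError(f"unknown scenario kind {kind!r}")  # pragma: no cover


def _neck_slab_from_body(phantom: VoxelPhantom) -> tuple[float, float]:
    """Inferior axial slab ('neck area') = lower quarter of the body extent."""
    idx = np.argwhere(phantom.masks["body"])
    z_lo = phantom.world_coords(idx.min(axis=0))[2]
    z_hi = phantom.world_coords(idx.max(axis=0))[2]
    return z_lo, z_lo + 0.28 * (z_hi - z_lo)


def _disk_area_fractions(phantom: VoxelPhantom, center_xy: np.ndarray, radius: float,
                         subsamples: int = 5):
    """Supersampled in-plane overlap fraction of each voxel with a disk."""
    sp, o = phantom.spacing, phantom.origin
    nx, ny = phantom.shape[0], phantom.shape[1]
    i0 = max(int((center_xy[0] - radius - o[0]) / sp[0]) - 1, 0)
    i1 = min(int((center_xy[0] + radius - o[0]) / sp[0]) + 2, nx)
    j0 = max(int((center_xy[1] - radius - o[1]) / sp[1]) - 1, 0)
    j1 = min(int((center_xy[1] + radius - o[1]) / sp[1]) + 2, ny)
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    idx_x, idx_y, fracs = [], [], []
    for i in range(i0, i1):
        for j in range(j0, j1):
            xc = o[0] + i * sp[0] + offs * sp[0]
            yc = o[1] + j * sp[1] + offs * sp[1]
            XX, YY = np.meshgrid(xc, yc, indexing="ij")
            inside = (XX - center_xy[0]) ** 2 + (YY - center_xy[1]) ** 2 <= radius**2
            f = inside.mean()
            if f > 0:
                idx_x.append(i)
                idx_y.append(j)
                fracs.append(f)
    return np.array(idx_x), np.array(idx_y), np.array(fracs)


def _attach_area_weights(phantom: VoxelPhantom, layout: OsldLayout) -> None:
    layout.slice_index = int(round((layout.centers[0, 2] - phantom.origin[2]) / phantom.spacing[2]))
    layout.area_weights = [
        _disk_area_fractions(phantom, c[:2], layout.disk_radius_mm) for c in layout.centers
    ]


def place_osld_roi(phantom: VoxelPhantom, layout_config: OsldLayoutConfig | None = None) -> VoxelPhantom:
    """Place seven 3-mm detector disks (one central, six on a circle) on one
    axial plane inside the PTV, and the single-slice ROI contour enclosing them."""
    cfg = layout_config or OsldLayoutConfig()
    if cfg.circle_radius_mm < 3.0:
        raise ValueError("layout circle radius must be at least 3 mm")
    if "rod_channel" not in phantom.masks or not phantom.masks["rod_channel"].any():
        raise ValueError("phantom has no rod channel to carry the detectors")

    out = phantom.copy()
    rod = np.argwhere(phantom.masks["rod_channel"])
    center_xy = phantom.world_coords(rod.mean(axis=0))[:2]
    zc = cfg.plane_z_mm
    k = int(round((zc - phantom.origin[2]) / phantom.spacing[2]))

    centers = [np.array([center_xy[0], center_xy[1], zc])]
    for m in range(cfg.n_ring):
        ang = 2 * np.pi * m / cfg.n_ring
        centers.append(np.array([center_xy[0] + cfg.circle_radius_mm * np.cos(ang),
                                 center_xy[1] + cfg.circle_radius_mm * np.sin(ang), zc]))
    centers = np.array(centers)

    sp, o = phantom.spacing, phantom.origin
    xs = o[0] + sp[0] * np.arange(phantom.shape[0])
    ys = o[1] + sp[1] * np.arange(phantom.shape[1])
    XX, YY = np.meshgrid(xs, ys, indexing="ij")

    ptv = phantom.masks["ptv"]
    for n, c in enumerate(centers, start=1):
        disk2d = (XX - c[0]) ** 2 + (YY - c[1]) ** 2 <= cfg.disk_radius_mm**2
        mask = np.zeros(phantom.shape, dtype=bool)
        mask[:, :, k] = disk2d
        if not np.all(ptv[mask]):
            raise ValueError(f"detector disk {n} extends outside the PTV")
        out.masks[f"osld_disk_{n}"] = mask

    roi_r = cfg.effective_roi_radius()
    roi2d = (XX - center_xy[0]) ** 2 + (YY - center_xy[1]) ** 2 <= roi_r**2
    roi = np.zeros(phantom.shape, dtype=bool)
    roi[:, :, k] = roi2d
    out.masks["osld_roi"] = roi

    layout = OsldLayout(centers=centers, disk_radius_mm=cfg.disk_radius_mm, slice_index=k)
    _attach_area_weights(out, layout)
    out.osld_layout = layout
    return out
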