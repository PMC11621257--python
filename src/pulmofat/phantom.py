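"""Synthetic chest-CT phantoms with analytically known ground truth.

The phantom is a deliberately simple geometric stand-in for a chest CT:
two ellipsoidal "lungs" filled with aerated parenchyma (default -850 +/- 30
HU, far below the fat window), embedded in soft tissue (+40 HU), with
optional cylindrical "vessels" (+50 HU) and spherical fat inclusions
(-100 HU) of exactly known analytic volume.  Lobes are assigned by axial
cuts through each lung at configurable fractional heights.  Everything is
rasterized by voxel-center inclusion: a voxel belongs to a shape iff its
center does, which gives a provable surface-error bound on voxelized
volumes.

Ground truth is computed from the geometry equations only — sphere volumes,
ellipsoid membership, analytic distance to the lung surface — never from
the HU image, so agreement between the quantification pipeline and the
ground truth is a genuine two-implementation cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import PlacementError
from .io_volumes import DEFAULT_LOBE_LABELS, ImageVolume, LabelMask
from .quantify import voxel_volume_ml

__all__ = [
    "Ellipsoid",
    "FatSphere",
    "Cylinder",
    "LobePlan",
    "Placement",
    "PhantomSpec",
    "GroundTruth",
    "GroupProfile",
    "DEFAULT_GROUP_PROFILES",
    "default_spec",
    "single_sphere_spec",
    "generate_phantom",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# geometry primitives


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership of points (..., 3) by the ellipsoid inequality."""
        q = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (q * q).sum(axis=-1) <= 1.0

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(a * factor for a in self.semi_axes))

    @property
    def volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def surface_distance(self, p) -> float:
        """Exact Euclidean distance from a point to the ellipsoid surface.

        Solves the Lagrange condition sum((a_i q_i / (a_i^2 + t))^2) = 1 for
        the unique root t in (-a_min^2, inf); works for interior and exterior
        points alike.
        """
        a = np.asarray(self.semi_axes, float)
        q = np.asarray(p, float) - np.asarray(self.center, float)
        if np.linalg.norm(q) < 1e-12:
            return float(a.min())
        # degenerate on-axis points make the bracket endpoint singular; nudge
        q = np.where(np.abs(q) < 1e-9, 1e-9, q)

        def f(t: float) -> float:
            return float(np.sum((a * q / (a * a + t)) ** 2) - 1.0)

        lo = -float(a.min()) ** 2
        t_lo = lo + 1e-9 * max(1.0, abs(lo))
        while f(t_lo) < 0:  # pathological rounding near the pole
            t_lo = lo + (t_lo - lo) / 10.0
            if t_lo - lo < 1e-15:
                break
        t_hi = max(1.0, float(a.max()) ** 2)
        while f(t_hi) > 0:
            t_hi *= 4.0
        t_star = brentq(f, t_lo, t_hi, xtol=1e-10, rtol=1e-14)
        x = a * a * q / (a * a + t_star)
        return float(np.linalg.norm(x - q))


@dataclass(frozen=True)
class FatSphere:
    """Spherical fat inclusion; ``center=None`` requests random placement."""

    radius_mm: float
    center: tuple[float, float, float] | None = None
    hu: float = -100.0

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder (vessel surrogate) between two endpoints, mm."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_mm: float
    hu: float = 50.0


@dataclass(frozen=True)
class LobePlan:
    """Axial-cut lobe assignment as fractions of each lung's z-extent.

    The left lung splits at ``left_cut_frac`` into LLL (below) and LUL
    (above); the right lung splits at the two ``right_cut_fracs`` into
    RLL / RML / RUL from bottom to top.
    """

    left_cut_frac: float = 0.5
    right_cut_fracs: tuple[float, float] = (0.35, 0.65)


@dataclass(frozen=True)
class Placement:
    """Optional constraint on randomly placed fat spheres.

    Exactly one of the fields is typically set: keep the entire sphere within
    ``subpleural_within_mm`` of the lung surface, keep it entirely deeper
    than ``deeper_than_mm``, or confine it to a named lobe.
    """

    subpleural_within_mm: float | None = None
    deeper_than_mm: float | None = None
    lobe: str | None = None


# ---------------------------------------------------------------------------
# phantom specification


def _default_lungs() -> tuple[Ellipsoid, Ellipsoid]:
    return (
        Ellipsoid(center=(30.0, 48.0, 48.0), semi_axes=(16.0, 22.0, 34.0)),  # left
        Ellipsoid(center=(66.0, 48.0, 48.0), semi_axes=(16.0, 22.0, 34.0)),  # right
    )


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom.

    Defaults give a desk-scale thorax: a 64^3 grid at 1.5 mm isotropic
    spacing holding two ~50 mL ellipsoidal lungs (~100 mL total).  HU
    defaults keep parenchyma and soft tissue at least 4 effective noise
    standard deviations outside the fat window so spurious fat voxels are
    negligible.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    lung_geometry: tuple[Ellipsoid, Ellipsoid] = field(default_factory=_default_lungs)
    lobe_plan: LobePlan = field(default_factory=LobePlan)
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 30.0
    soft_tissue_hu: float = 40.0
    vessel_set: tuple[Cylinder, ...] | None = None  # None -> one axial vessel per lung
    fat_set: tuple[FatSphere, ...] = ()
    placement: Placement | None = None
    noise_sd: float = 0.0
    seed: int = 0
    fat_window_lower: float = -200.0
    fat_window_upper: float = -60.0

    def __post_init__(self) -> None:
        eff_sd = math.hypot(self.parenchyma_hu_sd, self.noise_sd)
        if self.parenchyma_hu_mean + 4 * eff_sd > self.fat_window_lower:
            raise ValueError(
                "parenchyma mean must sit at least 4 effective noise sd below the fat window"
            )
        if self.soft_tissue_hu - 4 * self.noise_sd < self.fat_window_upper:
            raise ValueError("soft tissue HU must sit at least 4 noise sd above the fat window")
        extent = tuple((n - 1) * s for n, s in zip(self.grid_shape, self.spacing))
        for e in self.lung_geometry:
            for c, a, ext in zip(e.center, e.semi_axes, extent):
                if c - a < 0 or c + a > ext:
                    raise ValueError(f"lung ellipsoid {e} exceeds the grid extent {extent} mm")

    def resolved_vessels(self) -> tuple[Cylinder, ...]:
        if self.vessel_set is not None:
            return tuple(self.vessel_set)
        out = []
        for e in self.lung_geometry:
            cx, cy, cz = e.center
            az = e.semi_axes[2]
            out.append(Cylinder((cx, cy, cz - 0.8 * az), (cx, cy, cz + 0.8 * az), 2.5))
        return tuple(out)


def default_spec(**overrides) -> PhantomSpec:
    """The package's reference phantom specification."""
    return PhantomSpec(**overrides)


def single_sphere_spec(radius_mm: float = 10.0, seed: int = 0) -> PhantomSpec:
    """A 1 mm-isotropic phantom with one noise-free fat sphere of known volume.

    The sphere sits at the left-lung center, whose distance to the lung
    surface equals the smallest semi-axis (14 mm), so any radius < 14 mm
    fits entirely inside aerated parenchyma.
    """
    lungs = (
        Ellipsoid(center=(21.0, 40.0, 40.0), semi_axes=(14.0, 22.0, 30.0)),
        Ellipsoid(center=(57.0, 40.0, 40.0), semi_axes=(14.0, 22.0, 30.0)),
    )
    if radius_mm >= lungs[0].semi_axes[0]:
        raise ValueError("sphere radius must be smaller than the smallest lung semi-axis")
    return PhantomSpec(
        grid_shape=(79, 81, 81),
        spacing=(1.0, 1.0, 1.0),
        lung_geometry=lungs,
        parenchyma_hu_sd=0.0,
        vessel_set=(),
        fat_set=(FatSphere(radius_mm=radius_mm, center=lungs[0].center),),
        noise_sd=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Geometry-derived reference volumes for one phantom.

    ``fat_volume_ml_analytic`` is the closed-form sum of sphere volumes;
    the voxelized quantities count voxel centers against the shape
    equations directly.  ``fat_surface_voxel_count`` counts voxels whose
    center lies within half a voxel diagonal of a sphere surface; the
    analytic-vs-voxelized discrepancy is bounded by that count times the
    voxel volume.  Compartment ground truth classifies fat voxel centers by
    analytic distance to the lung surface (<= ``depth_mm`` is subpleural).
    """

    fat_volume_ml_analytic: float
    fat_volume_ml_voxelized: float
    lung_volume_ml_voxelized: float
    fat_surface_voxel_count: int
    per_lobe_fat_ml: dict[str, float]
    per_compartment_fat_ml: dict[str, float]
    depth_mm: float = 10.0

    def to_dict(self) -> dict:
        return {
            "fat_volume_ml_analytic": self.fat_volume_ml_analytic,
            "fat_volume_ml_voxelized": self.fat_volume_ml_voxelized,
            "lung_volume_ml_voxelized": self.lung_volume_ml_voxelized,
            "fat_surface_voxel_count": self.fat_surface_voxel_count,
            "per_lobe_fat_ml": self.per_lobe_fat_ml,
            "per_compartment_fat_ml": self.per_compartment_fat_ml,
            "depth_mm": self.depth_mm,
        }


# ---------------------------------------------------------------------------
# rasterization helpers (voxel-center inclusion throughout)


def _axis_coords(spec: PhantomSpec):
    return tuple(
        np.arange(n, dtype=float) * s for n, s in zip(spec.grid_shape, spec.spacing)
    )


def _ellipsoid_grid_mask(e: Ellipsoid, axes) -> np.ndarray:
    x, y, z = axes
    qx = ((x - e.center[0]) / e.semi_axes[0]) ** 2
    qy = ((y - e.center[1]) / e.semi_axes[1]) ** 2
    qz = ((z - e.center[2]) / e.semi_axes[2]) ** 2
    return qx[:, None, None] + qy[None, :, None] + qz[None, None, :] <= 1.0


def _cylinder_grid_mask(cyl: Cylinder, axes) -> np.ndarray:
    x, y, z = axes
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    p0 = np.asarray(cyl.p0, float)
    v = np.asarray(cyl.p1, float) - p0
    L2 = float(v @ v)
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    t = (dx * v[0] + dy * v[1] + dz * v[2]) / L2
    inside_t = (t >= 0.0) & (t <= 1.0)
    rx = dx - t * v[0]
    ry = dy - t * v[1]
    rz = dz - t * v[2]
    return inside_t & (rx * rx + ry * ry + rz * rz <= cyl.radius_mm**2)


def _sphere_voxel_centers(sphere: FatSphere, spec: PhantomSpec):
    """Index triples and center coordinates of voxels inside the sphere."""
    c = np.asarray(sphere.center, float)
    r = sphere.radius_mm
    lo = [max(0, int(math.floor((c[d] - r) / spec.spacing[d]))) for d in range(3)]
    hi = [
        min(spec.grid_shape[d] - 1, int(math.ceil((c[d] + r) / spec.spacing[d])))
        for d in range(3)
    ]
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    I, J, K = np.meshgrid(*ranges, indexing="ij")
    pts = np.stack(
        [I * spec.spacing[0], J * spec.spacing[1], K * spec.spacing[2]], axis=-1
    )
    d2 = ((pts - c) ** 2).sum(axis=-1)
    sel = d2 <= r * r
    idx = np.stack([I[sel], J[sel], K[sel]], axis=-1)
    return idx, pts[sel], d2

def _sphere_surface_voxels(sphere: FatSphere, spec: PhantomSpec) -> int:
    """Voxels whose center is within half a voxel diagonal of the surface."""
    c = np.asarray(sphere.center, float)
    r = sphere.radius_mm
    h = 0.5 * math.sqrt(sum(s * s for s in spec.spacing))
    lo = [max(0, int(math.floor((c[d] - r - h) / spec.spacing[d]))) for d in range(3)]
    hi = [
        min(spec.grid_shape[d] - 1, int(math.ceil((c[d] + r + h) / spec.spacing[d])))
        for d in range(3)
    ]
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    I, J, K = np.meshgrid(*ranges, indexing="ij")
    pts = np.stack(
        [I * spec.spacing[0], J * spec.spacing[1], K * spec.spacing[2]], axis=-1
    )
    dist = np.sqrt(((pts - c) ** 2).sum(axis=-1))
    return int(np.count_nonzero(np.abs(dist - r) <= h))


# ---------------------------------------------------------------------------
# lobes


def _lobe_label_of_points(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Analytic lobe label (0 outside lung) of arbitrary points, (..., 3)."""
    left, right = spec.lung_geometry
    labels = np.zeros(pts.shape[:-1], dtype=np.int32)
    name_to_label = {v: k for k, v in DEFAULT_LOBE_LABELS.items()}

    in_left = left.contains(pts)
    zl0 = left.center[2] - left.semi_axes[2]
    z_cut = zl0 + spec.lobe_plan.left_cut_frac * 2 * left.semi_axes[2]
    z = pts[..., 2]
    labels[in_left & (z >= z_cut)] = name_to_label["LUL"]
    labels[in_left & (z < z_cut)] = name_to_label["LLL"]

    in_right = right.contains(pts)
    zr0 = right.center[2] - right.semi_axes[2]
    f1, f2 = spec.lobe_plan.right_cut_fracs
    z1 = zr0 + f1 * 2 * right.semi_axes[2]
    z2 = zr0 + f2 * 2 * right.semi_axes[2]
    labels[in_right & (z >= z2)] = name_to_label["RUL"]
    labels[in_right & (z >= z1) & (z < z2)] = name_to_label["RML"]
    labels[in_right & (z < z1)] = name_to_label["RLL"]
    return labels


def _lung_surface_distance(p, spec: PhantomSpec) -> float:
    """Analytic distance from a point to the lung (union) surface."""
    return min(e.surface_distance(p) for e in spec.lung_geometry)


# ---------------------------------------------------------------------------
# fat placement


def _check_sphere(
    sphere: FatSphere, placed: list[FatSphere], spec: PhantomSpec
) -> bool:
    c = np.asarray(sphere.center, float)
    inside = any(e.contains(c[None, :])[0] for e in spec.lung_geometry)
    if not inside:
        return False
    d_surf = _lung_surface_distance(c, spec)
    if d_surf < sphere.radius_mm:  # sphere must lie wholly inside the lung
        return False
    pl = spec.placement
    if pl is not None:
        if pl.subpleural_within_mm is not None and d_surf + sphere.radius_mm > pl.subpleural_within_mm:
            return False
        if pl.deeper_than_mm is not None and d_surf - sphere.radius_mm < pl.deeper_than_mm:
            return False
        if pl.lobe is not None:
            offsets = np.array(
                [(0, 0, 0), (0, 0, sphere.radius_mm), (0, 0, -sphere.radius_mm)]
            )
            if not (_lobe_label_of_points(c + offsets, spec) == _label_of_name(pl.lobe)).all():
                return False
    for other in placed:
        gap = np.linalg.norm(c - np.asarray(other.center, float))
        if gap < sphere.radius_mm + other.radius_mm:
            return False
    return True


def _label_of_name(name: str) -> int:
    for k, v in DEFAULT_LOBE_LABELS.items():
        if v == name:
            return k
    raise ValueError(f"unknown lobe name {name!r}")


def _sample_point_in_lungs(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    vols = np.array([e.volume_ml for e in spec.lung_geometry])
    e = spec.lung_geometry[rng.choice(len(vols), p=vols / vols.sum())]
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    r = rng.uniform() ** (1.0 / 3.0)
    return np.asarray(e.center) + r * u * np.asarray(e.semi_axes)


def _place_fat(spec: PhantomSpec, rng: np.random.Generator) -> list[FatSphere]:
    """Resolve fat-sphere centers: validate explicit ones, sample the rest."""
    placed: list[FatSphere] = []
    for sphere in spec.fat_set:
        if sphere.center is not None:
            if not _check_sphere(sphere, placed, spec):
                raise PlacementError(
                    f"explicit fat sphere at {sphere.center} r={sphere.radius_mm} mm violates "
                    "containment/placement/overlap constraints"
                )
            placed.append(sphere)
            continue
        ok = False
        for _ in range(2000):
            cand = replace(sphere, center=tuple(_sample_point_in_lungs(rng, spec)))
            if _check_sphere(cand, placed, spec):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place fat sphere r={sphere.radius_mm} mm under {spec.placement} "
                "after 2000 rejection-sampling attempts"
            )
    return placed


# ---------------------------------------------------------------------------
# generation


def generate_phantom(
    spec: PhantomSpec, depth_mm: float = 10.0, compute_compartment_gt: bool = True
) -> tuple[ImageVolume, LabelMask, LabelMask, GroundTruth]:
    """Rasterize a phantom: HU image, lung mask, lobe mask, and ground truth.

    The same spec and seed always produce bit-identical outputs.  Tissue is
    assigned in the order soft tissue -> parenchyma -> vessels -> fat, so fat
    inclusions always carry their nominal HU; i.i.d. Gaussian noise
    (``noise_sd``) is added last.
    """
    rng = np.random.default_rng(spec.seed)
    axes = _axis_coords(spec)

    lung = np.zeros(spec.grid_shape, dtype=bool)
    for e in spec.lung_geometry:
        lung |= _ellipsoid_grid_mask(e, axes)

    x, y, z = axes
    pts = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1)
    lobes = _lobe_label_of_points(pts, spec)
    lobes[~lung] = 0

    image = np.full(spec.grid_shape, spec.soft_tissue_hu, dtype=np.float64)
    paren = np.full(spec.grid_shape, spec.parenchyma_hu_mean)
    if spec.parenchyma_hu_sd > 0:
        paren = paren + spec.parenchyma_hu_sd * rng.standard_normal(spec.grid_shape)
    image[lung] = paren[lung]
    for cyl in spec.resolved_vessels():
        vm = _cylinder_grid_mask(cyl, axes) & lung
        image[vm] = cyl.hu

    fat_spheres = _place_fat(spec, rng)
    spec_placed = replace(spec, fat_set=tuple(fat_spheres))

    fat_vox = 0
    surface_vox = 0
    per_lobe_count: dict[str, int] = {}
    per_comp_count = {"subpleural": 0, "nonsubpleural": 0}
    for sphere in fat_spheres:
        idx, centers, _ = _sphere_voxel_centers(sphere, spec_placed)
        image[idx[:, 0], idx[:, 1], idx[:, 2]] = sphere.hu
        fat_vox += len(idx)
        surface_vox += _sphere_surface_voxels(sphere, spec_placed)
        lobe_labels = _lobe_label_of_points(centers, spec_placed)
        for lab in np.unique(lobe_labels):
            if lab == 0:
                continue
            name = DEFAULT_LOBE_LABELS[int(lab)]
            per_lobe_count[name] = per_lobe_count.get(name, 0) + int((lobe_labels == lab).sum())
        if compute_compartment_gt:
            for p in centers:
                key = (
                    "subpleural"
                    if _lung_surface_distance(p, spec_placed) <= depth_mm
                    else "nonsubpleural"
                )
                per_comp_count[key] += 1

    if spec.noise_sd > 0:
        image = image + spec.noise_sd * rng.standard_normal(spec.grid_shape)

    vv = voxel_volume_ml(spec.spacing)
    gt = GroundTruth(
        fat_volume_ml_analytic=sum(s.volume_ml for s in fat_spheres),
        fat_volume_ml_voxelized=fat_vox * vv,
        lung_volume_ml_voxelized=int(lung.sum()) * vv,
        fat_surface_voxel_count=surface_vox,
        per_lobe_fat_ml={k: v * vv for k, v in sorted(per_lobe_count.items())},
        per_compartment_fat_ml={k: v * vv for k, v in per_comp_count.items()},
        depth_mm=depth_mm,
    )
    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    volume = ImageVolume(image.astype(np.float32), **geom)
    lung_mask = LabelMask(lung.astype(np.uint8), label_map={1: "lung"}, **geom)
    lobe_mask = LabelMask(lobes, label_map=dict(DEFAULT_LOBE_LABELS), **geom)
    return volume, lung_mask, lobe_mask, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupProfile:
    """Sampling profile for one simulated cohort group.

    PFI targets and lung-size scales are lognormal: the median is the
    stated central value and ``*_log_sigma`` the standard deviation of the
    natural log.  ``lung_scale_median`` scales the template lung semi-axes
    linearly (volume scales with its cube).
    """

    pfi_median_pct: float
    pfi_log_sigma: float
    lung_scale_median: float = 1.0
    lung_scale_log_sigma: float = 0.0
    #: hard clips keeping sampled subjects rasterizable: lungs must stay on
    #: the grid and the fat load must remain packable as disjoint spheres
    lung_scale_bounds: tuple[float, float] = (0.7, 1.3)
    pfi_bounds_pct: tuple[float, float] = (0.05, 8.0)


#: Three-group design emulating a control / obstructive / fibrotic contrast:
#: median PFI 1.0 / 0.5 / 2.0 %, with the obstructive group's lungs enlarged
#: and the fibrotic group's slightly shrunken.  Log-spreads are set so the
#: quartile ratios resemble clinical PFI distributions (tight in the
#: obstructive group, heavy-tailed in the fibrotic group).
DEFAULT_GROUP_PROFILES: dict[str, GroupProfile] = {
    "control": GroupProfile(1.0, 0.39, 1.0, 0.11),
    "COPD": GroupProfile(0.5, 0.21, 1.17, 0.08),
    "fILD": GroupProfile(2.0, 0.87, 0.95, 0.11),
}


def _spheres_for_target(target_ml: float, base_radius_mm: float = 5.0, min_radius_mm: float = 2.0):
    """Decompose a target fat volume into non-overlapping spheres.

    Uses as many base-radius spheres as fit, plus one remainder sphere; a
    remainder below the minimum radius is dropped, bounding the shortfall by
    the minimum sphere volume (~0.034 mL at 2 mm).
    """
    v_base = 4.0 / 3.0 * math.pi * base_radius_mm**3 / 1000.0
    n = int(target_ml // v_base)
    rem = target_ml - n * v_base
    spheres = [FatSphere(radius_mm=base_radius_mm) for _ in range(n)]
    r_rem = (3.0 * rem * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if r_rem >= min_radius_mm:
        spheres.append(FatSphere(radius_mm=r_rem))
    return spheres


def generate_cohort(
    template: PhantomSpec | None = None,
    group_profiles: dict[str, GroupProfile] | None = None,
    n_per_group: int = 30,
    seed: int = 0,
    depth_mm: float = 10.0,
    keep_phantoms: bool = False,
):
    """Simulate a multi-group cohort of phantoms and quantify each subject.

    Per subject the lung geometry is scaled by a sampled factor, a PFI
    target is sampled from the group profile, fat spheres summing to the
    implied volume are placed uniformly in the lung, and the quantification
    pipeline (threshold + distance partition + lobar split) is run on the
    rasterized phantom.  Returns a per-subject table (and optionally the
    phantoms themselves).
    """
    from .compartments import compartment_quant, lobar_quant
    from .quantify import compute_ctpfav

    template = template or default_spec()
    profiles = group_profiles or DEFAULT_GROUP_PROFILES
    rng = np.random.default_rng(seed)
    rows = []
    phantoms = []
    for group, prof in profiles.items():
        for i in range(n_per_group):
            scale = prof.lung_scale_median * math.exp(
                prof.lung_scale_log_sigma * rng.standard_normal()
            )
            scale = float(np.clip(scale, *prof.lung_scale_bounds))
            lungs = tuple(e.scaled(scale) for e in template.lung_geometry)
            pfi_target = prof.pfi_median_pct * math.exp(
                prof.pfi_log_sigma * rng.standard_normal()
            )
            pfi_target = float(np.clip(pfi_target, *prof.pfi_bounds_pct))
            lung_ml = sum(e.volume_ml for e in lungs)
            target_fat_ml = pfi_target / 100.0 * lung_ml
            if target_fat_ml >= lung_ml:
                raise PlacementError(f"infeasible PFI target {pfi_target:.2f}% for {group}")
            spec = replace(
                template,
                lung_geometry=lungs,
                fat_set=tuple(_spheres_for_target(target_fat_ml)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, lung_mask, lobe_mask, gt = generate_phantom(
                spec, depth_mm=depth_mm, compute_compartment_gt=False
            )
            quant = compute_ctpfav(image, lung_mask)
            comp = compartment_quant(image, lung_mask, depth_mm=depth_mm)
            lobar = lobar_quant(image, lobe_mask)
            row = {
                "subject_id": f"{group}-{i:03d}",
                "group": group,
                "pfi_target_pct": pfi_target,
                "ctpfav_ml": quant.ctpfav_ml,
                "lung_volume_ml": quant.lung_volume_ml,
                "pfi_pct": quant.pfi_pct,
                "subpleural_pfi_pct": comp.subpleural.pfi_pct,
                "nonsubpleural_pfi_pct": comp.nonsubpleural.pfi_pct,
                "fat_volume_ml_analytic": gt.fat_volume_ml_analytic,
            }
            for grp_name, res in lobar.per_group.items():
                row[f"{grp_name}_pfi_pct"] = res.pfi_pct
            rows.append(row)
            if keep_phantoms:
                phantoms.append((row["subject_id"], image, lung_mask, lobe_mask, gt))
    table = pd.DataFrame(rows)
    return (table, phantoms) if keep_phantoms else table
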