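"""Reading and writing CT volumes and label masks, and geometry validation.

Volumes are held in a single canonical orientation (RAS: data axes run
left->Right, posterior->Anterior, inferior->Superior), so array index order
is (x, y, z) in physical terms regardless of on-disk layout.  Masks are never
resampled onto an image grid: a geometry mismatch is a hard refusal, because
silent resampling would change the volumes under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryMismatchError, VolumeFormatError

#: Componentwise spacing tolerance (mm) absorbing header float noise.
SPACING_TOL_MM = 1e-4

#: Default anatomical meaning of lobe labels.
DEFAULT_LOBE_LABELS: dict[int, str] = {
    1: "LUL",  # left upper lobe
    2: "LLL",  # left lower lobe
    3: "RUL",  # right upper lobe
    4: "RML",  # right middle lobe
    5: "RLL",  # right lower lobe
}

DEFAULT_LUNG_LABELS: dict[int, str] = {1: "lung"}

_CANONICAL_AXCODES = ("R", "A", "S")


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not math.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive finite components, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3-D scalar grid of Hounsfield units with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        HU values; finite throughout.  Out-of-range raw values are preserved.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm per axis; strictly positive.
    origin : tuple of 3 floats
        Physical position (mm) of the first voxel's center.
    axcodes : tuple of 3 str
        Anatomical axis codes, canonically ("R", "A", "S").
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = _CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D with each dim >= 1, got shape {self.data.shape}")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise VolumeFormatError(f"volume contains {bad} non-finite voxel(s) (NaN/Inf)")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axcodes = tuple(self.axcodes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMask:
    """A 3-D integer label grid sharing an ImageVolume's geometry.

    0 is always background; positive integers are anatomical labels mapped
    to names by ``label_map`` (e.g. {1: "lung"} or the five-lobe map).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = _CANONICAL_AXCODES
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LUNG_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"mask must be 3-D with each dim >= 1, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int64)
            if not np.array_equal(as_int, self.data):
                raise VolumeFormatError("mask voxels must be non-negative integers")
            self.data = as_int
        if self.data.size and self.data.min() < 0:
            raise VolumeFormatError("mask labels must be non-negative (0 = background)")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axcodes = tuple(self.axcodes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def binarize(self, label: int | None = None) -> np.ndarray:
        """Boolean foreground array: a specific label, or any nonzero voxel."""
        if label is None:
            return self.data > 0
        return self.data == label


@dataclass
class GeometryReport:
    """Outcome of an image/mask grid-compatibility check."""

    shape_match: bool
    spacing_delta: tuple[float, float, float]
    orientation_match: bool
    verdict: str  # "pass" | "fail"

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def validate_geometry(
    image: ImageVolume, mask: LabelMask, spacing_tol_mm: float = SPACING_TOL_MM
) -> GeometryReport:
    """Check that image and mask live on the identical voxel grid.

    Pass iff shapes equal, spacing componentwise within ``spacing_tol_mm``,
    and anatomical axis codes equal.  No resampling is ever attempted; the
    report only carries the verdict and downstream operations refuse failing
    pairs.
    """
    shape_match = image.shape == mask.shape
    delta = tuple(abs(a - b) for a, b in zip(image.spacing, mask.spacing))
    spacing_match = all(d <= spacing_tol_mm for d in delta)
    orientation_match = tuple(image.axcodes) == tuple(mask.axcodes)
    ok = shape_match and spacing_match and orientation_match
    return GeometryReport(
        shape_match=shape_match,
        spacing_delta=delta,
        orientation_match=orientation_match,
        verdict="pass" if ok else "fail",
    )


def require_geometry(image: ImageVolume, mask: LabelMask) -> None:
    report = validate_geometry(image, mask)
    if not report.passed:
        raise GeometryMismatchError(
            "image/mask grids differ "
            f"(shape_match={report.shape_match}, spacing_delta={report.spacing_delta}, "
            f"orientation_match={report.orientation_match}); masks are never resampled"
        )


# ---------------------------------------------------------------------------
# loading


def _from_nibabel(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    """Reorient to canonical RAS and extract (data, spacing, origin)."""
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, spacing, origin


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_series"
    if path.name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise VolumeFormatError(f"cannot infer format of {path}; expected .nii/.nii.gz or a DICOM directory")


def load_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Load a CT volume in HU from a NIfTI file or a DICOM series directory.

    DICOM stored values are rescaled with the mandatory slope/intercept tags;
    their absence is an explicit error (identity is never silently assumed).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such path: {path}")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        try:
            img = nib.load(path)
        except Exception as exc:  # nibabel raises several unrelated types
            raise VolumeFormatError(f"unreadable NIfTI file {path}: {exc}") from exc
        data, spacing, origin = _from_nibabel(img)
        return ImageVolume(data.astype(np.float32, copy=False), spacing, origin)
    if fmt == "dicom_series":
        data, spacing, origin = _from_nibabel(_read_dicom_series(path))
        return ImageVolume(data.astype(np.float32, copy=False), spacing, origin)
    raise VolumeFormatError(f"unknown format {fmt!r}")


def load_mask(path: str | Path, label_map: dict[int, str] | None = None) -> LabelMask:
    """Load a NIfTI label mask; labels are rounded-checked integers."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such path: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:
        raise VolumeFormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data, spacing, origin = _from_nibabel(img)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise VolumeFormatError(f"mask {path} holds non-integer labels")
        data = rounded
    mask = LabelMask(data.astype(np.int32, copy=False), spacing, origin)
    if label_map is not None:
        mask.label_map = dict(label_map)
    return mask


def _read_dicom_series(directory: Path) -> nib.Nifti1Image:
    """Assemble one coherent DICOM series into an in-memory NIfTI image.

    Slices are sorted by ImagePositionPatient projected on the slice normal;
    non-uniform slice gaps beyond 1% tolerance make the volume ill-defined
    and are an error.
    """
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no DICOM slices found in {directory}")
    uids = {ds.SeriesInstanceUID for ds in slices}
    if len(uids) != 1:
        raise VolumeFormatError(f"directory {directory} mixes {len(uids)} DICOM series; supply exactly one")

    first = slices[0]
    if "ImageOrientationPatient" not in first or "ImagePositionPatient" not in first:
        raise VolumeFormatError("DICOM series lacks ImageOrientationPatient/ImagePositionPatient")
    iop = np.array(first.ImageOrientationPatient, float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)

    slices.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))
    positions = np.array([np.dot(np.array(ds.ImagePositionPatient, float), normal) for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(positions)
        if gaps.min() <= 0:
            raise VolumeFormatError("duplicate or non-monotonic DICOM slice positions")
        if (gaps.max() - gaps.min()) / gaps.mean() > 0.01:
            raise VolumeFormatError(
                f"non-uniform DICOM slice spacing (min {gaps.min():.4f}, max {gaps.max():.4f} mm)"
            )
        slice_gap = float(gaps.mean())
    else:
        slice_gap = float(getattr(first, "SliceThickness", 1.0))

    hu_slices = []
    for ds in slices:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeFormatError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; refusing to assume identity rescale"
            )
        hu_slices.append(
            ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        )
    # (slice, row, col) -> (row, col, slice): index axes (i, j, k)
    vol = np.ascontiguousarray(np.stack(hu_slices, axis=0).transpose(1, 2, 0))

    row_spacing, col_spacing = (float(x) for x in first.PixelSpacing)
    # DICOM is LPS; NIfTI affine is RAS: flip the first two patient axes.
    lps = np.eye(4)
    lps[:3, 0] = col_dir * row_spacing   # moving along rows (index i) steps in col_dir
    lps[:3, 1] = row_dir * col_spacing   # moving along columns (index j) steps in row_dir
    lps[:3, 2] = normal * slice_gap
    lps[:3, 3] = np.array(first.ImagePositionPatient, float)
    ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps
    return nib.Nifti1Image(vol, ras)


# ---------------------------------------------------------------------------
# writing


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as NIfTI; load_mask(write_mask(m)) is the identity."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.int16), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an HU volume as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)
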