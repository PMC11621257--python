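"""Fat-isodense voxel extraction and pulmonary fat index (PFI) computation.

CTpfav (CT pulmonary fat attenuation volume) is the physical volume of all
lung-mask voxels whose attenuation falls inside a fat HU window, by default
the closed interval [-200, -60] HU.  The PFI normalizes CTpfav by the CT
lung volume:

    PFI [%] = 100 * CTpfav [mL] / lung volume [mL]

Voxels are counted wholly in or out by their HU value; no sub-voxel
(partial-volume) weighting is applied, and no vessel/airway exclusion is
performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError
from .io_volumes import ImageVolume, LabelMask, require_geometry

__all__ = [
    "HUWindow",
    "FatQuantResult",
    "DEFAULT_FAT_WINDOW",
    "voxel_volume_ml",
    "threshold_fat",
    "compute_ctpfav",
    "compute_pfi",
]


@dataclass(frozen=True)
class HUWindow:
    """Closed attenuation interval [lower, upper] in HU defining fat-isodense."""

    lower: float = -200.0
    upper: float = -60.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("HU window bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"HU window requires lower < upper, got [{self.lower}, {self.upper}]")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        """Boolean array: HU inside the window, both endpoints inclusive."""
        return (hu >= self.lower) & (hu <= self.upper)


DEFAULT_FAT_WINDOW = HUWindow(-200.0, -60.0)


def voxel_volume_ml(spacing: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in mL given spacing in mm."""
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(not math.isfinite(x) or x <= 0 for x in s):
        raise ValueError(f"spacing must be 3 positive finite components, got {spacing}")
    return s[0] * s[1] * s[2] / 1000.0


@dataclass
class FatQuantResult:
    """Volumetric fat quantification over one lung region."""

    ctpfav_ml: float
    lung_volume_ml: float
    pfi_pct: float
    fat_voxel_count: int
    lung_voxel_count: int
    voxel_volume_ml: float
    window: HUWindow = field(default_factory=lambda: DEFAULT_FAT_WINDOW)

    def to_dict(self) -> dict:
        return {
            "ctpfav_ml": self.ctpfav_ml,
            "lung_volume_ml": self.lung_volume_ml,
            "pfi_pct": self.pfi_pct,
            "fat_voxel_count": self.fat_voxel_count,
            "lung_voxel_count": self.lung_voxel_count,
            "voxel_volume_ml": self.voxel_volume_ml,
            "hu_low": self.window.lower,
            "hu_high": self.window.upper,
        }


def threshold_fat(
    image: ImageVolume,
    lung: LabelMask,
    window: HUWindow = DEFAULT_FAT_WINDOW,
    lung_label: int | None = None,
) -> LabelMask:
    """Binary fat mask: lung voxels whose HU lies inside the (closed) window.

    ``lung_label`` selects one label from a multi-label mask; by default any
    nonzero voxel counts as lung.  Refuses geometry mismatches and empty lung
    masks (the PFI would be undefined).
    """
    require_geometry(image, lung)
    lung_bool = lung.binarize(lung_label)
    if not lung_bool.any():
        raise EmptyMaskError("lung mask is empty; PFI is undefined")
    fat = lung_bool & window.contains(image.data)
    return LabelMask(
        fat.astype(np.uint8),
        spacing=lung.spacing,
        origin=lung.origin,
        axcodes=lung.axcodes,
        label_map={1: "fat"},
    )


def compute_pfi(ctpfav_ml: float, lung_volume_ml: float) -> float:
    """PFI [%] = 100 * CTpfav / lung volume."""
    if not lung_volume_ml > 0:
        raise EmptyMaskError(f"lung volume must be positive, got {lung_volume_ml} mL; PFI undefined")
    if not 0 <= ctpfav_ml <= lung_volume_ml:
        raise ValueError(f"CTpfav {ctpfav_ml} mL outside [0, lung volume {lung_volume_ml} mL]")
    return 100.0 * ctpfav_ml / lung_volume_ml


def compute_ctpfav(
    image: ImageVolume,
    lung: LabelMask,
    window: HUWindow = DEFAULT_FAT_WINDOW,
    lung_label: int | None = None,
) -> FatQuantResult:
    """Quantify CTpfav, lung volume and PFI over a lung mask."""
    fat = threshold_fat(image, lung, window, lung_label)
    vv = voxel_volume_ml(image.spacing)
    fat_n = int(np.count_nonzero(fat.data))
    lung_n = int(np.count_nonzero(lung.binarize(lung_label)))
    ctpfav = fat_n * vv
    lungvol = lung_n * vv
    return FatQuantResult(
        ctpfav_ml=ctpfav,
        lung_volume_ml=lungvol,
        pfi_pct=compute_pfi(ctpfav, lungvol),
        fat_voxel_count=fat_n,
        lung_voxel_count=lung_n,
        voxel_volume_ml=vv,
        window=window,
    )
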