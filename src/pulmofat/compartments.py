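"""Subpleural/nonsubpleural partition and lobar aggregation.

The subpleural compartment is the lung parenchyma within a physical depth
(default 10 mm) of the lung-mask boundary, measured on a signed exact
Euclidean distance map that honors anisotropic voxel spacing.  The sign
convention is negative inside the lung and positive outside; the magnitude
at a voxel is the distance (mm) to the center of the nearest voxel of the
opposite class.  The reference surface is the entire lung boundary —
costal, mediastinal, diaphragmatic and hilar alike — and both lungs are
processed as one binary mask, so interlobar fissures are never treated as
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import EmptyMaskError
from .io_volumes import DEFAULT_LOBE_LABELS, ImageVolume, LabelMask, require_geometry
from .quantify import DEFAULT_FAT_WINDOW, FatQuantResult, HUWindow, compute_ctpfav

__all__ = [
    "DistanceMap",
    "CompartmentResult",
    "LobarResult",
    "LOBE_GROUPS",
    "signed_distance",
    "subpleural_partition",
    "compartment_quant",
    "lobar_quant",
]

#: Anatomical grouping of the five lobes.
LOBE_GROUPS: dict[str, tuple[str, ...]] = {
    "upper": ("LUL", "RUL"),
    "middle": ("RML",),
    "lower": ("LLL", "RLL"),
}


@dataclass
class DistanceMap:
    """Signed Euclidean distances (mm): negative inside the mask, positive outside."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axcodes: tuple[str, str, str]


def signed_distance(mask: LabelMask, label: int | None = None) -> DistanceMap:
    """Exact signed Euclidean distance map of a binary mask in physical mm.

    Computed with the exact (Maurer-class) Euclidean distance transform on
    both the mask and its complement, with voxel spacing as the sampling so
    anisotropic grids measure true millimetres.  Empty and full masks are
    refused: they have no boundary to partition against.
    """
    fg = mask.binarize(label)
    if not fg.any():
        raise EmptyMaskError("mask is empty; distance map boundary undefined")
    if fg.all():
        raise EmptyMaskError("mask fills the whole grid; distance map boundary undefined")
    sampling = mask.spacing
    inside = distance_transform_edt(fg, sampling=sampling)
    outside = distance_transform_edt(~fg, sampling=sampling)
    return DistanceMap(outside - inside, mask.spacing, mask.origin, mask.axcodes)


def subpleural_partition(
    lung: LabelMask, depth_mm: float = 10.0, label: int | None = None
) -> tuple[LabelMask, LabelMask]:
    """Split a lung mask into subpleural (depth <= ``depth_mm``) and the rest.

    A lung voxel is subpleural iff the magnitude of its interior distance to
    the lung boundary is <= ``depth_mm`` (closed condition).  The two outputs
    are an exact disjoint partition of the lung mask.  Disconnected lungs are
    handled against the union's boundary, which for anatomically separated
    lungs equals per-component processing.
    """
    if not depth_mm > 0:
        raise ValueError(f"depth_mm must be positive, got {depth_mm}")
    fg = lung.binarize(label)
    dist = signed_distance(lung, label)
    interior_depth = -dist.data  # positive inside the lung
    sub = fg & (interior_depth <= depth_mm)
    nonsub = fg & ~sub
    geom = dict(spacing=lung.spacing, origin=lung.origin, axcodes=lung.axcodes)
    return (
        LabelMask(sub.astype(np.uint8), label_map={1: "subpleural"}, **geom),
        LabelMask(nonsub.astype(np.uint8), label_map={1: "nonsubpleural"}, **geom),
    )


def _quant_or_empty(
    image: ImageVolume, region: LabelMask, window: HUWindow
) -> FatQuantResult:
    """Quantify a compartment; an empty compartment yields zero volumes with NaN PFI."""
    if region.data.any():
        return compute_ctpfav(image, region, window)
    from .quantify import voxel_volume_ml

    vv = voxel_volume_ml(image.spacing)
    return FatQuantResult(0.0, 0.0, float("nan"), 0, 0, vv, window)


@dataclass
class CompartmentResult:
    """Fat quantification in the subpleural vs nonsubpleural compartments."""

    subpleural: FatQuantResult
    nonsubpleural: FatQuantResult
    depth_mm: float = 10.0

    def to_dict(self) -> dict:
        return {
            "depth_mm": self.depth_mm,
            "subpleural": self.subpleural.to_dict(),
            "nonsubpleural": self.nonsubpleural.to_dict(),
        }


def compartment_quant(
    image: ImageVolume,
    lung: LabelMask,
    window: HUWindow = DEFAULT_FAT_WINDOW,
    depth_mm: float = 10.0,
    lung_label: int | None = None,
) -> CompartmentResult:
    """Quantify fat separately within and beyond ``depth_mm`` of the pleura."""
    require_geometry(image, lung)
    sub, nonsub = subpleural_partition(lung, depth_mm, lung_label)
    return CompartmentResult(
        subpleural=_quant_or_empty(image, sub, window),
        nonsubpleural=_quant_or_empty(image, nonsub, window),
        depth_mm=depth_mm,
    )


@dataclass
class LobarResult:
    """Per-lobe and per-group (upper/middle/lower) fat quantification.

    Groups pool voxel counts over their member lobes, so a group's PFI is
    100 * sum(CTpfav) / sum(lung volume) over the pooled region — not the
    mean of the member lobes' PFIs.  Groups with no lobe present in the mask
    are absent from ``per_group``, not reported as zero.
    """

    per_lobe: dict[str, FatQuantResult]
    per_group: dict[str, FatQuantResult]

    def to_dict(self) -> dict:
        return {
            "per_lobe": {k: v.to_dict() for k, v in self.per_lobe.items()},
            "per_group": {k: v.to_dict() for k, v in self.per_group.items()},
        }


def lobar_quant(
    image: ImageVolume,
    lobes: LabelMask,
    window: HUWindow = DEFAULT_FAT_WINDOW,
    label_map: dict[int, str] | None = None,
) -> LobarResult:
    """Quantify fat per pulmonary lobe and per anatomical lobe group.

    Lobe labels must all be known to the label map (default
    {1: LUL, 2: LLL, 3: RUL, 4: RML, 5: RLL}); an unexpected label is an
    error.  Lobes need not tile the whole lung (incomplete fissures), but
    being an integer label field they cannot overlap.
    """
    require_geometry(image, lobes)
    lmap = dict(label_map) if label_map is not None else (
        dict(lobes.label_map) if set(lobes.label_map) != {1} else dict(DEFAULT_LOBE_LABELS)
    )
    present = sorted(int(v) for v in np.unique(lobes.data) if v != 0)
    unknown = [v for v in present if v not in lmap]
    if unknown:
        raise ValueError(f"lobe mask holds labels {unknown} absent from label map {lmap}")

    per_lobe: dict[str, FatQuantResult] = {}
    for lab in present:
        per_lobe[lmap[lab]] = compute_ctpfav(image, lobes, window, lung_label=lab)

    from .quantify import compute_pfi

    per_group: dict[str, FatQuantResult] = {}
    for group, members in LOBE_GROUPS.items():
        hits = [per_lobe[m] for m in members if m in per_lobe]
        if not hits:
            continue
        fat_n = sum(r.fat_voxel_count for r in hits)
        lung_n = sum(r.lung_voxel_count for r in hits)
        vv = hits[0].voxel_volume_ml
        ctpfav = fat_n * vv
        lungvol = lung_n * vv
        per_group[group] = FatQuantResult(
            ctpfav_ml=ctpfav,
            lung_volume_ml=lungvol,
            pfi_pct=compute_pfi(ctpfav, lungvol),
            fat_voxel_count=fat_n,
            lung_voxel_count=lung_n,
            voxel_volume_ml=vv,
            window=window,
        )
    return LobarResult(per_lobe=per_lobe, per_group=per_group)
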