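"""Agreement metrics between a reference contour A and a test contour B.

Level I metrics quantify volumetric/uptake properties: signed percentage
errors in volume, mean uptake and maximum uptake, plus the Euclidean
distance between centers of mass (mm). Level II metrics quantify geometric
agreement: Dice similarity coefficient DSC = 2|A∩B|/(|A|+|B|), sensitivity
S = |A∩B|/|A|, positive predictive value PPV = |A∩B|/|B|, a modified
Hausdorff distance in which the directed distances are *mean* minimum
surface distances (the maximum of the two directions is reported, in cm),
the delineation-uncertainty volume DUV = |A∪B| - |A∩B| (voxels), and the
mean thickness of that uncertainty volume (cm).

Surface points for the modified Hausdorff distance are the physical centers
of boundary voxels, where a boundary voxel is a mask voxel with at least one
face-adjacent (6-connectivity) neighbor outside the mask; the volume border
counts as outside.

Conventions for an empty test mask B: volume_error = -100 %, DSC = S = 0;
PPV, the uptake errors and the Hausdorff distance are undefined and raise
:class:`EmptyMaskError` (the evaluation harness records them as missing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import GeometryError, ImageVolume, VoiMask

__all__ = [
    "EmptyMaskError",
    "volume_error",
    "mean_uptake_error",
    "max_uptake_error",
    "center_of_mass_error",
    "dsc",
    "sensitivity",
    "ppv",
    "modified_hausdorff",
    "duv",
    "mean_uncertainty_thickness",
    "surface_points",
    "surface_area_mm2",
    "METRICS",
    "compute_metric",
]


class EmptyMaskError(ValueError):
    """A metric's denominator mask (or surface) is empty."""


def _check_pair(a: VoiMask, b: VoiMask) -> None:
    if not a.same_grid(b):
        raise GeometryError("masks A and B do not share the same grid/frame")


def _check_image(image: ImageVolume, m: VoiMask) -> None:
    if not image.same_grid(m):
        raise GeometryError("mask does not share the image grid/frame")


# ---------------------------------------------------------------------- Level I

def volume_error(a: VoiMask, b: VoiMask) -> float:
    """Signed volume error (|B|-|A|)/|A| x 100 (%); positive = over-segmentation."""
    _check_pair(a, b)
    na = a.count
    if na == 0:
        raise EmptyMaskError("reference mask A is empty")
    return (b.count - na) / na * 100.0


def mean_uptake_error(image: ImageVolume, a: VoiMask, b: VoiMask) -> float:
    """Signed error in mean uptake over the mask voxels, in %."""
    _check_image(image, a)
    _check_image(image, b)
    if a.count == 0:
        raise EmptyMaskError("reference mask A is empty")
    if b.count == 0:
        raise EmptyMaskError("test mask B is empty; mean uptake undefined")
    ma = float(image.voxels[a.bits].mean())
    if ma == 0:
        raise EmptyMaskError("mean uptake over A is zero; relative error undefined")
    mb = float(image.voxels[b.bits].mean())
    return (mb - ma) / ma * 100.0


def max_uptake_error(image: ImageVolume, a: VoiMask, b: VoiMask) -> float:
    """Signed error in maximum uptake over the mask voxels, in %."""
    _check_image(image, a)
    _check_image(image, b)
    if a.count == 0:
        raise EmptyMaskError("reference mask A is empty")
    if b.count == 0:
        raise EmptyMaskError("test mask B is empty; max uptake undefined")
    xa = float(image.voxels[a.bits].max())
    if xa == 0:
        raise EmptyMaskError("max uptake over A is zero; relative error undefined")
    xb = float(image.voxels[b.bits].max())
    return (xb - xa) / xa * 100.0


def center_of_mass_error(
    a: VoiMask, b: VoiMask, *, image: ImageVolume | None = None,
    intensity_weighted: bool = False,
) -> float:
    """Euclidean distance (mm) between the mask centroids.

    By default the unweighted binary-mask centroid of voxel-center
    coordinates; pass ``intensity_weighted=True`` with an image for an
    uptake-weighted variant.
    """
    _check_pair(a, b)
    if a.count == 0 or b.count == 0:
        raise EmptyMaskError("center of mass undefined for an empty mask")

    def com(m: VoiMask) -> np.ndarray:
        pts = m.voxel_centers_mm()
        if intensity_weighted:
            if image is None:
                raise ValueError("intensity_weighted=True requires an image")
            w = image.voxels[m.bits].astype(float)
            if w.sum() == 0:
                raise EmptyMaskError("zero total uptake; weighted centroid undefined")
            return (pts * w[:, None]).sum(axis=0) / w.sum()
        return pts.mean(axis=0)

    return float(np.linalg.norm(com(b) - com(a)))


# --------------------------------------------------------------------- Level II

def dsc(a: VoiMask, b: VoiMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|), in [0, 1]."""
    _check_pair(a, b)
    denom = a.count + b.count
    if denom == 0:
        raise EmptyMaskError("DSC undefined: both masks empty")
    return 2.0 * int((a.bits & b.bits).sum()) / denom


def sensitivity(a: VoiMask, b: VoiMask) -> float:
    """Sensitivity S = |A∩B|/|A|, in [0, 1]."""
    _check_pair(a, b)
    if a.count == 0:
        raise EmptyMaskError("sensitivity undefined: reference mask A empty")
    return int((a.bits & b.bits).sum()) / a.count


def ppv(a: VoiMask, b: VoiMask) -> float:
    """Positive predictive value PPV = |A∩B|/|B|, in [0, 1]."""
    _check_pair(a, b)
    if b.count == 0:
        raise EmptyMaskError("PPV undefined: test mask B empty")
    return int((a.bits & b.bits).sum()) / b.count


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_points(mask: VoiMask) -> np.ndarray:
    """Physical centers (mm) of the mask's boundary voxels.

    Boundary = mask voxels with >= 1 face-adjacent outside neighbor; voxels
    on the array border count as boundary.
    """
    if mask.count == 0:
        raise EmptyMaskError("surface undefined for an empty mask")
    interior = ndimage.binary_erosion(mask.bits, structure=_FACE_STRUCT,
                                      border_value=0)
    boundary = mask.bits & ~interior
    idx = np.argwhere(boundary)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def modified_hausdorff(a: VoiMask, b: VoiMask) -> float:
    """Modified Hausdorff distance in cm.

    max( mean_i min_j ||a_i - b_j||, mean_j min_i ||b_j - a_i|| ) over the
    two surface point sets, computed in mm and reported in cm.
    """
    _check_pair(a, b)
    pa = surface_points(a)
    pb = surface_points(b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float(max(d_ab, d_ba)) / 10.0


def duv(a: VoiMask, b: VoiMask) -> int:
    """Delineation uncertainty volume |A∪B| - |A∩B|, in voxels."""
    _check_pair(a, b)
    return int((a.bits ^ b.bits).sum())


def surface_area_mm2(mask: VoiMask) -> float:
    """Surface area (mm^2) as the total area of exposed voxel faces."""
    if mask.count == 0:
        raise EmptyMaskError("surface area undefined for an empty mask")
    bits = mask.bits
    sx, sy, sz = mask.spacing
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    total = 0.0
    for axis, area in face_area.items():
        padded = np.pad(bits, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        exposed = int((np.diff(padded.astype(np.int8), axis=axis) != 0).sum())
        total += exposed * area
    return total


def mean_uncertainty_thickness(a: VoiMask, b: VoiMask) -> float:
    """Average thickness (cm) of the delineation uncertainty volume.

    DUV volume (voxel count x voxel volume) divided by the *reference*
    surface area (exposed-face count x face area). Zero when A == B.
    """
    _check_pair(a, b)
    if a.count == 0:
        raise EmptyMaskError("reference mask A is empty")
    n = duv(a, b)
    if n == 0:
        return 0.0
    return n * a.voxel_volume_mm3 / surface_area_mm2(a) / 10.0


# ----------------------------------------------------------------- registry

class MetricInfo:
    """Static description of a metric used by the evaluation harness."""

    def __init__(self, name, level, units, func, *, needs_image=False,
                 signed=False, best=0.0, clamp_side="lower", clamp_value=0.0):
        self.name = name
        self.level = level
        self.units = units
        self.func = func
        self.needs_image = needs_image
        #: signed error metrics are summarised on their absolute value
        self.signed = signed
        self.best = best
        #: which side of an agreement-limit interval is clamped to the best
        #: achievable value ("lower" for error/distance, "upper" for overlap)
        self.clamp_side = clamp_side
        self.clamp_value = clamp_value


METRICS: dict[str, MetricInfo] = {
    "volume_error": MetricInfo("volume_error", "I", "%", volume_error, signed=True),
    "mean_uptake_error": MetricInfo("mean_uptake_error", "I", "%", mean_uptake_error,
                                    needs_image=True, signed=True),
    "max_uptake_error": MetricInfo("max_uptake_error", "I", "%", max_uptake_error,
                                   needs_image=True, signed=True),
    "com_error": MetricInfo("com_error", "I", "mm", center_of_mass_error),
    "dsc": MetricInfo("dsc", "II", "unitless", dsc, best=1.0,
                      clamp_side="upper", clamp_value=1.0),
    "sensitivity": MetricInfo("sensitivity", "II", "unitless", sensitivity, best=1.0,
                              clamp_side="upper", clamp_value=1.0),
    "ppv": MetricInfo("ppv", "II", "unitless", ppv, best=1.0,
                      clamp_side="upper", clamp_value=1.0),
    "hd_mod": MetricInfo("hd_mod", "II", "cm", modified_hausdorff),
    "duv": MetricInfo("duv", "II", "voxels", duv),
    "duv_thickness": MetricInfo("duv_thickness", "II", "cm", mean_uncertainty_thickness),
}

LEVEL_I = [m for m in METRICS if METRICS[m].level == "I"]
LEVEL_II = [m for m in METRICS if METRICS[m].level == "II"]


def compute_metric(name: str, a: VoiMask, b: VoiMask,
                   image: ImageVolume | None = None) -> float:
    """Compute a metric by registry name (harness entry point)."""
    try:
        info = METRICS[name]
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; known: {sorted(METRICS)}") from None
    if info.needs_image:
        if image is None:
            raise ValueError(f"metric {name!r} requires the PET image")
        return float(info.func(image, a, b))
    return float(info.func(a, b))
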