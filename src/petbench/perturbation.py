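"""Controlled perturbations of a reference contour for specificity testing.

A benchmark is *specific* if its metrics detect contours that are known to
be degraded. The test suite perturbs a reference contour (RC) three ways:

- isotropic shrinkage by a physical distance (under-contouring),
- isotropic expansion by 0.25-1.0 cm (moderate to large over-contouring),
- an iso-volumetric local erosion/dilation that changes the shape while
  preserving the volume (shape error without volume error).

Expansion and shrinkage threshold the Euclidean distance transform computed
in physical millimetres (``scipy.ndimage.distance_transform_edt`` with the
grid spacing as sampling), so anisotropic voxels behave correctly. The
distance is measured between voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import VoiMask

__all__ = [
    "PerturbationSpec",
    "expand",
    "shrink",
    "isovolumetric_deform",
    "specificity_suite",
    "SPECIFICITY_LABELS",
]

#: expansion distances of the standard specificity suite, in cm
EXPANSIONS_CM = (0.25, 0.35, 0.45, 0.5, 1.0)
SPECIFICITY_LABELS = (
    "RC",
    "RC-0.5cm",
    "RC+0.25cm",
    "RC+0.35cm",
    "RC+0.45cm",
    "RC+0.5cm",
    "RC+1.0cm",
    "RC-eroded",
)


@dataclass
class PerturbationSpec:
    """One perturbation: kind in {shrink, expand, isovolumetric}."""

    kind: str
    distance_cm: float = 0.0
    magnitude_cm: float = 0.0
    seed: int = 0
    volume_tolerance: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in {"shrink", "expand", "isovolumetric"}:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind in {"shrink", "expand"} and self.distance_cm <= 0:
            raise ValueError("distance_cm must be > 0")
        if self.kind == "isovolumetric" and self.magnitude_cm <= 0:
            raise ValueError("magnitude_cm must be > 0")

    def apply(self, mask: VoiMask) -> VoiMask:
        if self.kind == "expand":
            return expand(mask, self.distance_cm)
        if self.kind == "shrink":
            return shrink(mask, self.distance_cm)
        return isovolumetric_deform(mask, self.magnitude_cm, self.seed,
                                    self.volume_tolerance)


def _dist_outside_mm(mask: VoiMask) -> np.ndarray:
    """Distance (mm) from each voxel center to the nearest mask voxel center."""
    return ndimage.distance_transform_edt(~mask.bits, sampling=mask.spacing)


def _dist_inside_mm(mask: VoiMask) -> np.ndarray:
    """Distance (mm) from each mask voxel center to the nearest outside center."""
    return ndimage.distance_transform_edt(mask.bits, sampling=mask.spacing)


def expand(mask: VoiMask, distance_cm: float) -> VoiMask:
    """Isotropic expansion: all voxels within ``distance_cm`` of the mask."""
    if mask.count == 0:
        raise ValueError("cannot expand an empty mask")
    if distance_cm <= 0:
        raise ValueError("distance_cm must be > 0")
    bits = _dist_outside_mm(mask) <= distance_cm * 10.0
    return mask.with_bits(bits, f"{mask.label}+{distance_cm:g}cm")


def shrink(mask: VoiMask, distance_cm: float) -> VoiMask:
    """Isotropic shrinkage: mask voxels deeper than ``distance_cm`` inside."""
    if mask.count == 0:
        raise ValueError("cannot shrink an empty mask")
    if distance_cm <= 0:
        raise ValueError("distance_cm must be > 0")
    din = _dist_inside_mm(mask)
    bits = din > distance_cm * 10.0
    if not bits.any():
        raise ValueError(
            f"shrinkage of {distance_cm:g} cm annihilates the mask "
            f"(maximum feasible distance: {float(din.max()) / 10.0:.3f} cm)"
        )
    return mask.with_bits(bits, f"{mask.label}-{distance_cm:g}cm")


def isovolumetric_deform(mask: VoiMask, magnitude_cm: float = 0.2,
                         seed: int = 0,
                         volume_tolerance: float = 0.005) -> VoiMask:
    """Local erosion/dilation that modifies the geometry at constant volume.

    A random direction (seeded) splits the mask at its centroid into two
    half-space caps. The mask is dilated by ``magnitude_cm`` within one cap;
    the opposite cap is then eroded boundary-inward — voxels removed in
    order of increasing interior depth, ties broken by flat index — until
    exactly as many voxels are removed as were added. The volume is
    therefore preserved exactly (always within ``volume_tolerance``), while
    the shape changes (DSC < 1 against the input).
    """
    if mask.count == 0:
        raise ValueError("cannot deform an empty mask")
    if magnitude_cm <= 0:
        raise ValueError("magnitude_cm must be > 0")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)

    # on grids coarser than the requested depth, deform by at least one
    # voxel layer so the perturbation never degenerates to the identity
    depth_mm = max(magnitude_cm * 10.0, float(max(mask.spacing)))

    centers = np.indices(mask.shape).reshape(3, -1).T * np.asarray(mask.spacing) \
        + np.asarray(mask.origin)
    side = (centers - mask.voxel_centers_mm().mean(axis=0)) @ u
    cap_pos = (side > 0).reshape(mask.shape)

    added = (~mask.bits) & cap_pos & (_dist_outside_mm(mask) <= depth_mm)
    n_add = int(added.sum())
    if n_add == 0:
        raise ValueError("magnitude too small: dilation adds no voxels")

    removable = mask.bits & ~cap_pos
    if int(removable.sum()) <= n_add:
        raise ValueError(
            "magnitude infeasible: the erosion cap has too few voxels to "
            "balance the dilation"
        )
    depth = _dist_inside_mm(mask)
    flat = np.flatnonzero(removable.ravel())
    order = flat[np.lexsort((flat, depth.ravel()[flat]))]
    remove_idx = order[:n_add]
    bits = mask.bits | added
    bits.ravel()[remove_idx] = False

    out = mask.with_bits(bits, f"{mask.label}-eroded")
    err = abs(out.count - mask.count) / mask.count
    if err > volume_tolerance:
        raise RuntimeError(
            f"volume tolerance not met: relative error {err:.4f}"
        )
    return out


def specificity_suite(rc: VoiMask, seed: int = 0,
                      magnitude_cm: float = 0.2) -> list[tuple[str, VoiMask]]:
    """The standard labeled suite of perturbed contours, plus the RC itself.

    Eight contours: the unmodified RC, a 0.5 cm shrinkage, expansions of
    0.25/0.35/0.45/0.5/1.0 cm, and an iso-volumetric erosion/dilation.
    """
    if rc.count == 0:
        raise ValueError("reference contour is empty")
    suite: list[tuple[str, VoiMask]] = [("RC", rc)]
    suite.append(("RC-0.5cm", shrink(rc, 0.5)))
    for d in EXPANSIONS_CM:
        suite.append((f"RC+{d}cm", expand(rc, d)))
    suite.append(("RC-eroded", isovolumetric_deform(rc, magnitude_cm, seed)))
    assert [lab for lab, _ in suite] == list(SPECIFICITY_LABELS)
    return suite
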