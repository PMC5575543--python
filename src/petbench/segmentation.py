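"""Reference PET auto-segmentation methods.

All methods operate on a PET :class:`~petbench.core_io.ImageVolume` inside a
user-supplied :class:`SearchRegion` (an axis-aligned voxel box enclosing the
lesion plus margin) and return a :class:`~petbench.core_io.VoiMask` on the
full image grid. Every method is deterministic given (image, region,
parameters, seed), and every returned mask is post-processed to a single
26-connected component with enclosed holes filled, clipped to the region.

Implemented methods and their ids:

========  =====================================================
``FT``    fixed threshold at a percentage of the region maximum
``ABS``   fixed threshold at an absolute intensity
``SBR``   signal-to-background-ratio adaptive threshold,
          T = B̄ + θ(SBR)·(S̄ − B̄) with θ(SBR) = a + b/SBR
``AT``    iterative adaptive threshold,
          T_{k+1} = B̄ + ε·(mean uptake inside current mask − B̄)
``RG``    descending-threshold region growing from the max voxel
``KM``    k-means clustering of region intensities
``GMM``   univariate Gaussian-mixture clustering (EM)
``GCM``   GMM with the component count selected by BIC in {2,3,4}
``WC``    watershed of the smoothed gradient magnitude with
          basins clustered into tumor/background (alias ``WT``)
========  =====================================================

The SBR calibration constants (a, b) are scanner-dependent and are fitted on
phantom data with :func:`calibrate_sbr` rather than hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .core_io import ImageVolume, VoiMask, rasterize_rtstruct, read_mask

__all__ = [
    "SearchRegion",
    "SegmentationSpec",
    "SbrCalibration",
    "AdaptiveResult",
    "segment",
    "segment_fixed_threshold",
    "segment_absolute_threshold",
    "segment_sbr",
    "segment_adaptive_threshold",
    "segment_region_growing",
    "segment_kmeans",
    "segment_gmm",
    "segment_watershed_clustering",
    "postprocess",
    "calibrate_sbr",
    "auto_background_shell",
    "import_external_contour",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SearchRegion:
    """Axis-aligned voxel-index box enclosing the lesion plus margin.

    ``lo`` is inclusive, ``hi`` exclusive. ``background_shell`` is an
    optional full-grid boolean mask used for background sampling by the
    SBR and adaptive-threshold methods; when absent a shell is built
    automatically (see :func:`auto_background_shell`).
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    background_shell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        if any(h - l < 1 for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate region box lo={self.lo} hi={self.hi}")
        if int(np.prod([h - l for l, h in zip(self.lo, self.hi)])) < 2:
            raise ValueError("region box must contain at least 2 voxels")

    def validate(self, shape: tuple[int, int, int]) -> None:
        if any(l < 0 or h > n for l, h, n in zip(self.lo, self.hi, shape)):
            raise ValueError(
                f"region box lo={self.lo} hi={self.hi} exceeds image shape {shape}"
            )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore

    def box_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m

    def on_border(self, idx: Sequence[int]) -> bool:
        return any(i == l or i == h - 1 for i, l, h in zip(idx, self.lo, self.hi))

    @classmethod
    def from_mask(cls, mask: VoiMask, margin_mm: float = 15.0) -> "SearchRegion":
        """Bounding box of a mask expanded by a physical margin, clipped to grid."""
        idx = np.argwhere(mask.bits)
        if idx.size == 0:
            raise ValueError("cannot build a search region from an empty mask")
        marg = [int(np.ceil(margin_mm / s)) for s in mask.spacing]
        lo = [max(0, int(idx[:, ax].min()) - marg[ax]) for ax in range(3)]
        hi = [min(mask.shape[ax], int(idx[:, ax].max()) + 1 + marg[ax]) for ax in range(3)]
        return cls(tuple(lo), tuple(hi))


@dataclass
class SegmentationSpec:
    """A method id plus its parameters and seed, for the dispatch entry point."""

    method_id: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


class AdaptiveResult(NamedTuple):
    mask: VoiMask
    iterations: int
    converged: bool


@dataclass(frozen=True)
class SbrCalibration:
    """Threshold calibration θ(SBR) = a + b/SBR for the SBR method."""

    a: float
    b: float


# ------------------------------------------------------------------ helpers

def _region_values(image: ImageVolume, region: SearchRegion) -> np.ndarray:
    region.validate(image.shape)
    return image.voxels[region.slices]


def _max_voxel(image: ImageVolume, region: SearchRegion) -> tuple[int, int, int]:
    sub = _region_values(image, region)
    local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return tuple(int(l + o) for l, o in zip(local, region.lo))  # type: ignore


def postprocess(mask: VoiMask, region: SearchRegion,
                anchor: Sequence[int]) -> VoiMask:
    """Shared clean-up: clip to region, keep one 26-connected component, fill holes.

    The component containing ``anchor`` is kept (the largest one if the
    anchor is outside the mask); fully enclosed holes are filled.
    """
    region.validate(mask.shape)
    bits = mask.bits & region.box_mask(mask.shape)
    if not bits.any():
        warnings.warn("postprocess received an empty mask")
        return mask.with_bits(bits)
    labels, n = ndimage.label(bits, structure=_CONN26)
    anchor = tuple(int(v) for v in anchor)
    lab = labels[anchor]
    if lab == 0:  # anchor outside the mask: fall back to the largest component
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lab = int(np.argmax(counts))
    keep = labels == lab
    keep = ndimage.binary_fill_holes(keep)
    return mask.with_bits(keep & region.box_mask(mask.shape))


def _threshold_mask(image: ImageVolume, region: SearchRegion, t: float,
                    label: str) -> VoiMask:
    bits = np.zeros(image.shape, dtype=bool)
    bits[region.slices] = image.voxels[region.slices] >= t
    mask = VoiMask.from_image(image, bits, label=label)
    return postprocess(mask, region, _max_voxel(image, region))


def auto_background_shell(image: ImageVolume, region: SearchRegion) -> np.ndarray:
    """Background-sampling shell built from the 70%-of-max core.

    The shell is the ring between the 2-voxel and 4-voxel morphological
    expansions (6-connectivity) of the 70 % threshold mask, clipped to the
    search region.
    """
    sub = _region_values(image, region)
    core = np.zeros(image.shape, dtype=bool)
    core[region.slices] = sub >= 0.7 * sub.max()
    d2 = ndimage.binary_dilation(core, structure=_CONN6, iterations=2)
    d4 = ndimage.binary_dilation(core, structure=_CONN6, iterations=4)
    shell = d4 & ~d2 & region.box_mask(image.shape)
    if not shell.any():
        raise ValueError("could not build a background shell inside the region; "
                         "enlarge the search region or supply one explicitly")
    return shell


def _background_mean(image: ImageVolume, region: SearchRegion) -> float:
    shell = region.background_shell
    if shell is None:
        shell = auto_background_shell(image, region)
    return float(image.voxels[shell].mean())


# ------------------------------------------------------------------ methods

def segment_fixed_threshold(image: ImageVolume, region: SearchRegion,
                            fraction: float) -> VoiMask:
    """Fixed threshold at ``fraction`` percent of the region maximum."""
    if not 0 < fraction < 100:
        raise ValueError("fraction must be in (0, 100) percent")
    sub = _region_values(image, region)
    if sub.max() == sub.min():
        raise ValueError("flat region: cannot threshold at a fraction of max")
    t = fraction / 100.0 * float(sub.max())
    return _threshold_mask(image, region, t, f"FT{fraction:g}")


def segment_absolute_threshold(image: ImageVolume, region: SearchRegion,
                               value: float) -> VoiMask:
    """Fixed threshold at an absolute intensity ``value``."""
    sub = _region_values(image, region)
    if not sub.min() <= value <= sub.max():
        raise ValueError(
            f"threshold {value} outside region intensity range "
            f"[{sub.min():g}, {sub.max():g}]"
        )
    return _threshold_mask(image, region, float(value), f"ABS{value:g}")


def segment_sbr(image: ImageVolume, region: SearchRegion,
                calibration: SbrCalibration | tuple[float, float]) -> VoiMask:
    """Signal-to-background-ratio thresholding.

    The threshold is T = B̄ + θ(SBR)·(S̄ − B̄), where B̄ is the background-
    shell mean, S̄ the mean of region voxels above 90 % of the maximum,
    SBR = S̄/B̄ and θ(SBR) = a + b/SBR with (a, b) from a phantom
    calibration (:func:`calibrate_sbr`). In the zero-background limit
    θ → a and the method reduces to a fixed threshold at a·S̄.
    """
    if not isinstance(calibration, SbrCalibration):
        calibration = SbrCalibration(*calibration)
    sub = _region_values(image, region)
    smax = float(sub.max())
    sbar = float(sub[sub >= 0.9 * smax].mean())
    bbar = _background_mean(image, region)
    if bbar < 0:
        raise ValueError("negative background mean")
    if bbar == 0.0:
        theta = calibration.a  # SBR -> infinity limit
    else:
        sbr = sbar / bbar
        if sbr <= 1.0:
            raise ValueError("lesion not distinguishable from background (SBR <= 1)")
        theta = calibration.a + calibration.b / sbr
    t = bbar + theta * (sbar - bbar)
    return _threshold_mask(image, region, t, "SBR")


def segment_adaptive_threshold(image: ImageVolume, region: SearchRegion,
                               epsilon: float = 0.5,
                               max_iter: int = 50) -> AdaptiveResult:
    """Iterative adaptive thresholding.

    Fixed-point iteration T_{k+1} = B̄ + ε·(mean uptake inside the current
    mask − B̄), initialised from the 40 %-of-max mask; stops when the mask
    is unchanged or after ``max_iter`` iterations (non-converged flag).
    ε = 1 degenerates to thresholding at the object mean and is allowed but
    rarely useful.
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    bbar = _background_mean(image, region)
    mask = segment_fixed_threshold(image, region, 40.0)
    for it in range(1, max_iter + 1):
        t = bbar + epsilon * (float(image.voxels[mask.bits].mean()) - bbar)
        new = _threshold_mask(image, region, t, "AT")
        if np.array_equal(new.bits, mask.bits):
            return AdaptiveResult(new.with_bits(new.bits, "AT"), it, True)
        mask = new
    warnings.warn(f"adaptive threshold did not converge in {max_iter} iterations")
    return AdaptiveResult(mask.with_bits(mask.bits, "AT"), max_iter, False)


def segment_region_growing(image: ImageVolume, region: SearchRegion,
                           jump_factor: float = 1.5,
                           seed_voxel: Sequence[int] | None = None,
                           min_growth_voxels: int = 20) -> VoiMask:
    """Descending-threshold region growing.

    For t from 95 % down to 10 % of the region maximum in 5 % steps, the
    candidate mask is the 26-connected component of {intensity >= t}
    containing the seed (default: the region maximum voxel). Growth stops
    at the step *before* the relative volume jump exceeds ``jump_factor``
    or before the component touches the region boundary. The jump test
    only engages once the component holds ``min_growth_voxels`` voxels:
    below that, step-to-step ratios are dominated by discretization (a
    2-voxel component tripling is not a flood into background). With
    ``jump_factor = inf`` and an interior object this reduces to a fixed
    threshold at 10 % of max.
    """
    seed = tuple(int(v) for v in (seed_voxel or _max_voxel(image, region)))
    if region.on_border(seed):
        raise ValueError("region too tight: seed voxel lies on the region border")
    sub = _region_values(image, region)
    vmax = float(sub.max())
    prev: np.ndarray | None = None
    for pct in range(95, 9, -5):
        thr = pct / 100.0 * vmax
        cand = np.zeros(image.shape, dtype=bool)
        cand[region.slices] = sub >= thr
        labels, _ = ndimage.label(cand, structure=_CONN26)
        comp = labels == labels[seed]
        if labels[seed] == 0:
            continue  # seed below threshold (cannot happen for the max voxel)
        touches = any(
            comp.take(b, axis=ax).any()
            for ax in range(3) for b in (region.lo[ax], region.hi[ax] - 1)
        )
        if touches:
            if prev is None:
                raise ValueError("region too tight: object touches the region "
                                 "boundary at the first growth step")
            break
        if (prev is not None and prev.sum() >= min_growth_voxels
                and comp.sum() / prev.sum() > jump_factor):
            break
        prev = comp
    if prev is None:
        raise ValueError("region growing failed to produce a mask")
    mask = VoiMask.from_image(image, prev, label="RG")
    return postprocess(mask, region, seed)


def segment_kmeans(image: ImageVolume, region: SearchRegion, k: int = 2,
                   seed: int = 0, n_init: int = 10) -> VoiMask:
    """K-means clustering of region intensities; tumor = highest-centroid cluster."""
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    sub = _region_values(image, region)
    values = sub.reshape(-1, 1)
    n_distinct = np.unique(values).size
    if n_distinct < k:
        warnings.warn(f"only {n_distinct} distinct intensities; reducing k from {k}")
        k = n_distinct
        if k < 2:
            raise ValueError("flat region: cannot cluster")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(values)
    top = int(np.argmax(km.cluster_centers_.ravel()))
    bits = np.zeros(image.shape, dtype=bool)
    bits[region.slices] = (km.labels_ == top).reshape(sub.shape)
    mask = VoiMask.from_image(image, bits, label=f"KM{k}")
    return postprocess(mask, region, _max_voxel(image, region))


def fit_gmm_intensities(values: np.ndarray, n_components: int, seed: int = 0):
    """Fit a univariate Gaussian mixture (EM, k-means init) to intensities."""
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=n_components, random_state=seed,
                         init_params="kmeans", reg_covar=1e-8, max_iter=500,
                         n_init=1)
    gm.fit(np.asarray(values, dtype=float).reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge after {gm.n_iter_} iterations "
            f"(lower bound {gm.lower_bound_:.6g})"
        )
    return gm


def segment_gmm(image: ImageVolume, region: SearchRegion,
                n_components: int = 2, seed: int = 0,
                select_bic: bool = False) -> VoiMask:
    """Gaussian-mixture clustering of region intensities.

    A voxel is assigned to the tumor iff the posterior probability of the
    highest-mean component is >= 0.5. With ``select_bic=True`` (the GCM
    variant) the component count is chosen among {2, 3, 4} by BIC.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    sub = _region_values(image, region)
    values = sub.reshape(-1, 1)
    if select_bic:
        fits = {n: fit_gmm_intensities(values, n, seed) for n in (2, 3, 4)}
        n_components = min(fits, key=lambda n: fits[n].bic(values))
        gm = fits[n_components]
        label = f"GCM{n_components}"
    else:
        gm = fit_gmm_intensities(values, n_components, seed)
        label = "GMM"
    top = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(values)[:, top]
    bits = np.zeros(image.shape, dtype=bool)
    bits[region.slices] = (post >= 0.5).reshape(sub.shape)
    mask = VoiMask.from_image(image, bits, label=label)
    return postprocess(mask, region, _max_voxel(image, region))


def watershed_basins(image: ImageVolume, region: SearchRegion,
                     sigma_voxels: float = 1.0):
    """Watershed of the gradient magnitude of the smoothed image.

    The image (not the gradient) is Gaussian-smoothed, which suppresses
    spurious noise ridges while leaving the edge inflection — and hence the
    watershed line — in place. Markers are the connected local-minima
    plateaus of the gradient magnitude. Returns ``(labels, n_basins,
    gradient)`` on the region subvolume; used by
    :func:`segment_watershed_clustering` and exposed for inspection.
    """
    from skimage.morphology import local_minima
    from skimage.segmentation import watershed

    sub = _region_values(image, region)
    if sub.max() == sub.min():
        raise ValueError("flat region: watershed undefined")
    smoothed = (ndimage.gaussian_filter(sub.astype(float), sigma_voxels)
                if sigma_voxels > 0 else sub.astype(float))
    grads = np.gradient(smoothed, *[float(s) for s in image.spacing])
    grad = np.sqrt(sum(g * g for g in grads))
    # 6-connectivity: the gradient ridge between adjacent plateaus can be a
    # single voxel wide, which 26-connectivity would leak across diagonally
    markers, n = ndimage.label(local_minima(grad, allow_borders=True),
                               structure=_CONN6)
    labels = watershed(grad, markers)
    return labels, int(n), grad


def segment_watershed_clustering(image: ImageVolume, region: SearchRegion,
                                 sigma_voxels: float = 1.0,
                                 seed: int = 0) -> VoiMask:
    """Watershed-based clustering.

    Basins of the smoothed gradient magnitude are clustered into two groups
    by mean intensity (k-means, seeded); the tumor is the high-intensity
    group, reduced to the 26-connected component containing the region
    maximum. Falls back to a 40 % fixed threshold when the watershed yields
    a single basin.
    """
    from sklearn.cluster import KMeans

    sub = _region_values(image, region)
    labels, n, _ = watershed_basins(image, region, sigma_voxels)
    if n < 2:
        warnings.warn("watershed produced a single basin; falling back to FT40")
        ft = segment_fixed_threshold(image, region, 40.0)
        return ft.with_bits(ft.bits, "WC")
    means = ndimage.mean(sub, labels=labels, index=np.arange(1, n + 1))
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
        np.asarray(means).reshape(-1, 1))
    high = int(np.argmax(km.cluster_centers_.ravel()))
    tumor_basins = np.where(km.labels_ == high)[0] + 1
    bits = np.zeros(image.shape, dtype=bool)
    bits[region.slices] = np.isin(labels, tumor_basins)
    mask = VoiMask.from_image(image, bits, label="WC")
    return postprocess(mask, region, _max_voxel(image, region))


# ------------------------------------------------------------- calibration

def calibrate_sbr(cases: Sequence[tuple[ImageVolume, SearchRegion, VoiMask]],
                  ) -> SbrCalibration:
    """Fit the SBR threshold calibration θ(SBR) = a + b/SBR on phantom data.

    For each (image, region, reference-mask) case the optimal threshold
    fraction θ* — the one whose thresholded volume best matches the
    reference volume — is found by bisection (volume is monotone in θ), and
    (a, b) are then obtained by least squares of θ* against 1/SBR.
    """
    thetas, inv_sbrs = [], []
    for image, region, rc in cases:
        sub = _region_values(image, region)
        smax = float(sub.max())
        sbar = float(sub[sub >= 0.9 * smax].mean())
        bbar = _background_mean(image, region)
        if bbar <= 0:
            raise ValueError("calibration case has non-positive background mean")
        sbr = sbar / bbar
        if sbr <= 1:
            raise ValueError("calibration case has SBR <= 1")
        target = rc.count

        def count_at(theta: float) -> int:
            t = bbar + theta * (sbar - bbar)
            return int((sub >= t).sum())

        lo, hi = 0.01, 0.99
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if count_at(mid) > target:
                lo = mid  # mask too big -> raise threshold
            else:
                hi = mid
        theta = min((lo, hi, 0.5 * (lo + hi)),
                    key=lambda th: abs(count_at(th) - target))
        thetas.append(theta)
        inv_sbrs.append(1.0 / sbr)
    A = np.column_stack([np.ones(len(thetas)), inv_sbrs])
    coef, *_ = np.linalg.lstsq(A, np.asarray(thetas), rcond=None)
    return SbrCalibration(a=float(coef[0]), b=float(coef[1]))


# ---------------------------------------------------------------- externals

def import_external_contour(path: str | Path, image: ImageVolume,
                            method_id: str, roi_name: str | None = None) -> VoiMask:
    """Import a contour produced outside the package (NIfTI mask or RTSTRUCT).

    Methods not implemented here (e.g. FLAB) enter the benchmark this way;
    the returned mask is tagged with the caller's ``method_id``.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        mask = rasterize_rtstruct(path, image, roi_name or method_id)
    else:
        mask = read_mask(path, image)
    return mask.with_bits(mask.bits, method_id)


# ----------------------------------------------------------------- dispatch

def segment(image: ImageVolume, region: SearchRegion,
            spec: SegmentationSpec) -> VoiMask:
    """Run a segmentation method by :class:`SegmentationSpec`."""
    p = dict(spec.parameters)
    mid = spec.method_id.upper()
    if mid == "FT":
        return segment_fixed_threshold(image, region, p.get("fraction", 42.0))
    if mid == "ABS":
        return segment_absolute_threshold(image, region, p["value"])
    if mid == "SBR":
        return segment_sbr(image, region, (p["a"], p["b"]))
    if mid == "AT":
        return segment_adaptive_threshold(
            image, region, p.get("epsilon", 0.5), p.get("max_iter", 50)).mask
    if mid == "RG":
        return segment_region_growing(image, region, p.get("jump_factor", 1.5))
    if mid == "KM":
        return segment_kmeans(image, region, p.get("k", 2), spec.seed)
    if mid == "GMM":
        return segment_gmm(image, region, p.get("n_components", 2), spec.seed)
    if mid == "GCM":
        return segment_gmm(image, region, seed=spec.seed, select_bic=True)
    if mid in {"WC", "WT"}:
        return segment_watershed_clustering(
            image, region, p.get("sigma_voxels", 1.0), spec.seed)
    raise ValueError(f"unknown method id {spec.method_id!r}")
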