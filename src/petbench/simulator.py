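"""Synthetic PET study generator.

Produces ground-truth phantoms (activity maps with exactly known tumor
support), projects them to sinograms, adds Poisson counting noise with
uniform scatter/randoms components, and reconstructs with filtered
back-projection (FBP) or ordered-subset expectation maximisation (OSEM)
with optional point-spread-function (PSF) modelling. Every stage is
deterministic under a fixed seed, so whole study suites are bit-for-bit
reproducible.

Geometry is 2-D slice-wise parallel-beam, stacked along the z axis — a
deliberately desk-scale simplification of a clinical scanner that still
produces the resolution/noise phenomenology a segmentation benchmark needs
(partial-volume blur, count-dependent noise, reconstruction-dependent
texture). Attenuation is not modelled; scatter and randoms enter as uniform
additive sinogram components. The projector is an explicit sparse matrix
(pixel-driven, linear interpolation onto detector bins), so the OSEM
forward/backprojection pair is exactly adjoint.

The reference contour (RC) of each simulated tumor is the voxel support of
uptake strictly above background in the original activity map — the
absolute truth against which reconstructed-image segmentations are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse

from .core_io import ImageVolume, Study, StudyDatabase, VoiMask, save_database

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "ReconConfig",
    "Sinogram",
    "build_phantom",
    "forward_project",
    "add_counts_noise",
    "reconstruct_fbp",
    "reconstruct_osem",
    "reconstruct",
    "simulate_study",
    "make_benchmark_suite",
    "default_suite_config",
    "project_slice",
    "backproject_slice",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ----------------------------------------------------------------- phantoms

@dataclass
class TumorSpec:
    """One tumor: shape, position, size and uptake.

    ``shape`` is one of {"sphere", "ellipsoid", "union_of_spheres"}. Sizes
    are in mm: ``size`` is a radius (sphere), a 3-tuple of semi-axes
    (ellipsoid), or a list of (center_mm, radius_mm) pairs
    (union_of_spheres, centers absolute). ``uptake`` is a uniform activity
    level, or a (core, rim) pair for heterogeneous two-level uptake with
    the core scaled by ``core_fraction``.
    """

    center_mm: tuple[float, float, float]
    size: float | tuple | list
    uptake: float | tuple[float, float]
    shape: str = "sphere"
    core_fraction: float = 0.5
    label: str = "tumor"

    def support(self, centers: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Boolean support over an (..., 3) array of voxel centers (mm)."""
        c = np.asarray(self.center_mm, dtype=float)
        if self.shape == "sphere":
            r = float(self.size) * scale
            return ((centers - c) ** 2).sum(axis=-1) <= r * r
        if self.shape == "ellipsoid":
            radii = np.asarray(self.size, dtype=float) * scale
            return (((centers - c) / radii) ** 2).sum(axis=-1) <= 1.0
        if self.shape == "union_of_spheres":
            out = np.zeros(centers.shape[:-1], dtype=bool)
            for sc, r in self.size:
                sc = np.asarray(sc, dtype=float)
                out |= ((centers - sc) ** 2).sum(axis=-1) <= (r * scale) ** 2
            return out
        raise ValueError(f"unknown tumor shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Background plus tumors on a regular grid."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tumors: list[TumorSpec]
    background: float | ImageVolume = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = "sim"


def _voxel_centers(shape, spacing, origin) -> np.ndarray:
    grids = np.meshgrid(*[o + np.arange(n) * s
                          for n, s, o in zip(shape, spacing, origin)],
                        indexing="ij")
    return np.stack(grids, axis=-1)


def build_phantom(spec: PhantomSpec) -> tuple[ImageVolume, list[VoiMask]]:
    """Build the activity map and one reference contour per tumor.

    Tumors overwrite the background; the RC of a tumor is the support of
    uptake strictly above background — for two-level tumors this is the
    whole core ∪ rim support. Overlapping tumors are rejected.
    """
    if not spec.tumors:
        raise ValueError("phantom has no tumors: no reference contour definable")
    if isinstance(spec.background, ImageVolume):
        if spec.background.shape != tuple(spec.grid_shape):
            raise ValueError("background template shape does not match the grid")
        bg = spec.background.voxels.copy()
    else:
        bg = np.full(spec.grid_shape, float(spec.background))
    if np.any(bg < 0):
        raise ValueError("background activity must be non-negative")
    centers = _voxel_centers(spec.grid_shape, spec.spacing, spec.origin)
    activity = bg.copy()
    rcs: list[VoiMask] = []
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    for t in spec.tumors:
        sup = t.support(centers)
        if not sup.any():
            raise ValueError(f"tumor {t.label!r} lies outside the grid")
        if (sup & occupied).any():
            raise ValueError(f"tumor {t.label!r} overlaps another tumor")
        occupied |= sup
        values = np.zeros(spec.grid_shape)
        if isinstance(t.uptake, (tuple, list)):
            core_level, rim_level = (float(v) for v in t.uptake)
            core = t.support(centers, scale=t.core_fraction)
            values[sup] = rim_level
            values[sup & core] = core_level
        else:
            values[sup] = float(t.uptake)
        above = sup & (values > bg)
        if not above.any():
            raise ValueError(
                f"tumor {t.label!r} has no uptake above background: RC undefined"
            )
        activity[sup] = values[sup]
        rcs.append(VoiMask(above, spec.spacing, spec.origin, spec.frame_id,
                           label=t.label))
    image = ImageVolume(activity, spec.spacing, spec.origin, spec.frame_id)
    return image, rcs


# ----------------------------------------------------------- reconstruction

@dataclass
class ReconConfig:
    """Acquisition + reconstruction settings for the simulation chain."""

    n_angles: int = 60
    n_radial_bins: int | None = None  # default: grid diagonal + margin
    counts_target: float = 1e6  # expected total TRUE counts
    scatter_fraction: float = 0.1
    randoms_fraction: float = 0.05
    psf_fwhm_mm: float = 5.0  # scanner resolution blur, image space
    algorithm: str = "OSEM"  # or "FBP"
    osem_iterations: int = 4
    osem_subsets: int = 6
    psf_in_recon: bool = False
    post_filter_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate YAML-1.1 style scientific notation arriving as strings
        self.counts_target = float(self.counts_target)
        self.scatter_fraction = float(self.scatter_fraction)
        self.randoms_fraction = float(self.randoms_fraction)
        self.psf_fwhm_mm = float(self.psf_fwhm_mm)
        self.post_filter_fwhm_mm = float(self.post_filter_fwhm_mm)
        if self.counts_target <= 0:
            raise ValueError("counts_target must be > 0")
        if self.scatter_fraction + self.randoms_fraction >= 1:
            raise ValueError("scatter_fraction + randoms_fraction must be < 1")
        if min(self.scatter_fraction, self.randoms_fraction) < 0:
            raise ValueError("contamination fractions must be >= 0")
        if self.algorithm not in {"FBP", "OSEM"}:
            raise ValueError("algorithm must be 'FBP' or 'OSEM'")
        if self.n_angles % self.osem_subsets != 0:
            raise ValueError(
                f"osem_subsets={self.osem_subsets} must divide n_angles={self.n_angles}"
            )

    def validate_for_shape(self, shape: tuple[int, int, int]) -> None:
        min_angles = max(shape[0], shape[1]) // 2
        if self.n_angles < min_angles:
            raise ValueError(
                f"n_angles={self.n_angles} too small for a "
                f"{shape[0]}x{shape[1]} grid (need >= {min_angles})"
            )


@dataclass
class Sinogram:
    """Projection data, one (n_angles, n_bins) plane per axial slice.

    ``kind`` is "trues" (noise-free line integrals in activity units) or
    "counts" (Poisson counts; ``additive`` holds the expected uniform
    scatter+randoms component and ``scale`` the counts-per-activity-unit
    factor applied before the Poisson draw).
    """

    data: np.ndarray  # (nz, n_angles, n_bins)
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    frame_id: str
    kind: str = "trues"
    additive: np.ndarray | None = None
    scale: float = 1.0

    @property
    def n_angles(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]


@lru_cache(maxsize=16)
def _projector_unit(nx: int, ny: int, n_angles: int, n_bins: int) -> sparse.csr_matrix:
    """Pixel-driven parallel-beam projector, bin width = pixel size.

    Each pixel's value is distributed to the two detector bins nearest its
    projected position with linear weights; the weights of a pixel sum to 1
    for every angle, so per-angle mass is conserved exactly.
    """
    xs = np.arange(nx) - (nx - 1) / 2.0
    ys = np.arange(ny) - (ny - 1) / 2.0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cols = np.arange(nx * ny)
    rows_l, cols_l, vals_l = [], [], []
    for m in range(n_angles):
        th = m * math.pi / n_angles
        s = (X * math.cos(th) + Y * math.sin(th)).ravel() + (n_bins - 1) / 2.0
        i0 = np.floor(s).astype(np.int64)
        if i0.min() < 0 or i0.max() + 1 >= n_bins:
            raise ValueError(
                f"n_radial_bins={n_bins} too small for a {nx}x{ny} grid"
            )
        w1 = s - i0
        rows_l += [m * n_bins + i0, m * n_bins + i0 + 1]
        cols_l += [cols, cols]
        vals_l += [1.0 - w1, w1]
    P = sparse.csr_matrix(
        (np.concatenate(vals_l),
         (np.concatenate(rows_l), np.concatenate(cols_l))),
        shape=(n_angles * n_bins, nx * ny),
    )
    return P


def _default_bins(nx: int, ny: int) -> int:
    return int(math.ceil(math.hypot(nx, ny))) + 5


def project_slice(plane: np.ndarray, n_angles: int, n_bins: int,
                  pixel_size: float) -> np.ndarray:
    """Forward-project one 2-D plane; returns (n_angles, n_bins) line integrals."""
    nx, ny = plane.shape
    P = _projector_unit(nx, ny, n_angles, n_bins)
    return (P @ plane.ravel()).reshape(n_angles, n_bins) * pixel_size


def backproject_slice(sino2d: np.ndarray, shape: tuple[int, int],
                      pixel_size: float) -> np.ndarray:
    """Exact adjoint of :func:`project_slice` (up to float rounding)."""
    n_angles, n_bins = sino2d.shape
    P = _projector_unit(shape[0], shape[1], n_angles, n_bins)
    return (P.T @ sino2d.ravel()).reshape(shape) * pixel_size


def forward_project(activity: ImageVolume, cfg: ReconConfig) -> Sinogram:
    """Slice-wise parallel-beam projection with optional PSF pre-blur.

    Linear and non-negativity preserving; the per-angle bin sums equal the
    (blurred) slice activity times the pixel size for every angle.
    """
    cfg.validate_for_shape(activity.shape)
    sx, sy, _ = activity.spacing
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError("in-plane voxel spacing must be isotropic for projection")
    vol = activity.voxels
    if cfg.psf_fwhm_mm > 0:
        sigma = [cfg.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in activity.spacing]
        vol = ndimage.gaussian_filter(vol, sigma)
    nx, ny, nz = activity.shape
    n_bins = cfg.n_radial_bins or _default_bins(nx, ny)
    data = np.empty((nz, cfg.n_angles, n_bins))
    for k in range(nz):
        data[k] = project_slice(vol[:, :, k], cfg.n_angles, n_bins, sx)
    return Sinogram(data, activity.shape, activity.spacing, activity.origin,
                    activity.frame_id)


def add_counts_noise(sino: Sinogram, cfg: ReconConfig) -> Sinogram:
    """Scale trues to the target count level and draw Poisson counts.

    Uniform additive scatter and randoms components are added so that the
    expected total is counts_target / (1 - scatter_fraction -
    randoms_fraction); the draw is seeded and bit-reproducible.
    """
    if sino.kind != "trues":
        raise ValueError("add_counts_noise expects a noise-free sinogram")
    total = float(sino.data.sum())
    if total <= 0:
        raise ValueError("sinogram carries no activity")
    alpha = cfg.counts_target / total
    trues = sino.data * alpha
    frac = cfg.scatter_fraction + cfg.randoms_fraction
    add_total = cfg.counts_target * frac / (1.0 - frac)
    additive = np.full_like(trues, add_total / trues.size)
    lam = trues + additive
    rng = np.random.default_rng(cfg.seed)
    counts = rng.poisson(lam).astype(np.float64)
    return Sinogram(counts, sino.grid_shape, sino.spacing, sino.origin,
                    sino.frame_id, kind="counts", additive=additive,
                    scale=alpha)


def _ramp_filter(sino2d: np.ndarray, bin_width: float) -> np.ndarray:
    n_angles, n_bins = sino2d.shape
    m = 1 << max(6, int(math.ceil(math.log2(2 * n_bins))))
    freqs = np.fft.fftfreq(m, d=bin_width)
    filt = np.abs(freqs)
    spec = np.fft.fft(sino2d, n=m, axis=1) * filt
    return np.real(np.fft.ifft(spec, axis=1))[:, :n_bins]


def _sino_as_precorrected(sino: Sinogram) -> np.ndarray:
    """Counts minus the expected additive component, in activity units."""
    if sino.kind == "counts":
        add = sino.additive if sino.additive is not None else 0.0
        return (sino.data - add) / sino.scale
    return sino.data


def reconstruct_fbp(sino: Sinogram, cfg: ReconConfig) -> ImageVolume:
    """Filtered back-projection with a ramp filter; output clipped at 0.

    The additive scatter/randoms expectation is subtracted from the counts
    before filtering (simple pre-correction).
    """
    nx, ny, nz = sino.grid_shape
    y = _sino_as_precorrected(sino)
    pixel = sino.spacing[0]
    out = np.empty(sino.grid_shape)
    for k in range(nz):
        filtered = _ramp_filter(y[k], pixel)
        # backprojection sum over angles * dtheta; the unit projector's
        # interpolation weights sum to 1 per pixel and angle
        bp = backproject_slice(filtered, (nx, ny), 1.0)
        out[:, :, k] = bp * (math.pi / sino.n_angles)
    if cfg.post_filter_fwhm_mm > 0:
        sigma = [cfg.post_filter_fwhm_mm * _FWHM_TO_SIGMA / s for s in sino.spacing]
        out = ndimage.gaussian_filter(out, sigma)
    np.clip(out, 0.0, None, out=out)
    return ImageVolume(out, sino.spacing, sino.origin, sino.frame_id)


def reconstruct_osem(sino: Sinogram, cfg: ReconConfig) -> ImageVolume:
    """Ordered-subset EM reconstruction.

    Multiplicative updates over interleaved angle subsets preserve
    non-negativity; the expected additive component is modelled inside the
    forward projection of the update (not pre-subtracted). With
    ``psf_in_recon`` an isotropic Gaussian PSF is applied inside the system
    operator (and, being symmetric, inside its adjoint).
    """
    nx, ny, nz = sino.grid_shape
    pixel = sino.spacing[0]
    n_angles, n_bins = sino.n_angles, sino.n_bins
    P = _projector_unit(nx, ny, n_angles, n_bins)
    subsets = [np.arange(s, n_angles, cfg.osem_subsets)
               for s in range(cfg.osem_subsets)]
    rows = [
        (idx[:, None] * n_bins + np.arange(n_bins)[None, :]).ravel()
        for idx in subsets
    ]
    P_s = [P[r] * pixel for r in rows]

    sigma_pix = 0.0
    if cfg.psf_in_recon and cfg.psf_fwhm_mm > 0:
        sigma_pix = cfg.psf_fwhm_mm * _FWHM_TO_SIGMA / pixel

    def blur(x2d: np.ndarray) -> np.ndarray:
        if sigma_pix > 0:
            return ndimage.gaussian_filter(x2d, sigma_pix)
        return x2d

    sens = []
    for Ps in P_s:
        s_img = (Ps.T @ np.ones(Ps.shape[0])).reshape(nx, ny)
        sens.append(np.maximum(blur(s_img), 1e-12))

    if sino.kind == "counts":
        scale = sino.scale
        additive = sino.additive if sino.additive is not None else np.zeros_like(sino.data)
    else:
        scale = 1.0
        additive = np.zeros_like(sino.data)

    eps = 1e-12
    out = np.empty(sino.grid_shape)
    for k in range(nz):
        yk = sino.data[k]
        rk = additive[k]
        x = np.full((nx, ny), max(yk.sum(), 1.0) / (nx * ny * pixel))
        for _ in range(cfg.osem_iterations):
            for Ps, sk, idx in zip(P_s, sens, subsets):
                fp = (Ps @ blur(x).ravel()).reshape(len(idx), n_bins)
                ratio = yk[idx] / (fp + rk[idx] + eps)
                back = blur((Ps.T @ ratio.ravel()).reshape(nx, ny))
                x = x * back / sk
        out[:, :, k] = x / scale
    if cfg.post_filter_fwhm_mm > 0:
        sigma = [cfg.post_filter_fwhm_mm * _FWHM_TO_SIGMA / s for s in sino.spacing]
        out = ndimage.gaussian_filter(out, sigma)
    np.clip(out, 0.0, None, out=out)
    return ImageVolume(out, sino.spacing, sino.origin, sino.frame_id)


def reconstruct(sino: Sinogram, cfg: ReconConfig) -> ImageVolume:
    if cfg.algorithm == "FBP":
        return reconstruct_fbp(sino, cfg)
    return reconstruct_osem(sino, cfg)


# ----------------------------------------------------------------- studies

def simulate_study(
    phantom: PhantomSpec,
    cfg: ReconConfig,
    dataset_tag: str,
    *,
    study_id: str | None = None,
    site: str = "other",
    acquisition_instance: int = 0,
    reconstruction_id: str | None = None,
    voxel_sampling_id: str = "",
) -> Study:
    """Full chain: build -> project -> noise -> reconstruct -> Study.

    The Study carries the RC(s), the seed and the whole configuration in
    its metadata; rerunning with identical inputs reproduces the image
    bit-for-bit.
    """
    activity, rcs = build_phantom(phantom)
    sino = forward_project(activity, cfg)
    noisy = add_counts_noise(sino, cfg)
    image = reconstruct(noisy, cfg)
    recon_id = reconstruction_id or (
        cfg.algorithm + ("+PSF" if cfg.psf_in_recon else ""))
    sid = study_id or f"{dataset_tag}_{recon_id}_a{acquisition_instance}"
    meta = {"recon": asdict(cfg), "seed": cfg.seed,
            "n_tumors": len(phantom.tumors)}
    return Study(
        study_id=sid, image=image, references=rcs, dataset=dataset_tag,
        site=site, data_type="simulated",
        acquisition_instance=acquisition_instance,
        reconstruction_id=recon_id,
        voxel_sampling_id=voxel_sampling_id or
        f"{phantom.spacing[0]:g}mm", metadata=meta,
    )


# -------------------------------------------------------------- suite files

def default_suite_config() -> dict:
    """A small default benchmark suite covering the four robustness axes:
    acquisition instances (seeds), reconstruction variants, count levels
    and lesion geometry/location, plus two voxel samplings of one object.
    """
    return {
        "dataset": "SIMDEFAULT",
        "background": 1.0,
        "phantoms": [
            {"name": "sphLU", "site": "lung",
             "tumors": [{"shape": "sphere", "center_mm": [64, 64, 32],
                         "size": 12.0, "uptake": 5.0, "label": "sphLU"}]},
            {"name": "ellHN", "site": "H&N",
             "tumors": [{"shape": "ellipsoid", "center_mm": [60, 70, 32],
                         "size": [14.0, 10.0, 12.0], "uptake": 4.0,
                         "label": "ellHN"}]},
        ],
        "samplings": [
            {"id": "vox4", "shape": [32, 32, 16], "spacing": [4.0, 4.0, 4.0]},
            {"id": "vox2", "shape": [64, 64, 32], "spacing": [2.0, 2.0, 2.0]},
        ],
        "recons": [
            {"id": "FBP", "algorithm": "FBP"},
            {"id": "OSEM", "algorithm": "OSEM"},
            {"id": "OSEM+PSF", "algorithm": "OSEM", "psf_in_recon": True},
        ],
        "counts_target": 1e6,
        "seeds": [11, 12, 13],
    }


def make_benchmark_suite(config: dict, out_dir: str | Path | None = None,
                         ) -> StudyDatabase:
    """Generate the cartesian suite phantoms x samplings x recons x seeds.

    When ``out_dir`` is given, images/masks and a ``manifest.json`` loadable
    by :func:`petbench.core_io.load_database` are written there; the files
    are deterministic functions of the configuration.
    """
    db = StudyDatabase()
    dataset = config.get("dataset", "SIM")
    background = config.get("background", 1.0)
    for ph in config["phantoms"]:
        for samp in config["samplings"]:
            tumors = [TumorSpec(
                center_mm=tuple(t["center_mm"]), size=t["size"],
                uptake=tuple(t["uptake"]) if isinstance(t["uptake"], list)
                else t["uptake"],
                shape=t.get("shape", "sphere"),
                core_fraction=t.get("core_fraction", 0.5),
                label=t.get("label", ph["name"]),
            ) for t in ph["tumors"]]
            spec = PhantomSpec(
                grid_shape=tuple(samp["shape"]), spacing=tuple(samp["spacing"]),
                tumors=tumors, background=background,
            )
            for rc_cfg in config["recons"]:
                for inst, seed in enumerate(config["seeds"]):
                    kwargs = {k: v for k, v in rc_cfg.items() if k != "id"}
                    kwargs.setdefault("counts_target",
                                      config.get("counts_target", 1e6))
                    cfg = ReconConfig(seed=int(seed), **kwargs)
                    study = simulate_study(
                        spec, cfg, dataset,
                        study_id=(f"{dataset}_{ph['name']}_{samp['id']}_"
                                  f"{rc_cfg['id']}_a{inst}"),
                        site=ph.get("site", "other"),
                        acquisition_instance=inst,
                        reconstruction_id=rc_cfg["id"],
                        voxel_sampling_id=samp["id"],
                    )
                    db.add(study)
    if out_dir is not None:
        save_database(db, out_dir)
    return db
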