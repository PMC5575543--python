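"""Domain model and file I/O for the benchmark.

The benchmark operates on three kinds of objects: 3-D PET intensity volumes
(:class:`ImageVolume`), binary volumes of interest defined on the same voxel
grid (:class:`VoiMask`), and :class:`Study` records that bundle an image with
one or more reference contours plus acquisition/reconstruction provenance.
All contours in a study live on the image's own grid and frame of reference;
no resampling or registration is performed anywhere in the package.

Coordinate convention: voxel indices are 0-based, and the physical position
(mm) of the *center* of voxel (i, j, k) is ``origin + index * spacing``.
All distances are computed in physical millimetres so that anisotropic
voxels behave correctly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "GeometryError",
    "FormatError",
    "ImageVolume",
    "VoiMask",
    "Study",
    "StudyDatabase",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "rasterize_rtstruct",
    "load_database",
    "save_database",
]


class GeometryError(ValueError):
    """Raised when two objects do not share the same voxel grid / frame."""


class FormatError(ValueError):
    """Raised when a file does not parse as the expected format."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3-D PET activity grid with physical geometry.

    Parameters
    ----------
    voxels:
        3-D array of non-negative, finite activity values (arbitrary units
        or SUV).
    spacing:
        Per-axis voxel size in mm, all components > 0.
    origin:
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    frame_id:
        Text identifier of the frame of reference.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3-D array with each axis >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel values must be non-negative")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        self.origin = _as_tuple3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for an (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.frame_id)

    def same_grid(self, other: "ImageVolume | VoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and self.frame_id == other.frame_id
        )


@dataclass
class VoiMask:
    """A binary voxel set on an :class:`ImageVolume` grid.

    Carries its companion image's geometry unchanged so that set operations
    and physical-space measurements are well defined.
    """

    bits: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise ValueError("bits must be a 3-D boolean array")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        self.origin = _as_tuple3(self.origin, "origin")

    @classmethod
    def from_image(cls, image: ImageVolume, bits: np.ndarray, label: str = "") -> "VoiMask":
        bits = np.asarray(bits, dtype=bool)
        if bits.shape != image.shape:
            raise GeometryError(
                f"mask shape {bits.shape} does not match image shape {image.shape}"
            )
        return cls(bits, image.spacing, image.origin, image.frame_id, label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Set cardinality |A| = number of true voxels."""
        return int(self.bits.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.count * self.voxel_volume_mm3

    def voxel_centers_mm(self) -> np.ndarray:
        """(N, 3) physical coordinates of the centers of the true voxels."""
        idx = np.argwhere(self.bits)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.frame_id)

    def same_grid(self, other: "ImageVolume | VoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and self.frame_id == other.frame_id
        )

    def with_bits(self, bits: np.ndarray, label: str | None = None) -> "VoiMask":
        """New mask with the same geometry (geometry propagation invariant)."""
        return VoiMask(
            bits, self.spacing, self.origin, self.frame_id,
            self.label if label is None else label,
        )


_SITES = {"lung", "H&N", "pelvis", "other"}
_DATA_TYPES = {"clinical", "physical_phantom", "simulated"}


@dataclass
class Study:
    """One PET series with its reference contour(s) and provenance metadata."""

    study_id: str
    image: ImageVolume
    references: list[VoiMask]
    dataset: str
    site: str = "other"
    data_type: str = "simulated"
    acquisition_instance: int = 0
    reconstruction_id: str = ""
    voxel_sampling_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise ValueError(f"site must be one of {sorted(_SITES)}, got {self.site!r}")
        if self.data_type not in _DATA_TYPES:
            raise ValueError(
                f"data_type must be one of {sorted(_DATA_TYPES)}, got {self.data_type!r}"
            )
        if not self.references:
            raise ValueError("a study requires at least one reference contour")
        for rc in self.references:
            if not self.image.same_grid(rc):
                raise GeometryError(
                    f"reference contour {rc.label!r} does not share the image grid "
                    f"in study {self.study_id!r}"
                )
            if not rc.bits.any():
                raise ValueError(
                    f"reference contour {rc.label!r} is empty in study {self.study_id!r}"
                )

    @property
    def reference(self) -> VoiMask:
        """The primary (first) reference contour."""
        return self.references[0]

    def series_key(self) -> tuple:
        return (self.dataset, self.acquisition_instance,
                self.reconstruction_id, self.voxel_sampling_id)


class StudyDatabase:
    """Ordered collection of studies with unique ids (the benchmark dataset)."""

    def __init__(self, studies: Iterable[Study] = (), manifest: Mapping | None = None):
        self.studies: list[Study] = []
        self._by_id: dict[str, Study] = {}
        self.manifest = dict(manifest) if manifest else {}
        for s in studies:
            self.add(s)

    def add(self, study: Study) -> None:
        if study.study_id in self._by_id:
            raise ValueError(f"duplicate study id {study.study_id!r}")
        self.studies.append(study)
        self._by_id[study.study_id] = study

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> Study:
        return self._by_id[study_id]

    def __contains__(self, study_id: str) -> bool:
        return study_id in self._by_id

    def ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def by_dataset(self) -> dict[str, list[Study]]:
        out: dict[str, list[Study]] = {}
        for s in self.studies:
            out.setdefault(s.dataset, []).append(s)
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = aff[:3, :3]
    diag = np.diag(rot)
    if np.any(np.abs(rot - np.diag(diag)) > 1e-4 * max(1.0, np.abs(diag).max())):
        raise FormatError(
            f"{path}: oblique/non-axis-aligned orientation is not supported; "
            "resample the volume to an axis-aligned grid first"
        )
    if np.any(diag <= 0):
        raise FormatError(
            f"{path}: flipped axes (negative affine diagonal) are not supported"
        )
    return tuple(float(d) for d in diag), tuple(float(t) for t in aff[:3, 3])


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI; geometry goes into the affine."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine_from_geometry(volume.spacing, volume.origin))
    img.header["descrip"] = volume.frame_id.encode()[:79]
    nib.save(img, str(path))


def _read_nifti(path: str | Path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing, origin = _geometry_from_affine(np.asarray(img.affine), path)
    # get_fdata applies the header's own slope/intercept; no further rescale.
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    frame_id = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    return ImageVolume(data, spacing, origin, frame_id)


def _read_dicom_series(path: str | Path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"}) \
        if path.is_dir() else [path]
    if not files:
        raise FormatError(f"{path}: no DICOM files found")
    slices = [pydicom.dcmread(str(f)) for f in files]
    for ds in slices:
        iop = [float(v) for v in ds.ImageOrientationPatient]
        if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-4):
            raise FormatError(
                f"{path}: oblique DICOM orientation {iop} is not supported"
            )
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) < 2:
        raise FormatError(f"{path}: a DICOM series needs at least 2 slices")
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise FormatError(f"{path}: duplicate slice positions in series")
    step = np.median(dz)
    bad = np.where(np.abs(dz - step) > 0.01 * step)[0]
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"{path}: inconsistent slice spacing — gap of {dz[i]:.3f} mm between "
            f"z={zs[i]:.3f} and z={zs[i + 1]:.3f} (expected {step:.3f} mm); "
            "a slice is probably missing"
        )
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    spacing = (col_sp, row_sp, float(step))
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + inter)
    # pixel_array is (row, col) = (y, x); volume axes are (x, y, z)
    vol = np.stack([p.T for p in planes], axis=2)
    frame_id = str(getattr(slices[0], "FrameOfReferenceUID", ""))
    return ImageVolume(vol, spacing, origin, frame_id)


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read a PET volume from NIfTI or an axis-aligned DICOM series.

    ``format`` is one of ``{"nifti", "dicom_series"}``; when omitted it is
    inferred from the path (directories are treated as DICOM series).
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_mask(mask: VoiMask, path: str | Path) -> None:
    """Write a mask as an unsigned 8-bit 0/1 NIfTI carrying the grid geometry."""
    img = nib.Nifti1Image(mask.bits.astype(np.uint8),
                          _affine_from_geometry(mask.spacing, mask.origin))
    img.header["descrip"] = mask.frame_id.encode()[:79]
    nib.save(img, str(path))


def read_mask(path: str | Path, image: ImageVolume, label: str = "") -> VoiMask:
    """Read a mask NIfTI and validate it against the companion image grid."""
    vol = _read_nifti(path)
    if vol.shape != image.shape:
        raise GeometryError(
            f"{path}: mask shape {vol.shape} does not match image shape {image.shape}"
        )
    if not (np.allclose(vol.spacing, image.spacing) and np.allclose(vol.origin, image.origin)):
        raise GeometryError(f"{path}: mask geometry does not match the image geometry")
    return VoiMask.from_image(image, vol.voxels > 0.5, label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# DICOM-RT RTSTRUCT rasterization
# ---------------------------------------------------------------------------

def rasterize_rtstruct(
    path: str | Path,
    image: ImageVolume,
    roi_name: str,
    *,
    allow_frame_mismatch: bool = False,
) -> VoiMask:
    """Rasterize the named RTSTRUCT ROI onto the image grid.

    Planar polygons are rasterized slice-wise; a voxel belongs to the mask
    iff its center is inside the polygon (even-odd rule across multiple
    contours on a slice, boundary-inclusive: a center exactly on an edge
    counts as inside).
    """
    import shapely

    ds = pydicom.dcmread(str(path))
    names = {r.ROIName: r.ROINumber for r in ds.StructureSetROISequence}
    if roi_name not in names:
        raise KeyError(
            f"ROI {roi_name!r} not found in {path}; available: {sorted(names)}"
        )
    frame = ""
    try:
        frame = str(ds.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID)
    except Exception:
        pass
    if frame and image.frame_id and frame != image.frame_id:
        msg = (f"RTSTRUCT frame of reference {frame!r} does not match the image's "
               f"{image.frame_id!r}")
        if not allow_frame_mismatch:
            raise GeometryError(msg + " (pass allow_frame_mismatch=True to override)")
        warnings.warn(msg + "; proceeding because allow_frame_mismatch=True")

    number = names[roi_name]
    contours = []
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber == number:
            contours = list(getattr(rc, "ContourSequence", []))
    bits = np.zeros(image.shape, dtype=bool)
    sx, sy, sz = image.spacing
    ox, oy, oz = image.origin
    nx, ny, _ = image.shape
    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for item in contours:
        pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
        z = float(np.mean(pts[:, 2]))
        k = (z - oz) / sz
        ki = int(round(k))
        if abs(k - ki) > 0.5 or not (0 <= ki < image.shape[2]):
            raise GeometryError(
                f"contour plane z={z:.3f} mm does not coincide with an image slice"
            )
        poly = shapely.Polygon(pts[:, :2])
        inside = shapely.intersects_xy(poly, X.ravel(), Y.ravel()).reshape(nx, ny)
        bits[:, :, ki] ^= inside  # even-odd across rings on the same slice
    return VoiMask.from_image(image, bits, label=roi_name)


# ---------------------------------------------------------------------------
# Study database manifest (JSON)
# ---------------------------------------------------------------------------

def load_database(manifest_path: str | Path) -> StudyDatabase:
    """Load a study database from a JSON manifest.

    The manifest lists, per study: id, image path, reference-mask paths with
    labels, and the Study metadata fields. Paths are relative to the manifest
    file. Every study is validated against the domain invariants; problems
    are reported with the offending study id.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    db = StudyDatabase(manifest=manifest)
    seen: set[str] = set()
    for entry in manifest["studies"]:
        sid = entry["id"]
        if sid in seen:
            raise ValueError(f"duplicate study id {sid!r} in manifest")
        seen.add(sid)
        image_path = base / entry["image"]
        if not image_path.exists():
            raise FileNotFoundError(f"study {sid!r}: missing image file {image_path}")
        image = read_volume(image_path, entry.get("image_format"))
        refs = []
        for ref in entry["references"]:
            rp = base / ref["path"]
            if not rp.exists():
                raise FileNotFoundError(f"study {sid!r}: missing mask file {rp}")
            try:
                refs.append(read_mask(rp, image, label=ref.get("label", "")))
            except GeometryError as exc:
                raise GeometryError(f"study {sid!r}: {exc}") from exc
        try:
            db.add(Study(
                study_id=sid,
                image=image,
                references=refs,
                dataset=entry.get("dataset", "default"),
                site=entry.get("site", "other"),
                data_type=entry.get("data_type", "simulated"),
                acquisition_instance=int(entry.get("acquisition_instance", 0)),
                reconstruction_id=entry.get("reconstruction_id", ""),
                voxel_sampling_id=entry.get("voxel_sampling_id", ""),
                metadata=entry.get("metadata", {}),
            ))
        except (ValueError, GeometryError) as exc:
            raise type(exc)(f"study {sid!r}: {exc}") from exc
    return db


def save_database(db: StudyDatabase, out_dir: str | Path) -> Path:
    """Write all studies (image + masks) and a manifest.json under ``out_dir``.

    Returns the manifest path. Volumes are written as uncompressed NIfTI so
    that regenerating a suite from the same configuration yields byte-
    identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in db.studies:
        img_rel = f"{s.study_id}_pet.nii"
        write_volume(s.image, out_dir / img_rel)
        refs = []
        for i, rc in enumerate(s.references):
            rel = f"{s.study_id}_rc{i}.nii"
            write_mask(rc, out_dir / rel)
            refs.append({"path": rel, "label": rc.label or f"rc{i}"})
        entries.append({
            "id": s.study_id,
            "image": img_rel,
            "references": refs,
            "dataset": s.dataset,
            "site": s.site,
            "data_type": s.data_type,
            "acquisition_instance": s.acquisition_instance,
            "reconstruction_id": s.reconstruction_id,
            "voxel_sampling_id": s.voxel_sampling_id,
            "metadata": s.metadata,
        })
    manifest = {"schema": "petbench-manifest-v1", "studies": entries}
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest_path
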