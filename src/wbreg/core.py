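"""Image, label and landmark data model with physical geometry and file I/O.

All spatial quantities in this package live in physical millimetres: the
clinical volumes the pipeline targets have strongly anisotropic voxels
(CT ~1.37x1.37x2.5 mm, MR ~1.9x1.9x6 mm), so voxel-space distances are
meaningless.  Conventions:

* array axes are (x, y, z); 0-based voxel indices;
* the centre of voxel ``i`` sits at ``origin + i * spacing``;
* only axis-aligned volumes are supported — non-trivial direction cosines
  are rejected at read time rather than silently mishandled.

NIfTI I/O goes through nibabel, MetaImage I/O through SimpleITK (I/O only).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class VolumeFormatError(ValueError):
    """Unreadable or unsupported volume header."""


class LandmarkFormatError(ValueError):
    """Malformed landmark point file."""


class GeometryError(ValueError):
    """Mismatched or invalid physical geometry."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data
        Rank-3 array, axes (x, y, z).  Intensity units are modality
        dependent (Hounsfield units for CT-like data, arbitrary for MR).
    spacing
        Voxel size per axis in mm, strictly positive.
    origin
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) == 0:
            raise GeometryError("volume data must be rank 3 with no size-0 axis")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_to_physical(self, index) -> np.ndarray:
        """Physical position (mm) of a voxel index; integer indices are bounds-checked."""
        idx = np.asarray(index)
        if idx.shape == (3,) and np.issubdtype(idx.dtype, np.integer):
            if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
                raise IndexError(f"voxel index {tuple(idx)} outside volume of shape {self.shape}")
        return self.origin + idx * self.spacing

    def physical_to_voxel(self, points) -> np.ndarray:
        """Continuous voxel coordinates of physical points (no rounding)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    @property
    def bounds(self) -> tuple:
        """(lo, hi) physical positions of the first and last voxel centres."""
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    @property
    def center(self) -> np.ndarray:
        lo, hi = self.bounds
        return 0.5 * (lo + hi)

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical positions of every voxel centre, x-fastest."""
        grids = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        idx = np.stack([g.reshape(-1) for g in grids], axis=1)
        return self.origin + idx * self.spacing

    def same_geometry(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelVolume:
    """Integer-coded organ masks sharing a Volume's geometry.

    ``regions`` maps region name to integer code; background is 0 and is
    never listed.  The array stores the *most specific* region per voxel;
    the conventional region ``"body"`` denotes the union of all nonzero
    labels (organs are nested inside the body), every other region is an
    exact code match — see :meth:`region_mask`.
    """

    labels: np.ndarray
    regions: dict
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("label array must have an integer dtype")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.regions.values())
        if not present <= known:
            raise GeometryError(
                f"labels contain codes {sorted(present - known)} missing from the region map"
            )

    @property
    def geometry(self) -> Volume:
        """The label array wrapped as a Volume (shares memory)."""
        v = Volume.__new__(Volume)
        v.data = self.labels
        v.spacing = self.spacing
        v.origin = self.origin
        return v

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of a named region ('body' = union of all nonzero labels)."""
        if name == "body" and "body" in self.regions:
            return self.labels > 0
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; known: {sorted(self.regions)}")
        return self.labels == self.regions[name]


@dataclass
class LandmarkSet:
    """Named physical points (mm) defined on one volume.

    Paired fixed/moving sets must share identical name lists and order.
    """

    names: list
    points: np.ndarray

    def __post_init__(self):
        self.names = list(self.names)
        self.points = np.asarray(self.points, dtype=float).reshape(len(self.names), 3)
        if len(set(self.names)) != len(self.names):
            raise LandmarkFormatError("landmark names must be unique within a set")

    def __len__(self):
        return len(self.names)

    def __eq__(self, other):
        return (
            isinstance(other, LandmarkSet)
            and self.names == other.names
            and np.array_equal(self.points, other.points)
        )


# ---------------------------------------------------------------------------
# Volume I/O


def _check_axis_aligned(mat3: np.ndarray, what: str):
    mat3 = np.asarray(mat3, dtype=float)
    scale = np.abs(np.diag(mat3))
    off = mat3 - np.diag(np.diag(mat3))
    if np.any(np.abs(off) > 1e-4 * max(scale.max(), 1.0)):
        raise VolumeFormatError(
            f"{what}: non-axis-aligned orientation is not supported "
            f"(off-diagonal terms {off[np.abs(off) > 0].tolist()})"
        )
    if np.any(np.diag(mat3) <= 0):
        raise VolumeFormatError(
            f"{what}: flipped/negative axis orientation is not supported "
            f"(diagonal {np.diag(mat3).tolist()})"
        )


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        _check_axis_aligned(affine[:3, :3], f"{path}: affine")
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
        return Volume(data, np.diag(affine[:3, :3]), affine[:3, 3])
    if lower.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        if img.GetDimension() != 3:
            raise VolumeFormatError(f"{path}: expected 3D data, got {img.GetDimension()}D")
        _check_axis_aligned(np.array(img.GetDirection()).reshape(3, 3), f"{path}: Direction")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        return Volume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    raise VolumeFormatError(f"{path}: unsupported volume format (use .nii/.nii.gz/.mha/.mhd)")


def write_volume(vol: Volume, path) -> None:
    """Write a volume; format chosen from the file extension."""
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), path)
        return
    if lower.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, path)
        return
    raise VolumeFormatError(f"{path}: unsupported volume format (use .nii/.nii.gz/.mha/.mhd)")


# ---------------------------------------------------------------------------
# Landmark I/O
#
# Plain-text dialect: line 1 is the literal word "point" (physical mm) or
# "index" (voxel indices, converted on read against a reference volume);
# line 2 the point count N; then N lines of three whitespace-separated
# numbers, optionally followed by "# name".  Unnamed points are given
# sequential names on read.


def read_landmarks(path, reference: Volume | None = None) -> LandmarkSet:
    path = os.fspath(path)
    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise LandmarkFormatError(f"{path}: empty landmark file")
    lineno, header = lines[0]
    if header not in ("point", "index"):
        raise LandmarkFormatError(f"{path}:{lineno}: header must be 'point' or 'index', got {header!r}")
    if len(lines) < 2:
        raise LandmarkFormatError(f"{path}: missing point count line")
    lineno, count_s = lines[1]
    try:
        count = int(count_s)
    except ValueError:
        raise LandmarkFormatError(f"{path}:{lineno}: point count must be an integer, got {count_s!r}")
    body = lines[2:]
    if len(body) != count:
        raise LandmarkFormatError(
            f"{path}: count line says {count} points but file has {len(body)} coordinate lines"
        )
    names, pts = [], []
    for lineno, ln in body:
        coord_part, _, name = ln.partition("#")
        fields = coord_part.split()
        if len(fields) != 3:
            raise LandmarkFormatError(
                f"{path}:{lineno}: expected three coordinates, got {len(fields)}"
            )
        try:
            pts.append([float(f) for f in fields])
        except ValueError:
            raise LandmarkFormatError(f"{path}:{lineno}: non-numeric coordinate in {fields}")
        names.append(name.strip() or f"p{len(names):03d}")
    pts = np.array(pts, dtype=float).reshape(count, 3)
    if header == "index":
        if reference is None:
            raise LandmarkFormatError(
                f"{path}: 'index' landmark files need a reference volume to convert to mm"
            )
        pts = reference.origin + pts * reference.spacing
    try:
        return LandmarkSet(names, pts)
    except LandmarkFormatError as exc:
        raise LandmarkFormatError(f"{path}: {exc}") from None


def write_landmarks(lms: LandmarkSet, path) -> None:
    with open(os.fspath(path), "w") as fh:
        fh.write("point\n")
        fh.write(f"{len(lms)}\n")
        for name, p in zip(lms.names, lms.points):
            fh.write("%.17g %.17g %.17g # %s\n" % (p[0], p[1], p[2], name))


def pair_check(fixed: LandmarkSet, moving: LandmarkSet) -> None:
    """Validate that two landmark sets are pairable (same names, same order)."""
    if fixed.names != moving.names:
        raise LandmarkFormatError(
            "landmark sets are not paired: name lists differ "
            f"({fixed.names[:3]}... vs {moving.names[:3]}...)"
        )
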