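"""Core geometric containers: volumes, stacks, label maps and rigid transforms.

Conventions
-----------
* World space is RAS+ in millimetres.  Orientation lives entirely in the
  4x4 voxel-to-world affine, exactly as in a NIfTI header; voxel data are
  stored in ``[i, j, k]`` index order and the affine maps *voxel centres*
  to world coordinates.
* Rigid transforms map world points to world points (mm).  Applying a
  transform ``T`` to an image means replacing its affine ``A`` by
  ``T @ A`` — a pure header update that moves the image content by ``T``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class FetalReconError(Exception):
    """Base class for all package errors."""


class InvalidTransformError(FetalReconError):
    """Rotation matrix is not a proper rotation."""


class GridMismatchError(FetalReconError):
    """Two volumes expected on a common grid are not."""


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------

def _rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    axis = axis / n
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def rotation_from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle (rotation-vector, radians) triple."""
    rotvec = np.asarray(rotvec, dtype=float)
    angle = np.linalg.norm(rotvec)
    if angle < 1e-30:
        return np.eye(3)
    return _rotation_from_axis_angle(rotvec / angle, np.rad2deg(angle))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` in world millimetres."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or \
                np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise InvalidTransformError(
                "R is not a proper rotation (det=%.3g)" % np.linalg.det(R))
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return RigidTransform(M[:3, :3], M[:3, 3])

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, center=None,
                        translation=None) -> "RigidTransform":
        """Rotation about ``center`` (world mm) plus an optional translation."""
        R = _rotation_from_axis_angle(axis, angle_deg)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return RigidTransform(R, t)

    @staticmethod
    def from_params(params: np.ndarray, center=None) -> "RigidTransform":
        """6-vector ``(rx, ry, rz [rad], tx, ty, tz [mm])``, rotation about center."""
        params = np.asarray(params, dtype=float)
        R = rotation_from_rotvec(params[:3])
        t = params[3:6].copy()
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return RigidTransform(R, t)

    # -- algebra -----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other`` — apply *other* first."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def distance_to(self, other: "RigidTransform",
                    reference_point=None) -> tuple[float, float]:
        """(rotation angle deg, translation mm) of ``self⁻¹ ∘ other``.

        Translation is evaluated at ``reference_point`` (default origin) so
        that the error is meaningful for rotations about off-origin centres.
        """
        d = self.inverse().compose(other)
        p = np.zeros(3) if reference_point is None else np.asarray(reference_point)
        return d.rotation_angle_deg(), float(np.linalg.norm(d.apply(p) - p))


# --------------------------------------------------------------------------
# Image containers
# --------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """3D scalar voxel grid with a voxel-centre-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume requires 3D data")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("non-invertible affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (mm) along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def center_world(self) -> np.ndarray:
        c = (np.asarray(self.shape, float) - 1.0) / 2.0
        return self.voxel_to_world(c)

    def grid_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.moveaxis(idx, 0, -1).reshape(-1, 3)
        return self.voxel_to_world(pts).reshape(*self.shape, 3)

    def sample_world(self, xyz: np.ndarray, order: int = 1,
                     cval: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world points ``xyz`` (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        flat = xyz.reshape(-1, 3)
        vox = self.world_to_voxel(flat)
        vals = map_coordinates(self.data.astype(float, copy=False), vox.T,
                               order=order, cval=cval, mode="constant")
        return vals.reshape(xyz.shape[:-1])

    def resample_to(self, affine: np.ndarray, shape, order: int = 1,
                    transform: RigidTransform | None = None,
                    cval: float = 0.0) -> "ImageVolume":
        """Resample onto a target grid, optionally after moving by ``transform``.

        ``transform`` maps this volume's world frame into the target frame;
        the output voxel at target-world point ``y`` takes the value
        ``self(transform⁻¹ y)``.
        """
        target = ImageVolume(np.zeros(tuple(int(s) for s in shape)), affine)
        pts = target.grid_world().reshape(-1, 3)
        if transform is not None:
            pts = transform.inverse().apply(pts)
        vals = self.sample_world(pts, order=order, cval=cval)
        return ImageVolume(vals.reshape(target.shape), np.asarray(affine, float))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.affine.copy())

    # -- I/O ---------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @staticmethod
    def load(path: str) -> "ImageVolume":
        img = nib.load(path)
        return ImageVolume(np.asanyarray(img.dataobj), img.affine)


@dataclass
class LabelMap(ImageVolume):
    """Integer volume with mutually exclusive named labels."""

    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.labels[name]

    def volume_mm3(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.voxel_volume_mm3

    def centroid_world(self, name: str) -> np.ndarray:
        """Unweighted mean of voxel centres carrying the label, in world mm."""
        ijk = np.argwhere(self.mask(name))
        if ijk.size == 0:
            raise ValueError(f"label {name!r} is empty")
        return self.voxel_to_world(ijk.mean(axis=0))

    def resample_to(self, affine, shape, transform=None, order: int = 0,
                    cval: float = 0.0) -> "LabelMap":
        out = super().resample_to(affine, shape, order=order,
                                  transform=transform, cval=cval)
        return LabelMap(np.rint(out.data).astype(self.data.dtype),
                        out.affine, labels=dict(self.labels))

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.affine.copy(),
                        labels=dict(self.labels))


@dataclass
class Stack(ImageVolume):
    """A multi-slice acquisition: an ImageVolume whose last index axis is the
    slice axis, with per-slice package bookkeeping and optional simulation
    ground truth attached."""

    slice_thickness_mm: float = 2.5
    slice_spacing_mm: float = 1.25
    package_index: np.ndarray | None = None
    name: str = "stack"
    # simulation ground truth (None on clinical data)
    truth_global: LabelMap | None = None
    truth_organs: LabelMap | None = None
    true_pose: RigidTransform | None = None

    def __post_init__(self):
        super().__post_init__()
        if self.package_index is None:
            self.package_index = np.zeros(self.data.shape[2], dtype=int)
        self.package_index = np.asarray(self.package_index, dtype=int)
        if self.package_index.shape != (self.data.shape[2],):
            raise ValueError("package_index must have one entry per slice")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def get_slice(self, k: int) -> np.ndarray:
        return self.data[:, :, k]

    def with_data(self, data: np.ndarray) -> "Stack":
        out = dataclasses.replace(self, data=data)
        return out

    def with_affine(self, affine: np.ndarray) -> "Stack":
        """Header-only update: same voxels, new voxel-to-world mapping.

        Ground-truth label maps share the stack grid, so their headers are
        updated consistently.
        """
        out = dataclasses.replace(self, affine=np.asarray(affine, float))
        if out.truth_global is not None:
            out.truth_global = LabelMap(out.truth_global.data, affine,
                                        labels=dict(out.truth_global.labels))
        if out.truth_organs is not None:
            out.truth_organs = LabelMap(out.truth_organs.data, affine,
                                        labels=dict(out.truth_organs.labels))
        return out

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str) -> None:
        super().save(path)
        meta = {
            "slice_thickness_mm": self.slice_thickness_mm,
            "slice_spacing_mm": self.slice_spacing_mm,
            "package_index": self.package_index.tolist(),
            "name": self.name,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh)

    @staticmethod
    def load(path: str) -> "Stack":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        meta_path = str(path) + ".meta.json"
        kw = {}
        try:
            with open(meta_path) as fh:
                meta = json.load(fh)
            kw = dict(slice_thickness_mm=meta["slice_thickness_mm"],
                      slice_spacing_mm=meta["slice_spacing_mm"],
                      package_index=np.asarray(meta["package_index"]),
                      name=meta.get("name", "stack"))
        except FileNotFoundError:
            pass
        return Stack(data, img.affine, **kw)


def centered_affine(shape, spacing, directions: np.ndarray | None = None,
                    center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Affine for a grid whose centre sits at ``center`` (world mm).

    ``directions`` is a rotation applied to the grid axes (default identity,
    i.e. axis-aligned RAS+).
    """
    shape = np.asarray(shape, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    D = np.eye(3) if directions is None else np.asarray(directions, float)
    A = np.eye(4)
    A[:3, :3] = D @ np.diag(spacing)
    A[:3, 3] = np.asarray(center, float) - A[:3, :3] @ ((shape - 1) / 2.0)
    return A
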