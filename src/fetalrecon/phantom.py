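"""Digital fetal-trunk phantom and motion-corrupted stack simulator.

The phantom is a purely geometric stand-in for fetal anatomy: nested
ellipsoids for the uterus shell, trunk, thorax, abdomen, heart, liver and
brain, plus a few dark tubular "vessels" inside the thorax that give the
super-resolution stage fine structure to recover.  A smooth seeded texture
is added inside the fetus so that intensity-based registration has
non-degenerate structure to lock onto.

Stack simulation mimics a single-shot T2 acquisition at desk scale: the
phantom is moved by a rigid pose (rotation about the trunk centroid),
sampled slice-by-slice through a Gaussian (or boxcar) slice profile of
FWHM equal to the slice thickness, and optionally corrupted by per-slice
rigid jitter, a smooth multiplicative bias field and Gaussian noise.
No MR physics (T2 decay, k-space) is modelled.

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (FetalReconError, ImageVolume, LabelMap, RigidTransform,
                   Stack, centered_affine)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PhantomGeometryError(FetalReconError):
    """Organ geometry violates the containment invariants."""


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def quadratic(self, pts: np.ndarray) -> np.ndarray:
        """((x-c)/a)² summed — ≤ 1 inside."""
        d = (np.asarray(pts, float) - np.asarray(self.center)) \
            / np.asarray(self.semi_axes)
        return (d * d).sum(axis=-1)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.quadratic(pts) <= 1.0

    def boundary_points(self, n: int = 400) -> np.ndarray:
        """Deterministic quasi-uniform sample of the surface (Fibonacci)."""
        i = np.arange(n, dtype=float)
        z = 1.0 - 2.0 * (i + 0.5) / n
        phi = i * np.pi * (3.0 - np.sqrt(5.0))
        r = np.sqrt(np.clip(1 - z * z, 0, 1))
        sphere = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)
        return sphere * np.asarray(self.semi_axes) + np.asarray(self.center)


@dataclass(frozen=True)
class Tube:
    """Cylinder segment (``p0`` to ``p1``, radius mm) — a mock vessel."""
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, float)
        d = np.asarray(self.p1, float) - p0
        L2 = float(d @ d)
        v = np.asarray(pts, float) - p0
        s = np.clip((v @ d) / L2, 0.0, 1.0)
        closest = p0 + s[..., None] * d
        dist2 = ((np.asarray(pts, float) - closest) ** 2).sum(axis=-1)
        return dist2 <= self.radius ** 2


GLOBAL_LABELS = {"background": 0, "uterus": 1, "brain": 2, "trunk": 3}
ORGAN_LABELS = {"background": 0, "thorax": 1, "abdomen": 2,
                "heart": 3, "liver": 4}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and sampling grid of the digital phantom.

    The default grid is 160³ voxels at 0.7 mm isotropic spacing (112 mm
    field of view, matching the reconstruction output resolution); reduced
    desk-scale grids keep the same 112 mm field of view with coarser voxels.
    All organ geometry is expressed in world mm about the grid centre.
    """

    grid_size: int = 160
    voxel_mm: float = 0.7
    uterus_outer: Ellipsoid = Ellipsoid((0, 0, 0), (54, 52, 50))
    uterus_inner: Ellipsoid = Ellipsoid((0, 0, 0), (50, 48, 46))
    trunk: Ellipsoid = Ellipsoid((0, 0, -4), (26, 24, 34))
    thorax: Ellipsoid = Ellipsoid((0, 0, 9), (20, 18, 15))
    abdomen: Ellipsoid = Ellipsoid((0, 1, -18), (20, 19, 15))
    heart: Ellipsoid = Ellipsoid((5, 3, 12), (8, 7, 7))
    liver: Ellipsoid = Ellipsoid((-6, 3, -16), (10, 8, 7))
    brain: Ellipsoid = Ellipsoid((0, -1, 37), (9, 9, 8))
    vessels: tuple[Tube, ...] = (
        Tube((2, -6, -2), (2, -6, 22), 1.8),
        Tube((-9, 1, 0), (7, 3, 21), 1.6),
        Tube((-11, 6, 13), (12, 6, 13), 1.5),
    )
    intensity: dict = field(default_factory=lambda: {
        "background": 10.0, "uterus": 60.0, "fluid": 130.0, "trunk": 80.0,
        "thorax": 70.0, "abdomen": 85.0, "heart": 110.0, "liver": 95.0,
        "brain": 100.0, "vessel": 25.0,
    })
    texture_amplitude: float = 8.0
    texture_scale_mm: float = 4.0
    smooth_mm: float = 1.2   # band-limiting blur: tissue interfaces are not
    rng_seed: int = 0        # step edges at MR resolution

    def validate(self) -> None:
        """Numerically enforce the containment invariants."""
        pairs = [
            ("heart", self.heart, "thorax", self.thorax),
            ("liver", self.liver, "abdomen", self.abdomen),
            ("thorax", self.thorax, "trunk", self.trunk),
            ("abdomen", self.abdomen, "trunk", self.trunk),
        ]
        for iname, inner, oname, outer in pairs:
            if not np.all(outer.contains(inner.boundary_points())):
                raise PhantomGeometryError(
                    f"{iname} ellipsoid is not contained in {oname}")
        # non-degenerate 4-landmark configuration
        pts = np.array([self.thorax.center, self.abdomen.center,
                        self.heart.center, self.liver.center], float)
        centred = pts - pts.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        if s[-1] < 1e-3 * s[0]:
            raise PhantomGeometryError("landmark configuration is collinear")


def desk_spec(grid_size: int = 64, **overrides) -> PhantomSpec:
    """Reduced-resolution spec with the standard 112 mm field of view."""
    voxel = 112.0 / grid_size
    return PhantomSpec(grid_size=grid_size, voxel_mm=voxel, **overrides)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMap, LabelMap]:
    """Build the phantom intensity volume and its two ground-truth label maps.

    Returns ``(image, global_labels, organ_labels)`` where the global map
    carries {background, uterus, brain, trunk} and the organ map carries
    {thorax, abdomen, heart, liver} (mutually exclusive: heart and liver
    voxels are not part of the thorax/abdomen labels).
    """
    spec.validate()
    n = int(spec.grid_size)
    affine = centered_affine((n, n, n), spec.voxel_mm)
    grid = ImageVolume(np.zeros((n, n, n)), affine)
    pts = grid.grid_world()

    in_outer = spec.uterus_outer.contains(pts)
    in_inner = spec.uterus_inner.contains(pts)
    in_trunk = spec.trunk.contains(pts)
    in_thorax = spec.thorax.contains(pts)
    in_abdomen = spec.abdomen.contains(pts)
    in_heart = spec.heart.contains(pts)
    in_liver = spec.liver.contains(pts)
    in_brain = spec.brain.contains(pts)
    in_vessel = np.zeros_like(in_trunk)
    for tube in spec.vessels:
        in_vessel |= tube.contains(pts)
    in_vessel &= in_thorax & ~in_heart

    glob = np.zeros((n, n, n), dtype=np.int16)
    glob[in_outer & ~in_inner] = GLOBAL_LABELS["uterus"]
    glob[in_trunk] = GLOBAL_LABELS["trunk"]
    glob[in_brain] = GLOBAL_LABELS["brain"]

    organs = np.zeros((n, n, n), dtype=np.int16)
    organs[in_thorax] = ORGAN_LABELS["thorax"]
    organs[in_abdomen] = ORGAN_LABELS["abdomen"]
    organs[in_heart] = ORGAN_LABELS["heart"]
    organs[in_liver] = ORGAN_LABELS["liver"]

    ity = spec.intensity
    img = np.full((n, n, n), ity["background"], dtype=float)
    img[in_outer & ~in_inner] = ity["uterus"]
    img[in_inner & ~in_trunk & ~in_brain] = ity["fluid"]
    img[in_trunk] = ity["trunk"]
    img[in_thorax] = ity["thorax"]
    img[in_abdomen] = ity["abdomen"]
    img[in_heart] = ity["heart"]
    img[in_liver] = ity["liver"]
    img[in_brain] = ity["brain"]
    img[in_vessel] = ity["vessel"]

    if spec.smooth_mm > 0:
        img = gaussian_filter(img, spec.smooth_mm / spec.voxel_mm)

    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.rng_seed)
        tex = rng.standard_normal((n, n, n))
        tex = gaussian_filter(tex, spec.texture_scale_mm / spec.voxel_mm)
        tex /= max(tex.std(), 1e-12)
        fetus = in_trunk | in_brain
        img[fetus] += spec.texture_amplitude * tex[fetus]

    return (ImageVolume(img, affine),
            LabelMap(glob, affine, labels=dict(GLOBAL_LABELS)),
            LabelMap(organs, affine, labels=dict(ORGAN_LABELS)))


def trunk_centroid(global_labels: LabelMap) -> np.ndarray:
    return global_labels.centroid_world("trunk")


# --------------------------------------------------------------------------
# Stack acquisition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Slice-acquisition geometry and corruption model.

    Defaults follow a clinical single-shot T2 protocol: 1.25 mm in-plane,
    2.5 mm slice thickness with 1.25 mm slice spacing (negative gap /
    two-fold through-plane oversampling), interleaved slice order split
    into 4 packages of 5 mm within-package spacing.
    """

    in_plane_mm: float = 1.25
    slice_thickness_mm: float = 2.5
    slice_spacing_mm: float = 1.25
    n_packages: int = 4
    package_spacing_mm: float = 5.0
    slice_order: str = "interleaved"  # interleaved | ascending
    noise_sigma: float = 0.0
    bias_field_amplitude: float = 0.0
    jitter_rot_deg: float = 0.0
    jitter_trans_mm: float = 0.0
    psf: str = "gaussian"  # gaussian | boxcar
    psf_taps: int = 7
    fov_mm: float | None = None

    def __post_init__(self):
        if self.n_packages < 1:
            raise ValueError("n_packages must be >= 1")
        if self.slice_thickness_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("slice geometry must be positive")
        if self.slice_order not in ("interleaved", "ascending"):
            raise ValueError(f"unknown slice order {self.slice_order!r}")
        if self.psf not in ("gaussian", "boxcar"):
            raise ValueError(f"unknown slice profile {self.psf!r}")


def _psf_taps(acq: AcquisitionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Through-plane sample offsets (mm) and weights for the slice profile."""
    m = int(acq.psf_taps)
    if m == 1:
        return np.zeros(1), np.ones(1)
    if acq.psf == "gaussian":
        sigma = acq.slice_thickness_mm * GAUSSIAN_FWHM_TO_SIGMA
        off = np.linspace(-2.0 * sigma, 2.0 * sigma, m)
        w = np.exp(-0.5 * (off / sigma) ** 2)
    else:
        off = np.linspace(-acq.slice_thickness_mm / 2,
                          acq.slice_thickness_mm / 2, m)
        w = np.ones(m)
    return off, w / w.sum()


def _package_assignment(n_slices: int, acq: AcquisitionSpec) -> np.ndarray:
    if acq.slice_order == "interleaved":
        return np.arange(n_slices) % acq.n_packages
    # ascending: contiguous blocks
    return np.minimum(np.arange(n_slices) * acq.n_packages // n_slices,
                      acq.n_packages - 1)


def simulate_stack(phantom: ImageVolume, pose: RigidTransform,
                   acq: AcquisitionSpec, seed: int,
                   labels: tuple[LabelMap, LabelMap] | None = None,
                   directions: np.ndarray | None = None,
                   name: str = "sim") -> Stack:
    """Simulate one anisotropic stack of the phantom moved by ``pose``.

    The stack grid is axis-aligned with ``directions`` (slice axis = third
    column) and centred on the phantom; the phantom content appears moved
    by ``pose`` in world space, so resampling the stack back through
    ``pose⁻¹`` overlays the phantom.  When ``labels`` (global, organ) are
    given, ground-truth label maps are sampled onto the stack grid
    (nearest neighbour, including per-slice jitter) and attached.
    """
    if np.ptp(phantom.spacing) > 1e-6:
        raise ValueError("phantom must have isotropic spacing")
    if phantom.spacing[0] > acq.slice_thickness_mm:
        raise ValueError("phantom spacing must be finer than slice thickness")
    pose = RigidTransform(pose.R, pose.t)  # re-validates det/orthonormality

    rng = np.random.default_rng(seed)
    fov = acq.fov_mm
    if fov is None:
        fov = float(max(np.asarray(phantom.shape) * phantom.spacing))
    nx = ny = max(int(round(fov / acq.in_plane_mm)), 2)
    nz = max(int(round(fov / acq.slice_spacing_mm)), 2)
    D = np.eye(3) if directions is None else np.asarray(directions, float)
    center = phantom.center_world()
    affine = centered_affine((nx, ny, nz),
                             (acq.in_plane_mm, acq.in_plane_mm,
                              acq.slice_spacing_mm), D, center)
    out = ImageVolume(np.zeros((nx, ny, nz)), affine)
    normal = D[:, 2]
    offsets, weights = _psf_taps(acq)

    # per-slice jitter transforms (drawn in slice order, even when zero,
    # so that turning jitter on/off does not reshuffle the noise stream)
    jitters = []
    for _ in range(nz):
        rot = rng.uniform(-1, 1, size=3) * acq.jitter_rot_deg
        tra = rng.uniform(-1, 1, size=3) * acq.jitter_trans_mm
        if acq.jitter_rot_deg == 0 and acq.jitter_trans_mm == 0:
            jitters.append(pose)
        else:
            J = RigidTransform.from_params(
                np.concatenate([np.deg2rad(rot), tra]), center=center)
            jitters.append(J.compose(pose))

    data = np.zeros((nx, ny, nz))
    ijk = np.indices((nx, ny, 1), dtype=float).reshape(3, -1).T
    for k in range(nz):
        ijk[:, 2] = k
        pts = out.voxel_to_world(ijk)                    # (nx*ny, 3)
        inv = jitters[k].inverse()
        tap_pts = (pts[None, :, :] + offsets[:, None, None] * normal)
        vals = phantom.sample_world(inv.apply(tap_pts.reshape(-1, 3)),
                                    order=1)
        vals = vals.reshape(len(offsets), -1)
        data[:, :, k] = (weights @ vals).reshape(nx, ny)

    if acq.bias_field_amplitude > 0:
        u = [np.linspace(-1, 1, s) for s in (nx, ny, nz)]
        U = np.meshgrid(*u, indexing="ij")
        basis = [U[0], U[1], U[2], U[0] * U[1], U[0] * U[2], U[1] * U[2],
                 U[0] ** 2, U[1] ** 2, U[2] ** 2]
        coeff = rng.normal(size=len(basis))
        fieldv = sum(c * b for c, b in zip(coeff, basis))
        fieldv = fieldv / max(np.abs(fieldv).max(), 1e-12)
        data *= np.clip(1.0 + acq.bias_field_amplitude * fieldv, 0.1, None)

    if acq.noise_sigma > 0:
        data += rng.normal(0.0, acq.noise_sigma, size=data.shape)

    stack = Stack(data, affine,
                  slice_thickness_mm=acq.slice_thickness_mm,
                  slice_spacing_mm=acq.slice_spacing_mm,
                  package_index=_package_assignment(nz, acq),
                  name=name, true_pose=pose)

    if labels is not None:
        glob_map, organ_map = labels
        for attr, lm in (("truth_global", glob_map), ("truth_organs", organ_map)):
            lab = np.zeros((nx, ny, nz), dtype=lm.data.dtype)
            for k in range(nz):
                ijk[:, 2] = k
                pts = out.voxel_to_world(ijk)
                q = jitters[k].inverse().apply(pts)
                lab[:, :, k] = lm.sample_world(q, order=0).reshape(nx, ny)
            setattr(stack, attr,
                    LabelMap(lab.astype(lm.data.dtype), affine,
                             labels=dict(lm.labels)))
    return stack


def split_packages(stack: Stack) -> list[Stack]:
    """Split a stack into quasi-static per-package sub-stacks.

    Each output stack keeps only the slices of one package; its affine is
    rebuilt from the actual slice positions so world geometry is unchanged.
    A single-package stack is returned as a singleton list, unchanged.
    """
    packages = np.unique(stack.package_index)
    if len(packages) == 1:
        return [stack]
    out = []
    for p in packages:
        idx = np.flatnonzero(stack.package_index == p)
        strides = np.diff(idx)
        if strides.size and np.ptp(strides) != 0:
            raise ValueError(f"package {p} has non-uniform slice stride")
        stride = int(strides[0]) if strides.size else 1
        A = stack.affine.copy()
        A[:3, 3] = A[:3, 3] + A[:3, 2] * idx[0]
        A[:3, 2] = A[:3, 2] * stride
        sub = Stack(stack.data[:, :, idx], A,
                    slice_thickness_mm=stack.slice_thickness_mm,
                    slice_spacing_mm=stack.slice_spacing_mm * stride,
                    package_index=np.zeros(len(idx), dtype=int),
                    name=f"{stack.name}_pkg{int(p)}",
                    true_pose=stack.true_pose)
        if stack.truth_global is not None:
            sub.truth_global = LabelMap(stack.truth_global.data[:, :, idx], A,
                                        labels=dict(stack.truth_global.labels))
        if stack.truth_organs is not None:
            sub.truth_organs = LabelMap(stack.truth_organs.data[:, :, idx], A,
                                        labels=dict(stack.truth_organs.labels))
        out.append(sub)
    return out
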