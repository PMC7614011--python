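"""Step II — landmark-guided pose estimation.

The fetal trunk pose is estimated from four anatomical fiducials — the
centroids of the thorax, abdomen, heart and liver masks — registered to
the corresponding reference landmarks of a trunk atlas by classical
least-squares rigid point registration (centroid alignment plus SVD
rotation with reflection correction, no scaling).  The resulting world
transform is applied directly to the stack's affine: a pure header
reorientation that never resamples voxel data.

Because the heart and liver labels may overlap the thorax and abdomen
labels (two separate segmentation networks in the clinical setting), the
heart/liver voxels are subtracted from the thorax/abdomen masks *before*
centroid computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import FetalReconError, LabelMap, RigidTransform, Stack

LANDMARK_NAMES = ("thorax", "abdomen", "heart", "liver")


class LandmarkMissingError(FetalReconError):
    """A required organ label is empty; the stack cannot be pose-estimated."""


class DegenerateConfigurationError(FetalReconError):
    """Landmarks are (near-)collinear; rotation is not identifiable."""


def _check_points(points: np.ndarray, what: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError(f"{what} must be 4 points in 3D, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{what} contains non-finite coordinates")
    return pts


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered (thorax, abdomen, heart, liver) world-mm points."""

    points: np.ndarray
    provenance: str = "oracle"  # oracle | segmented

    def __post_init__(self):
        object.__setattr__(self, "points",
                           _check_points(self.points, "LandmarkSet"))

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(T.apply(self.points), provenance=self.provenance)


@dataclass(frozen=True)
class AtlasReference:
    """The four reference landmarks in standard radiological space."""

    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "points",
                           _check_points(self.points, "AtlasReference"))

    @staticmethod
    def from_organ_labels(organ_labels: LabelMap) -> "AtlasReference":
        """Atlas built from an (untransformed) reference organ label map."""
        return AtlasReference(extract_landmarks(organ_labels).points)

    def save(self, path: str) -> None:
        payload = {name: list(map(float, p))
                   for name, p in zip(LANDMARK_NAMES, self.points)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def load(path: str) -> "AtlasReference":
        with open(path) as fh:
            payload = json.load(fh)
        return AtlasReference(np.array([payload[n] for n in LANDMARK_NAMES]))


def extract_landmarks(organ_labels: LabelMap,
                      provenance: str = "oracle") -> LandmarkSet:
    """Organ-centroid landmarks (world mm) from a thorax/abdomen/heart/liver map.

    Heart voxels are removed from the thorax mask and liver voxels from the
    abdomen mask before the (unweighted, voxel-centre) centroids are taken.
    An empty label raises :class:`LandmarkMissingError` — never a silent
    3-point registration.
    """
    masks = {}
    for name in LANDMARK_NAMES:
        if name not in organ_labels.labels:
            raise KeyError(f"organ label map lacks {name!r}")
        masks[name] = organ_labels.mask(name)
    masks["thorax"] = masks["thorax"] & ~masks["heart"]
    masks["abdomen"] = masks["abdomen"] & ~masks["liver"]
    points = []
    for name in LANDMARK_NAMES:
        ijk = np.argwhere(masks[name])
        if ijk.size == 0:
            raise LandmarkMissingError(f"organ label {name!r} is empty")
        points.append(organ_labels.voxel_to_world(ijk.mean(axis=0)))
    return LandmarkSet(np.array(points), provenance=provenance)


def point_register(source, target) -> RigidTransform:
    """Least-squares rigid transform taking ``source`` points onto ``target``.

    Classical closed-form solution: centre both sets, take the SVD of the
    cross-covariance and correct a possible reflection so the rotation is
    proper; the translation aligns the centroids.  Minimises
    ``Σ ‖R sᵢ + t − tᵢ‖²`` with no scaling.
    """
    s = np.asarray(source.points if isinstance(source, LandmarkSet) else source,
                   dtype=float)
    t = np.asarray(target.points if isinstance(target, LandmarkSet) else target,
                   dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise DegenerateConfigurationError(
            "source landmarks are collinear within tolerance")
    H = s0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, tc - R @ sc)


def reorient_to_atlas(stack: Stack, landmarks: LandmarkSet,
                      atlas: AtlasReference) -> tuple[Stack, RigidTransform]:
    """Reorient a stack into atlas space by a header-only affine update.

    Returns the reoriented stack (same voxel bytes, affine premultiplied by
    the estimated pose) and the pose transform itself.
    """
    T = point_register(landmarks, atlas.points)
    return stack.with_affine(T.matrix @ stack.affine), T
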