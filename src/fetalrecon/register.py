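"""Classical intensity-based rigid registration (masked NCC, gradient descent).

A multiresolution regular-step gradient descent over the 6 rigid
parameters (axis-angle rotation about the fixed-mask centroid plus
translation), maximising normalised cross-correlation sampled at the
fixed-mask voxel centres.  Rotation parameters are scaled so that one
radian is commensurate with the region radius in mm, the standard trick
that balances the step size between rotations and translations.

This is a *local* optimiser: it converges within a limited capture range
(tens of degrees) and is used both for pairwise stack refinement and as
the classical baseline whose capture range the landmark-based pose
estimation extends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import FetalReconError, ImageVolume, RigidTransform


class RegistrationError(FetalReconError):
    pass


@dataclass(frozen=True)
class RegistrationConfig:
    """Multiresolution NCC registration settings."""

    levels: tuple[int, ...] = (4, 2, 1)
    max_iterations: tuple[int, ...] = (60, 40, 25)
    initial_step_mm: float = 8.0
    min_step_mm: float = 0.02
    gradient_eps_mm: float = 0.1
    max_points_per_level: int = 4000

    def __post_init__(self):
        if len(self.levels) < 1:
            raise ValueError("at least one pyramid level required")
        if len(self.max_iterations) != len(self.levels):
            raise ValueError("max_iterations must match levels")
        if self.min_step_mm <= 0 or self.initial_step_mm <= 0:
            raise ValueError("step sizes must be positive")


def _ncc_vectors(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def _smoothed(vol: ImageVolume, factor: int) -> ImageVolume:
    if factor <= 1:
        return vol
    return ImageVolume(gaussian_filter(vol.data.astype(float), factor / 2.0),
                       vol.affine)


def _mask_points(fixed: ImageVolume, region: np.ndarray | None,
                 stride: int, cap: int) -> np.ndarray:
    if region is not None:
        binary = np.asarray(region) > 0
    else:
        binary = fixed.data != 0
    sl = (slice(None, None, stride),) * 3
    sub = np.zeros_like(binary)
    sub[sl] = binary[sl]
    ijk = np.argwhere(sub)
    if len(ijk) == 0:
        ijk = np.argwhere(binary)
    if len(ijk) > cap:
        pick = np.linspace(0, len(ijk) - 1, cap).astype(int)
        ijk = ijk[pick]
    return fixed.voxel_to_world(ijk.astype(float))


def rigid_register(moving: ImageVolume, fixed: ImageVolume,
                   init: RigidTransform | None = None,
                   cfg: RegistrationConfig = RegistrationConfig(),
                   region: np.ndarray | None = None,
                   ) -> tuple[RigidTransform, float]:
    """Find the rigid ``T`` (moving world -> fixed world) maximising masked NCC.

    ``region`` is a boolean mask on the fixed grid (default: nonzero fixed
    voxels).  Returns the transform and the final NCC.  Deterministic given
    its inputs; raises on empty initial overlap or non-finite similarity.
    """
    init = RigidTransform.identity() if init is None else init
    if region is not None and np.asarray(region).shape != fixed.shape:
        raise RegistrationError("region mask is not on the fixed grid")

    center = None
    pts_full = _mask_points(fixed, region, 1, 10 ** 9)
    if len(pts_full) < 2:
        raise RegistrationError("empty fixed region")
    center = pts_full.mean(axis=0)
    radius = float(np.linalg.norm(pts_full - center, axis=1).mean())
    radius = max(radius, 1.0)
    scale = np.array([radius] * 3 + [1.0] * 3)  # mm-equivalent parameters

    # initial overlap check at full resolution
    m0 = moving.sample_world(init.inverse().apply(pts_full[::4]))
    if np.count_nonzero(m0) < 2:
        raise RegistrationError("no overlap between moving and fixed at init")

    q = np.zeros(6)
    final_sim = np.nan
    for factor, max_iter in zip(cfg.levels, cfg.max_iterations):
        fx = _smoothed(fixed, factor)
        mv = _smoothed(moving, factor)
        pts = _mask_points(fx, region, max(factor, 1),
                           cfg.max_points_per_level)
        fvals = fx.sample_world(pts)

        def cost(qv):
            T = RigidTransform.from_params(qv / scale, center=center)
            total = T.compose(init)
            mvals = mv.sample_world(total.inverse().apply(pts))
            return -_ncc_vectors(fvals, mvals)

        step = cfg.initial_step_mm
        best = cost(q)
        if not np.isfinite(best):
            raise RegistrationError("non-finite similarity at initialisation")
        eps = cfg.gradient_eps_mm
        for _ in range(max_iter):
            g = np.zeros(6)
            for j in range(6):
                dq = np.zeros(6)
                dq[j] = eps
                g[j] = (cost(q + dq) - cost(q - dq)) / (2 * eps)
            ng = np.linalg.norm(g)
            if ng < 1e-12:
                break
            cand = q - step * g / ng
            c2 = cost(cand)
            if np.isfinite(c2) and c2 < best - 1e-12:
                q, best = cand, c2
            else:
                step *= 0.5
            if step < cfg.min_step_mm:
                break
        final_sim = -best

    if not np.isfinite(final_sim):
        raise RegistrationError("non-finite final similarity")
    T = RigidTransform.from_params(q / scale, center=center).compose(init)
    return T, float(final_sim)
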