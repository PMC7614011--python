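"""Step III — stack quality metrics, outlier rejection and template generation.

Per-stack metrics (all normalised cross-correlations are Pearson
correlations over the non-zero overlapping region):

* ``Ccor`` — within-stack motion corruption: the mean 2D NCC between each
  pair of sequential slices.
* ``Csim`` — mutual stack similarity: the mean 3D NCC of a stack against
  every stack (the self term included, contributing 1; this shifts every
  stack equally and cannot change any ordering or decision).
* ``Cvol`` — relative deviation of the thorax-mask volume from the median
  mask volume.

Inclusion requires, with strict inequalities,
``Ccor > 0.5·max Ccor``, ``Csim > 0.5·max Csim`` and ``Cvol < 0.40``
(thresholds configurable).  The reference stack is the included stack
maximising ``Ccor·Csim``; the template is the voxelwise median of the
included reoriented stacks and the thorax mask their majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (FetalReconError, GridMismatchError, ImageVolume, LabelMap,
                   RigidTransform, Stack)
from .register import RegistrationConfig, rigid_register


class NoUsableStacksError(FetalReconError):
    """Every stack failed the inclusion criteria."""


# --------------------------------------------------------------------------
# Normalised cross-correlation
# --------------------------------------------------------------------------

def ncc(a, b, region: np.ndarray | None = None) -> float:
    """Pearson correlation of two same-grid images over a region.

    The region defaults to the voxels where both images are nonzero.  By
    convention the result is 0 when the region holds fewer than two voxels
    or either side has zero variance — blank content counts as maximally
    dissimilar rather than undefined.
    """
    av = a.data if isinstance(a, ImageVolume) else np.asarray(a)
    bv = b.data if isinstance(b, ImageVolume) else np.asarray(b)
    if av.shape != bv.shape:
        raise GridMismatchError(
            f"ncc requires a common grid: {av.shape} vs {bv.shape}")
    if isinstance(a, ImageVolume) and isinstance(b, ImageVolume):
        if not np.allclose(a.affine, b.affine, atol=1e-6):
            raise GridMismatchError("ncc requires a common grid (affines differ)")
    if region is None:
        region = (av != 0) & (bv != 0)
    else:
        region = np.asarray(region) > 0
        if region.shape != av.shape:
            raise GridMismatchError("region mask shape mismatch")
        region = region & (av != 0) & (bv != 0)
    x = av[region].astype(float)
    y = bv[region].astype(float)
    if x.size < 2:
        return 0.0
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(x @ y / (nx * ny))


def motion_score(stack) -> float:
    """``Ccor``: mean sequential-slice 2D NCC (slice axis = last index axis)."""
    data = stack.data if isinstance(stack, ImageVolume) else np.asarray(stack)
    n = data.shape[2]
    if n < 2:
        raise ValueError("motion_score requires at least 2 slices")
    vals = [ncc(data[:, :, j], data[:, :, j + 1]) for j in range(n - 1)]
    return float(np.mean(vals))


def similarity_score(i: int, volumes: list, region: np.ndarray | None = None
                     ) -> float:
    """``Csim``: mean 3D NCC of stack ``i`` against every stack, self included."""
    if len(volumes) == 0:
        raise ValueError("no stacks")
    return float(np.mean([ncc(volumes[i], v, region=region) for v in volumes]))


def volume_deviation(mask_volumes_mm3) -> list[float]:
    """``Cvol``: per-stack relative deviation from the median mask volume."""
    v = np.asarray(mask_volumes_mm3, dtype=float)
    if v.size < 1:
        raise ValueError("at least one volume required")
    med = float(np.median(v))
    if med == 0.0:
        raise ValueError("median mask volume is zero")
    return list(np.abs(v - med) / med)


# --------------------------------------------------------------------------
# Inclusion and reference selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StackMetrics:
    name: str
    ccor: float
    csim: float
    cvol: float
    v_thorax_mm3: float = 0.0
    included: bool = False
    reason: str = ""

    @property
    def product(self) -> float:
        return self.ccor * self.csim


def apply_inclusion(metrics: list[StackMetrics],
                    ccor_frac: float = 0.5, csim_frac: float = 0.5,
                    cvol_max: float = 0.40) -> list[StackMetrics]:
    """Flag each stack using the three strict inclusion inequalities."""
    if not metrics:
        raise ValueError("no metrics")
    ccor_thr = ccor_frac * max(m.ccor for m in metrics)
    csim_thr = csim_frac * max(m.csim for m in metrics)
    out = []
    for m in metrics:
        reasons = []
        if not m.ccor > ccor_thr:
            reasons.append(f"motion_corrupted(Ccor={m.ccor:.3f}<= {ccor_thr:.3f})")
        if not m.csim > csim_thr:
            reasons.append(f"dissimilar(Csim={m.csim:.3f}<={csim_thr:.3f})")
        if not m.cvol < cvol_max:
            reasons.append(f"volume_outlier(Cvol={m.cvol:.3f}>={cvol_max:.2f})")
        out.append(replace(m, included=not reasons, reason=";".join(reasons)))
    if not any(m.included for m in out):
        detail = "; ".join(
            f"{m.name}: Ccor={m.ccor:.3f} Csim={m.csim:.3f} Cvol={m.cvol:.3f}"
            for m in out)
        raise NoUsableStacksError(f"all stacks excluded ({detail})")
    return out


def select_reference(metrics: list[StackMetrics]) -> int:
    """Index of the included stack with the highest ``Ccor·Csim``.

    Ties break to the lowest index, deterministically.
    """
    best, best_val = None, -np.inf
    for i, m in enumerate(metrics):
        if m.included and m.product > best_val:
            best, best_val = i, m.product
    if best is None:
        raise NoUsableStacksError("no included stacks")
    return best


def metrics_csv(metrics: list[StackMetrics], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("stack_id,Ccor,Csim,Cvol,product,included,reason\n")
        for m in metrics:
            fh.write(f"{m.name},{m.ccor:.6f},{m.csim:.6f},{m.cvol:.6f},"
                     f"{m.product:.6f},{int(m.included)},{m.reason}\n")


# --------------------------------------------------------------------------
# Common grid, metric orchestration, refinement and template
# --------------------------------------------------------------------------

def common_grid(stacks: list[Stack], transforms: list[RigidTransform],
                masks: list[np.ndarray] | None = None,
                spacing: float | None = None,
                margin_mm: float = 5.0) -> tuple[np.ndarray, tuple]:
    """Isotropic grid in atlas axes covering every transformed stack ROI.

    Spacing defaults to the finest in-plane spacing among the stacks.
    """
    if spacing is None:
        spacing = min(float(min(s.spacing[0], s.spacing[1])) for s in stacks)
    corners = []
    for k, (s, T) in enumerate(zip(stacks, transforms)):
        if masks is not None and masks[k] is not None and np.any(masks[k]):
            ijk = np.argwhere(np.asarray(masks[k]) > 0)
            lo, hi = ijk.min(axis=0), ijk.max(axis=0)
        else:
            lo = np.zeros(3)
            hi = np.asarray(s.shape) - 1
        box = np.array([[a, b] for a, b in zip(lo, hi)], dtype=float)
        pts = np.array([[box[0, i], box[1, j], box[2, k2]]
                        for i in (0, 1) for j in (0, 1) for k2 in (0, 1)])
        corners.append(T.apply(s.voxel_to_world(pts)))
    corners = np.concatenate(corners)
    lo = corners.min(axis=0) - margin_mm
    hi = corners.max(axis=0) + margin_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    A = np.eye(4)
    A[:3, :3] = np.diag([spacing] * 3)
    A[:3, 3] = lo
    return A, tuple(int(v) for v in shape)


def _resample_all(stacks, transforms, affine, shape, order=1):
    return [s.resample_to(affine, shape, order=order, transform=T)
            for s, T in zip(stacks, transforms)]


def compute_metrics(stacks: list[Stack], transforms: list[RigidTransform],
                    masks: list[np.ndarray],
                    spacing: float | None = None) -> list[StackMetrics]:
    """Compute Ccor, Csim and Cvol for every stack.

    ``Ccor`` is evaluated on each stack's own (cropped) grid; ``Csim`` on a
    common isotropic grid after applying the stack transforms, inside the
    union of the transformed thorax masks; ``Cvol`` from the thorax-mask
    volumes in mm³ (an empty mask gives volume 0 and is excluded through
    the volume criterion rather than crashing).
    """
    A, shape = common_grid(stacks, transforms, masks, spacing=spacing)
    vols = _resample_all(stacks, transforms, A, shape)
    region = np.zeros(shape, dtype=bool)
    for s, T, m in zip(stacks, transforms, masks):
        if m is None or not np.any(m):
            continue
        lm = ImageVolume(np.asarray(m, dtype=float), s.affine)
        region |= lm.resample_to(A, shape, order=0, transform=T).data > 0.5
    if not region.any():
        region = None

    out = []
    for i, s in enumerate(stacks):
        ccor = motion_score(s)
        csim = similarity_score(i, vols, region=region)
        vol_mm3 = (float(np.count_nonzero(masks[i])) * s.voxel_volume_mm3
                   if masks[i] is not None else 0.0)
        out.append(StackMetrics(name=s.name, ccor=ccor, csim=csim,
                                cvol=np.nan, v_thorax_mm3=vol_mm3))
    cvols = volume_deviation([m.v_thorax_mm3 for m in out])
    return [replace(m, cvol=c) for m, c in zip(out, cvols)]


def refine_pairwise(stacks: list[Stack], init: list[RigidTransform],
                    masks: list[np.ndarray],
                    cfg: RegistrationConfig = RegistrationConfig(),
                    reference_index: int | None = None,
                    ) -> tuple[list[RigidTransform], list[str]]:
    """Refine landmark-based stack transforms by intensity registration.

    All stacks are registered towards a provisional reference frame (the
    least motion-corrupted stack by default, resampled to an isotropic grid
    under its landmark transform).  A stack whose registration diverges —
    final similarity below its similarity at initialisation — keeps its
    landmark-only transform, and the event is logged.
    """
    if reference_index is None:
        scores = [motion_score(s) for s in stacks]
        reference_index = int(np.argmax(scores))
    A, shape = common_grid([stacks[reference_index]],
                           [init[reference_index]],
                           [masks[reference_index]])
    fixed = stacks[reference_index].resample_to(
        A, shape, transform=init[reference_index])
    region = None
    if masks[reference_index] is not None and np.any(masks[reference_index]):
        lm = ImageVolume(np.asarray(masks[reference_index], float),
                         stacks[reference_index].affine)
        region = lm.resample_to(A, shape, order=0,
                                transform=init[reference_index]).data > 0.5

    refined, log = [], []
    for i, s in enumerate(stacks):
        if i == reference_index:
            refined.append(init[i])
            continue
        init_sim = ncc(s.resample_to(A, shape, transform=init[i]), fixed,
                       region=region)
        try:
            T, sim = rigid_register(s, fixed, init=init[i], cfg=cfg,
                                    region=region)
        except FetalReconError as exc:
            log.append(f"{s.name}: registration failed ({exc}); "
                       "keeping landmark transform")
            refined.append(init[i])
            continue
        if not np.isfinite(sim) or sim < init_sim:
            log.append(f"{s.name}: registration diverged "
                       f"(NCC {sim:.3f} < init {init_sim:.3f}); "
                       "keeping landmark transform")
            refined.append(init[i])
        else:
            refined.append(T)
    return refined, log


def build_template(stacks: list[Stack], transforms: list[RigidTransform],
                   masks: list[np.ndarray], spacing: float | None = None,
                   ) -> tuple[ImageVolume, LabelMap]:
    """Median template and majority-vote thorax mask in atlas orientation.

    Each included stack is resampled (linear) to an isotropic grid; the
    template voxel is the median over the stacks that actually cover it,
    which is robust to a single artifactual stack value.  The mask is the
    voxelwise mean of the resampled binary masks thresholded at 0.5 — the
    median of binary values.
    """
    if len(stacks) == 0:
        raise ValueError("no stacks for template")
    A, shape = common_grid(stacks, transforms, masks, spacing=spacing)
    samples = np.full((len(stacks),) + shape, np.nan)
    for k, (s, T) in enumerate(zip(stacks, transforms)):
        vol = s.resample_to(A, shape, order=1, transform=T)
        cov = ImageVolume(np.ones(s.shape), s.affine).resample_to(
            A, shape, order=1, transform=T).data > 0.5
        arr = vol.data.copy()
        arr[~cov] = np.nan
        samples[k] = arr
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        template = np.nanmedian(samples, axis=0)   # uncovered voxels -> NaN
    template[np.isnan(template)] = 0.0

    mask_mean = np.zeros(shape)
    n_masks = 0
    for s, T, m in zip(stacks, transforms, masks):
        if m is None:
            continue
        lm = ImageVolume(np.asarray(m, dtype=float), s.affine)
        mask_mean += lm.resample_to(A, shape, order=1, transform=T).data
        n_masks += 1
    mask = (mask_mean / max(n_masks, 1)) >= 0.5
    return (ImageVolume(template, A),
            LabelMap(mask.astype(np.int16), A, labels={"background": 0,
                                                       "thorax": 1}))
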