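"""Step I — global localisation of the fetal trunk.

Produces the 4-class global label map (background / uterus / brain /
trunk), keeps the largest connected trunk component and crops stacks to
the trunk region of interest.

Two segmentation backends share one configuration type: the *oracle*
backend returns ground-truth labels carried alongside simulated stacks
(the deterministic, CNN-free path used throughout testing), and a *cnn*
backend slot describing the 3D UNet that would perform the same mapping
on clinical data (5 encoder/decoder levels of 32/64/128/256/512 channels,
instance normalisation, LeakyReLU, average pooling for the first two
down-samplings then max pooling, generalised Dice loss, Adam at lr 0.002,
batch 2, 128³ input grid).  Selecting the cnn backend without trained
weights raises an explicit error rather than returning silent garbage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
from scipy import ndimage

from .core import (FetalReconError, GridMismatchError, ImageVolume, LabelMap,
                   Stack)


class UntrainedBackendError(FetalReconError):
    """CNN backend selected without trained weights."""


class TrunkAbsentError(FetalReconError):
    """No trunk voxels found — the stack must be excluded upstream."""


@dataclass(frozen=True)
class SegmenterBackend:
    """Configuration for the segmentation step (oracle or 3D UNet)."""

    mode: str = "oracle"  # oracle | cnn
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    normalisation: str = "instance"
    activation: str = "leaky_relu"
    pooling: tuple[str, ...] = ("avg", "avg", "max", "max")
    loss: str = "generalised_dice"
    optimiser: str = "adam"
    learning_rate: float = 0.002
    batch_size: int = 2
    input_grid: int = 128
    weights: str | None = None

    def __post_init__(self):
        if self.mode not in ("oracle", "cnn"):
            raise ValueError(f"unknown backend mode {self.mode!r}")


def resample_to_grid(vol: ImageVolume, grid: int, order: int = 1) -> ImageVolume:
    """Resample a volume to an isotropic ``grid³`` cube.

    The aspect ratio is preserved by symmetric zero-padding to the largest
    world extent before scaling — never by anisotropic stretch — and the
    affine is updated so world geometry is unchanged.
    """
    if grid < 8:
        raise ValueError("grid must be >= 8")
    shape = np.asarray(vol.shape, dtype=int)
    spacing = vol.spacing
    extents = shape * spacing
    E = extents.max()
    pad_total = np.round((E - extents) / spacing).astype(int)
    pad_lo = pad_total // 2
    padded = shape + pad_total
    s = padded / float(grid)
    # output index -> input index (block-centre convention)
    offset = -pad_lo + (s - 1.0) / 2.0
    out_idx = np.indices((grid, grid, grid), dtype=float)
    coords = out_idx * s[:, None, None, None] + offset[:, None, None, None]
    vals = ndimage.map_coordinates(vol.data.astype(float, copy=False), coords,
                                   order=order, mode="constant", cval=0.0)
    A = vol.affine.copy()
    A[:3, :3] = vol.affine[:3, :3] @ np.diag(s)
    A[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ offset
    if order == 0 and np.issubdtype(vol.data.dtype, np.integer):
        vals = np.rint(vals).astype(vol.data.dtype)
    if isinstance(vol, LabelMap):
        return LabelMap(vals, A, labels=dict(vol.labels))
    return ImageVolume(vals, A)


def segment_global(stack: Stack, backend: SegmenterBackend,
                   truth: LabelMap | None = None) -> LabelMap:
    """Global 4-class segmentation of one stack.

    Oracle mode returns the ground-truth map carried with the stack (or
    passed explicitly); absent organs simply yield empty labels, e.g. a
    brain-only stack has an empty trunk label and is flagged downstream
    rather than crashing the pipeline.
    """
    if backend.mode == "cnn":
        if backend.weights is None:
            raise UntrainedBackendError(
                "cnn backend selected without trained weights; train a 3D "
                "UNet with this configuration or use the oracle backend")
        raise FetalReconError(
            "cnn inference requires a PyTorch runtime; only the oracle "
            "backend is available in this installation")
    lm = truth if truth is not None else stack.truth_global
    if lm is None:
        raise FetalReconError(
            "oracle backend requires ground-truth labels alongside the stack")
    if lm.shape != stack.shape:
        raise GridMismatchError("labels are not on the stack grid")
    return lm


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def largest_component(mask: LabelMap | np.ndarray):
    """Keep only the largest 26-connected component of a binary mask.

    Empty input yields an empty output.  Ties are broken deterministically
    in favour of the component with the lexicographically smallest
    bounding-box origin.
    """
    if isinstance(mask, LabelMap):
        binary = mask.data > 0
    else:
        binary = np.asarray(mask) > 0
    labelled, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        out = np.zeros_like(binary)
    else:
        sizes = np.bincount(labelled.ravel())[1:]
        best = sizes.max()
        candidates = np.flatnonzero(sizes == best) + 1
        if len(candidates) == 1:
            keep = candidates[0]
        else:
            objects = ndimage.find_objects(labelled)
            origins = [tuple(sl.start for sl in objects[c - 1])
                       for c in candidates]
            keep = candidates[min(range(len(candidates)),
                                  key=lambda i: origins[i])]
        out = labelled == keep
    if isinstance(mask, LabelMap):
        return LabelMap(out.astype(mask.data.dtype), mask.affine,
                        labels=dict(mask.labels))
    return out


def crop_to_roi(stack: Stack, mask, margin_mm: float = 15.0) -> Stack:
    """Crop a stack to the bounding box of ``mask`` dilated by ``margin_mm``.

    The mask must live on the stack grid; the crop is a pure sub-grid
    extraction (affine translated, world geometry preserved).  Ground-truth
    attachments and package indices are cropped consistently.
    """
    binary = mask.data > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    if binary.shape != stack.shape:
        raise GridMismatchError("mask is not on the stack grid")
    if not binary.any():
        raise TrunkAbsentError("empty mask: trunk absent from stack coverage")
    ijk = np.argwhere(binary)
    lo = ijk.min(axis=0)
    hi = ijk.max(axis=0) + 1
    margin_vox = np.array([math.ceil(margin_mm / s) for s in stack.spacing])
    lo = np.maximum(lo - margin_vox, 0)
    hi = np.minimum(hi + margin_vox, np.asarray(stack.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    A = stack.affine.copy()
    A[:3, 3] = stack.affine[:3, 3] + stack.affine[:3, :3] @ lo.astype(float)
    out = Stack(stack.data[sl], A,
                slice_thickness_mm=stack.slice_thickness_mm,
                slice_spacing_mm=stack.slice_spacing_mm,
                package_index=stack.package_index[sl[2]],
                name=stack.name, true_pose=stack.true_pose)
    for attr in ("truth_global", "truth_organs"):
        lm = getattr(stack, attr)
        if lm is not None:
            setattr(out, attr, LabelMap(lm.data[sl], A, labels=dict(lm.labels)))
    return out
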