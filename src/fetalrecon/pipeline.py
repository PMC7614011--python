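"""End-to-end orchestration of Steps I–IV with reporting and logging.

``run_pipeline`` takes raw stacks (in-memory :class:`~fetalrecon.core.Stack`
objects or NIfTI paths), localises and crops the fetal trunk, estimates
each stack's pose from organ-centroid landmarks, refines the alignments,
rejects outlier stacks, builds the median template and reconstructs the
high-resolution volume.  Every dropped stack or slice is reported with a
machine-readable reason, and a run with the oracle backend is fully
deterministic given its inputs and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core import FetalReconError, ImageVolume, LabelMap, RigidTransform, Stack
from .localise import (SegmenterBackend, TrunkAbsentError, crop_to_roi,
                       largest_component, segment_global)
from .phantom import split_packages
from .pose import (AtlasReference, LandmarkMissingError, extract_landmarks,
                   reorient_to_atlas)
from .reconstruct import ReconConfig, SliceWeightReport, svr_reconstruct
from .register import RegistrationConfig
from .stackselect import (StackMetrics, apply_inclusion, build_template,
                          compute_metrics, metrics_csv, refine_pairwise,
                          select_reference)


@dataclass
class PipelineConfig:
    backend: SegmenterBackend = field(default_factory=SegmenterBackend)
    atlas: AtlasReference | None = None
    crop_margin_mm: float = 15.0
    ccor_frac: float = 0.5
    csim_frac: float = 0.5
    cvol_max: float = 0.40
    split_packages: bool = True
    min_stacks: int = 6
    recon: ReconConfig = field(default_factory=ReconConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.min_stacks < 1:
            raise ValueError("min_stacks must be >= 1")
        for thr in (self.ccor_frac, self.csim_frac):
            if not 0.0 <= thr <= 1.0:
                raise ValueError("Ccor/Csim fractions must be in [0, 1]")
        if self.cvol_max <= 0:
            raise ValueError("Cvol threshold must be positive")


@dataclass
class ReconstructionBundle:
    volume: ImageVolume | None
    template: ImageVolume | None
    mask: LabelMap | None
    report: SliceWeightReport | None
    metrics: list[StackMetrics]
    transforms: dict[str, RigidTransform]
    reference: str | None
    dropped: list[tuple[str, str]]
    warnings: list[str]
    log: list[dict]
    pose_errors: dict[str, tuple[float, float]] = field(default_factory=dict)


def _thorax_mask(organ_labels: LabelMap) -> np.ndarray:
    return np.isin(organ_labels.data,
                   [organ_labels.labels["thorax"],
                    organ_labels.labels["heart"]])


def run_pipeline(stacks, cfg: PipelineConfig) -> ReconstructionBundle:
    """Execute localise → pose → select → reconstruct on a set of stacks."""
    log: list[dict] = []
    warnings: list[str] = []
    dropped: list[tuple[str, str]] = []

    def emit(event: str, **kw):
        log.append({"event": event, **kw})

    loaded: list[Stack] = []
    for s in stacks:
        if isinstance(s, Stack):
            loaded.append(s)
            continue
        try:
            loaded.append(Stack.load(s))
        except Exception as exc:  # unreadable file: per-file error with path
            raise FetalReconError(f"cannot read stack {s!r}: {exc}") from exc
    if not loaded:
        raise FetalReconError("no readable stacks provided")
    if len(loaded) < cfg.min_stacks:
        msg = (f"{len(loaded)} stacks provided, below recommended minimum "
               f"of {cfg.min_stacks}")
        warnings.append(msg)
        emit("warning", message=msg)

    # optional package splitting for interleaved acquisitions
    units: list[Stack] = []
    for st in loaded:
        if cfg.split_packages and len(np.unique(st.package_index)) > 1:
            pkgs = split_packages(st)
            emit("split_packages", stack=st.name, n_packages=len(pkgs))
            units.extend(pkgs)
        else:
            units.append(st)

    # ---- Step I: global localisation and trunk cropping ------------------
    cropped: list[Stack] = []
    for st in units:
        try:
            glob_lm = segment_global(st, cfg.backend)
            trunk = largest_component(LabelMap(
                (glob_lm.data == glob_lm.labels["trunk"]).astype(np.int16),
                glob_lm.affine, labels={"background": 0, "trunk": 1}))
            roi = crop_to_roi(st, trunk, margin_mm=cfg.crop_margin_mm)
        except TrunkAbsentError:
            dropped.append((st.name, "trunk_absent"))
            emit("drop", stack=st.name, reason="trunk_absent")
            continue
        cropped.append(roi)
        emit("localised", stack=st.name, shape=list(roi.shape))
    if not cropped:
        raise FetalReconError("no usable stacks: trunk absent everywhere")

    # ---- Step II: landmark pose estimation -------------------------------
    if cfg.atlas is None:
        raise FetalReconError("pipeline requires an atlas reference")
    posed: list[Stack] = []
    transforms: list[RigidTransform] = []
    landmark_sets = []
    for st in cropped:
        if st.truth_organs is None:
            dropped.append((st.name, "no_organ_labels"))
            emit("drop", stack=st.name, reason="no_organ_labels")
            continue
        try:
            lms = extract_landmarks(st.truth_organs)
        except LandmarkMissingError as exc:
            dropped.append((st.name, f"landmark_missing:{exc}"))
            emit("drop", stack=st.name, reason="landmark_missing")
            continue
        _, T = reorient_to_atlas(st, lms, cfg.atlas)
        posed.append(st)
        transforms.append(T)
        landmark_sets.append(lms)
        emit("pose", stack=st.name,
             rotation_deg=T.rotation_angle_deg())
    if not posed:
        raise FetalReconError("no usable stacks after pose estimation")

    # ---- Step III: refinement, metrics, selection, template --------------
    masks = [_thorax_mask(st.truth_organs) for st in posed]
    refined, reg_log = refine_pairwise(posed, transforms, masks,
                                       cfg=cfg.registration)
    for line in reg_log:
        emit("refine_warning", message=line)
    # Re-anchor the mutually-aligned ensemble to the atlas: each stack's
    # landmark error averages out over the ensemble, so registering the
    # mean landmark positions to the atlas removes most of the common-frame
    # bias inherited from any single stack's landmarks.
    from .pose import point_register
    mean_pts = np.mean([T.apply(lms.points)
                        for T, lms in zip(refined, landmark_sets)], axis=0)
    anchor = point_register(mean_pts, cfg.atlas.points)
    refined = [anchor.compose(T) for T in refined]
    emit("reanchor", rotation_deg=anchor.rotation_angle_deg())
    metrics = compute_metrics(posed, refined, masks)
    metrics = apply_inclusion(metrics, ccor_frac=cfg.ccor_frac,
                              csim_frac=cfg.csim_frac, cvol_max=cfg.cvol_max)
    for m in metrics:
        emit("metrics", stack=m.name, ccor=m.ccor, csim=m.csim,
             cvol=m.cvol, included=m.included, reason=m.reason)
        if not m.included:
            dropped.append((m.name, f"excluded:{m.reason}"))
    ref_idx = select_reference(metrics)
    included = [i for i, m in enumerate(metrics) if m.included]
    template, mask = build_template([posed[i] for i in included],
                                    [refined[i] for i in included],
                                    [masks[i] for i in included])
    emit("template", reference=posed[ref_idx].name,
         n_included=len(included), shape=list(template.shape))

    # ---- Step IV: super-resolution reconstruction ------------------------
    volume, report = svr_reconstruct([posed[i] for i in included],
                                     [refined[i] for i in included],
                                     template, mask, cfg=cfg.recon)
    emit("reconstructed", excluded_percent=report.excluded_percent())

    pose_errors = {}
    for i, st in enumerate(posed):
        if st.true_pose is not None:
            e_deg, e_mm = refined[i].distance_to(
                st.true_pose.inverse(),
                reference_point=template.center_world())
            pose_errors[st.name] = (e_deg, e_mm)

    bundle = ReconstructionBundle(
        volume=volume, template=template, mask=mask, report=report,
        metrics=metrics,
        transforms={posed[i].name: refined[i] for i in range(len(posed))},
        reference=posed[ref_idx].name, dropped=dropped, warnings=warnings,
        log=log, pose_errors=pose_errors)
    if cfg.out_dir:
        _write_outputs(bundle, cfg.out_dir)
    return bundle


def _write_outputs(bundle: ReconstructionBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    if bundle.volume is not None:
        bundle.volume.save(os.path.join(out_dir, "reconstruction.nii.gz"))
    if bundle.template is not None:
        bundle.template.save(os.path.join(out_dir, "template.nii.gz"))
    if bundle.mask is not None:
        bundle.mask.save(os.path.join(out_dir, "mask.nii.gz"))
    metrics_csv(bundle.metrics, os.path.join(out_dir, "metrics.csv"))
    for name, T in bundle.transforms.items():
        np.savetxt(os.path.join(out_dir, f"transform_{name}.txt"), T.matrix)
    if bundle.report is not None:
        with open(os.path.join(out_dir, "slice_weights.json"), "w") as fh:
            json.dump(bundle.report.to_json(), fh, indent=2)
    with open(os.path.join(out_dir, "log.jsonl"), "w") as fh:
        for rec in bundle.log:
            fh.write(json.dumps(rec) + "\n")
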