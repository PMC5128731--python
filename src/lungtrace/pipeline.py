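"""End-to-end slice-wise lung segmentation.

Per slice: (volume-level) alignment -> chest mask -> within-chest
binarization -> diagonal-seeded contour tracing -> left/right separation if
the lungs are fused -> arc-length smoothing -> concave correction ->
rasterization.  Slices without lungs yield empty masks; the volume loop
continues past per-slice failures and records them in the slice log.

The tilt angle is estimated once per volume from a mid-thoracic slice and
applied to all slices, so inter-slice consistency is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import preprocess, refinement, separation, tracing
from .config import PipelineConfig
from .core import CTVolume, SliceLog
from .errors import (
    DegenerateContour,
    LungTraceError,
    NoForeground,
    SeparationFailed,
    StartNotFound,
)
from .refinement import SmoothingParams

__all__ = ["SliceResult", "PipelineResult", "segment_slice", "run_pipeline"]

_EIGHT = np.ones((3, 3), dtype=int)

LABEL_LEFT = 1
LABEL_RIGHT = 2


@dataclass
class SliceResult:
    """Per-slice outputs: labeled mask (0 bg, 1 image-left, 2 image-right),
    union lung mask, the pre-correction (smoothed-only) mask, the chest
    mask, the refined contours per side, and the processing log."""

    label_mask: np.ndarray
    lung_mask: np.ndarray
    pre_correction_mask: np.ndarray
    chest: np.ndarray
    contours: dict = field(default_factory=dict)
    log: SliceLog = field(default_factory=lambda: SliceLog(index=-1))


@dataclass
class PipelineResult:
    label_mask: np.ndarray  # (n_slices, rows, cols) uint8
    lung_mask: np.ndarray
    pre_correction_mask: np.ndarray
    logs: list
    alignment: object = None

    @property
    def left_mask(self) -> np.ndarray:
        return self.label_mask == LABEL_LEFT

    @property
    def right_mask(self) -> np.ndarray:
        return self.label_mask == LABEL_RIGHT


def _empty_result(shape, index, status, detail="") -> SliceResult:
    z = np.zeros(shape, dtype=np.uint8)
    return SliceResult(
        label_mask=z,
        lung_mask=z.astype(bool),
        pre_correction_mask=z.astype(bool),
        chest=z.astype(bool),
        log=SliceLog(index=index, status=status, detail=detail),
    )


def _candidate_lungs(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Clean the 0-region (air within chest) into candidate lung blobs.

    Only small components are removed: an opening here would also erode the
    thin parenchyma wedge flanking a juxta-pleural nodule and artificially
    widen its notch mouth.
    """
    lung = binary == 0
    labels, n = ndi.label(lung, structure=_EIGHT)
    if n == 0:
        return lung
    sizes = ndi.sum_labels(lung, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def _trace_component(mask: np.ndarray) -> tracing.Contour:
    """Trace the border of a single connected component mask."""
    rs, cs = np.nonzero(mask)
    start = (int(rs[0]), int(cs[0]))  # topmost, leftmost in scan order
    return tracing.trace_border((~mask).astype(np.uint8), start)


def _refine_side(
    contour: tracing.Contour,
    raw_mask: np.ndarray,
    chest: np.ndarray,
    config: PipelineConfig,
):
    """Smooth + correct one lung contour; returns (pre_mask, final_mask,
    corrected_curve or None)."""
    shape = chest.shape
    try:
        curve = refinement.resample_contour(contour, step=config.arc_step)
    except DegenerateContour:
        # tiny lung section: keep the raw traced mask
        return raw_mask & chest, raw_mask & chest, None
    params = SmoothingParams(
        poly_degree=config.poly_degree,
        half_window=config.half_window,
        max_passes=config.max_passes,
        step=config.arc_step,
        perimeter_tol=config.t2_perimeter_tol,
    )
    smoothed = refinement.smooth_contour(curve, params)
    pre = refinement.rasterize(smoothed, shape) & chest
    corrected = refinement.correct_contour(
        smoothed,
        ratio_threshold=config.t1_ratio,
        perimeter_tol=config.t2_perimeter_tol,
        march_step=config.march_step,
    )
    final = refinement.rasterize(corrected, shape) & chest
    return pre, final, corrected


def segment_slice(
    slice_img: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    index: int = 0,
) -> SliceResult:
    """Segment the lungs on one (already aligned) slice."""
    img = np.asarray(slice_img, dtype=float)
    try:
        chest = preprocess.chest_mask(img, opening_radius=config.opening_radius)
    except NoForeground as exc:
        return _empty_result(img.shape, index, "no_chest", str(exc))

    threshold = preprocess.otsu_threshold(img)
    binary = tracing.binarize_within_chest(img, chest, threshold)
    lung_candidates = _candidate_lungs(binary, config.min_lung_area_px)
    if not lung_candidates.any():
        res = _empty_result(img.shape, index, "no_lung", "no candidate air region")
        res.chest = chest
        return res

    clean_binary = (~lung_candidates).astype(np.uint8)
    try:
        left_c, right_c = tracing.extract_lung_contours(clean_binary)
    except StartNotFound as exc:
        res = _empty_result(img.shape, index, "no_lung", str(exc))
        res.chest = chest
        return res

    labels, _ = ndi.label(lung_candidates, structure=_EIGHT)
    log = SliceLog(index=index)
    sides: dict[str, tuple[tracing.Contour, np.ndarray]] = {}
    fused = (
        left_c is not None
        and right_c is not None
        and labels[left_c.points[0]] == labels[right_c.points[0]]
    )
    if fused:
        comp = labels == labels[left_c.points[0]]
        try:
            sep = separation.separate_lungs(
                comp,
                img,
                max_iters=config.erosion_max_iters,
                band_fraction=config.dp_band_fraction,
            )
            log.separation_method = sep.method
            for name, m in (("left", sep.left_mask), ("right", sep.right_mask)):
                sides[name] = (_trace_component(m), m)
        except SeparationFailed as exc:
            log.separation_method = "failed"
            log.detail = str(exc)
            sides["left"] = (left_c, comp)
    else:
        if left_c is not None:
            sides["left"] = (left_c, labels == labels[left_c.points[0]])
        if right_c is not None:
            comp_r = labels == labels[right_c.points[0]]
            if left_c is None or labels[right_c.points[0]] != labels[left_c.points[0]]:
                sides["right"] = (right_c, comp_r)

    label_mask = np.zeros(img.shape, dtype=np.uint8)
    pre_union = np.zeros(img.shape, dtype=bool)
    contours = {}
    for name, (contour, raw_mask) in sides.items():
        try:
            pre, final, curve = _refine_side(contour, raw_mask, chest, config)
        except LungTraceError as exc:
            log.status = "partial"
            log.detail = f"{name}: {exc}"
            pre, final, curve = raw_mask & chest, raw_mask & chest, None
        value = LABEL_LEFT if name == "left" else LABEL_RIGHT
        label_mask[final & (label_mask == 0)] = value
        pre_union |= pre
        if curve is not None:
            log.n_concaves_corrected += curve.n_corrected
            contours[name] = curve

    if config.radiological_labels:
        swapped = label_mask.copy()
        swapped[label_mask == LABEL_LEFT] = LABEL_RIGHT
        swapped[label_mask == LABEL_RIGHT] = LABEL_LEFT
        label_mask = swapped

    return SliceResult(
        label_mask=label_mask,
        lung_mask=label_mask > 0,
        pre_correction_mask=pre_union,
        chest=chest,
        contours=contours,
        log=log,
    )


def run_pipeline(
    volume: CTVolume | np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Segment every slice of a volume (or a single 2D slice).

    Deterministic: the same volume and config always produce bit-identical
    outputs.  Per-slice failures produce empty slices and log entries; only
    unreadable input aborts.
    """
    if isinstance(volume, CTVolume):
        voxels = volume.voxels
    else:
        voxels = np.asarray(volume, dtype=float)
        if voxels.ndim == 2:
            voxels = voxels[None]
    n = voxels.shape[0]

    alignment = None
    try:
        alignment = preprocess.compute_principal_angle(
            voxels[n // 2],
            bone_threshold=config.bone_threshold,
            gate_deg=config.align_gate_deg,
        )
    except LungTraceError:
        pass

    labels = np.zeros(voxels.shape, dtype=np.uint8)
    pre = np.zeros(voxels.shape, dtype=bool)
    logs = []
    for i in range(n):
        sl = voxels[i]
        if alignment is not None and alignment.applied:
            sl = preprocess.align_image(sl, alignment, fill=float(sl.min()))
        res = segment_slice(sl, config, index=i)
        if alignment is not None:
            res.log.phi_deg = alignment.phi_deg
            res.log.aligned = alignment.applied
        labels[i] = res.label_mask
        pre[i] = res.pre_correction_mask
        logs.append(res.log)
    return PipelineResult(
        label_mask=labels,
        lung_mask=labels > 0,
        pre_correction_mask=pre,
        logs=logs,
        alignment=alignment,
    )
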