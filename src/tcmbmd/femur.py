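"""Femoral-neck vBMD protocol: segmentation, slice selection, VOI mean.

The clinical procedure converts a single mean CT number of the femoral
neck to vBMD: bone is segmented from soft tissue at a 250 HU threshold,
the coronal slice with the maximum neck cross-sectional area plus its two
neighbours is selected, and the mean HU over the neck VOI on those slices
is pushed through the TCM inversion.

Segmentation is performed on the whole slice (threshold, hole filling so
low-HU marrow and nonosseous voids enclosed by the cortical contour are
kept, largest connected component); the operator-drawn neck ROI then
confines both the area measurement and the VOI average.  Averaging over
the filled contour -- including sub-threshold interior voxels -- is what
lets the neck mean reflect nonosseous areas; a ``bone_only`` switch
restricts the average to supra-threshold voxels for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label

from .calibration import ROISpec
from .core import (
    CalibrationEntry,
    CalibrationTable,
    DiagnosticClass,
    classify_acr,
    ctn_to_bvf_vbmd,
)
from .image_io import CTImage

__all__ = [
    "BONE_THRESHOLD_HU",
    "SegmentationError",
    "SliceSelection",
    "VOIResult",
    "femoral_neck_vbmd",
    "segment_bone",
    "select_voi_slices",
]

#: HU threshold separating bone from surrounding soft tissue
BONE_THRESHOLD_HU = 250.0


class SegmentationError(ValueError):
    """Raised when no bone can be segmented from a slice."""


def segment_bone(
    slice_hu: np.ndarray,
    threshold: float = BONE_THRESHOLD_HU,
    roi: ROISpec | None = None,
    image: CTImage | None = None,
) -> np.ndarray:
    """Segment the bone contour of a 2D slice.

    Pixels >= ``threshold`` are thresholded, holes are filled (enclosed
    marrow/void pixels belong to the bone contour), and the largest
    connected component is kept.  With ``roi`` (requires ``image`` for
    pixel spacing), the component with the largest overlap with the ROI is
    kept instead, so stray high-HU speckle elsewhere cannot win.
    """
    slice_hu = np.asarray(slice_hu, dtype=float)
    if slice_hu.ndim != 2:
        raise ValueError("segment_bone expects a 2D slice")
    above = slice_hu >= threshold
    if not above.any():
        raise SegmentationError(
            f"no bone: no pixels at or above {threshold} HU in slice"
        )
    filled = binary_fill_holes(above)
    labels, n = label(filled, return_num=True)
    if n == 1:
        return filled
    if roi is not None and image is not None:
        roi_mask = roi.mask(image) if image.voxels.ndim == 2 else _roi_mask_2d(roi, image)
        overlaps = [(labels[roi_mask] == i).sum() for i in range(1, n + 1)]
        if max(overlaps) > 0:
            return labels == (int(np.argmax(overlaps)) + 1)
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def _roi_mask_2d(roi: ROISpec, image: CTImage) -> np.ndarray:
    flat = CTImage(
        voxels=image.get_slice(0),
        pixel_spacing=image.pixel_spacing,
        slice_thickness=image.slice_thickness,
        kvp=image.kvp,
    )
    return roi.mask(flat)


@dataclass(frozen=True)
class SliceSelection:
    """Outcome of maximum-neck-area slice selection."""

    indices: tuple[int, ...]
    areas_mm2: tuple[float, ...]
    max_index: int
    tie: bool = False
    at_boundary: bool = False


def select_voi_slices(
    volume: CTImage,
    neck_roi: ROISpec,
    threshold: float = BONE_THRESHOLD_HU,
) -> SliceSelection:
    """Pick the maximum-neck-area slice and its two neighbours.

    Area per slice is the filled-bone pixel count inside ``neck_roi`` times
    the pixel area (mm^2); slices with no supra-threshold pixels score zero.
    Ties go to the lower index (flagged); a maximum at the volume boundary
    returns the two available neighbours and sets ``at_boundary``.
    """
    if volume.voxels.ndim != 3 or volume.n_slices < 3:
        raise ValueError("slice selection requires a 3D volume with >= 3 slices")
    roi_mask = _roi_mask_2d(neck_roi, volume)
    pixel_area = volume.pixel_spacing[0] * volume.pixel_spacing[1]
    areas = []
    for i in range(volume.n_slices):
        try:
            mask = segment_bone(volume.voxels[i], threshold, neck_roi, volume)
        except SegmentationError:
            areas.append(0.0)
            continue
        areas.append(float((mask & roi_mask).sum()) * pixel_area)
    areas_arr = np.asarray(areas)
    best = int(np.argmax(areas_arr))  # argmax takes the lowest index on ties
    tie = int((areas_arr == areas_arr[best]).sum()) > 1
    indices = [i for i in (best - 1, best, best + 1) if 0 <= i < volume.n_slices]
    return SliceSelection(
        indices=tuple(indices),
        areas_mm2=tuple(areas),
        max_index=best,
        tie=tie,
        at_boundary=len(indices) < 3,
    )


@dataclass
class VOIResult:
    """Femoral-neck VOI summary: mean HU, vBMD and diagnostic class."""

    selection: SliceSelection
    voi_masks: np.ndarray  # boolean, one plane per selected slice
    mean_ctn: float
    vbmd: float
    n_voxels: int
    diagnostic: DiagnosticClass
    calibration: CalibrationEntry


def femoral_neck_vbmd(
    volume: CTImage,
    neck_roi: ROISpec,
    calibration: CalibrationEntry | CalibrationTable,
    kvp: int | None = None,
    threshold: float = BONE_THRESHOLD_HU,
    bone_only: bool = False,
    selection_roi: ROISpec | None = None,
) -> VOIResult:
    """Mean femoral-neck CT number over the selected slices, converted to vBMD.

    The VOI is the intersection of the filled bone mask with ``neck_roi``
    on each selected slice; ``bone_only`` drops the hole-filled
    sub-threshold voxels from the average instead.  ``selection_roi``
    (default: ``neck_roi``) is the region used only for the per-slice area
    ranking -- drawn generously around the neck so the cross-section is not
    cropped, while ``neck_roi`` itself may be a tighter region excluding,
    e.g., the cortical shell.
    """
    if isinstance(calibration, CalibrationTable):
        entry = calibration[kvp if kvp is not None else (volume.kvp or -1)]
    else:
        entry = calibration
    selection = select_voi_slices(volume, selection_roi or neck_roi, threshold)
    roi_mask = _roi_mask_2d(neck_roi, volume)
    masks, values = [], []
    for i in selection.indices:
        slab = volume.voxels[i]
        bone = segment_bone(slab, threshold, neck_roi, volume)
        if bone_only:
            bone = bone & (slab >= threshold)
        voi = bone & roi_mask
        masks.append(voi)
        values.append(slab[voi])
    values = np.concatenate(values) if values else np.empty(0)
    if values.size == 0:
        raise SegmentationError("VOI contains no voxels on the selected slices")
    mean_ctn = float(values.mean())
    dm = ctn_to_bvf_vbmd(mean_ctn, entry)
    vbmd = float(dm.vbmd)
    return VOIResult(
        selection=selection,
        voi_masks=np.stack(masks),
        mean_ctn=mean_ctn,
        vbmd=vbmd,
        n_voxels=int(values.size),
        diagnostic=classify_acr(max(vbmd, 0.0)),
        calibration=entry,
    )
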