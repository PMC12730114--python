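"""Nucleus and perinuclear-ring segmentation from the blue channel.

Nuclei are segmented on the 512x512 (or synthetic-size) blue channel.  The
default backend is a classical pipeline (Gaussian smoothing, Otsu threshold,
hole filling, connected components, optional watershed splitting); a
``cellpose_nuclei`` backend name is reserved for the external deep model and
raises a clear error when that library is not installed.

Detected nuclei are filtered by minimum area (100 px) and border contact.
The perinuclear ring is ``dilate(mask) AND NOT erode(mask)`` with a 5x5
disk-shaped structuring element: the discrete radius-2 disk inscribed in a
5x5 window (13-pixel footprint).  Masks found at low resolution can be
projected to the full-resolution frame by nearest-neighbor upscaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg, transform

DISK_5X5 = morphology.disk(2)  # 13-pixel discrete disk inscribed in 5x5


@dataclass
class NucleusROI:
    roi_id: int
    mask: np.ndarray  # boolean, full image frame
    area_px: int
    touches_border: bool
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    @classmethod
    def from_mask(cls, roi_id: int, mask: np.ndarray) -> "NucleusROI":
        mask = np.asarray(mask, dtype=bool)
        rows = np.any(mask, axis=1)
        cols = np.any(mask, axis=0)
        if not rows.any():
            raise ValueError("empty mask")
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        border = bool(
            mask[0, :].any()
            or mask[-1, :].any()
            or mask[:, 0].any()
            or mask[:, -1].any()
        )
        return cls(
            roi_id=roi_id,
            mask=mask,
            area_px=int(mask.sum()),
            touches_border=border,
            bbox=(int(r0), int(c0), int(r1) + 1, int(c1) + 1),
        )


@dataclass
class RingROI:
    parent_roi_id: int
    mask: np.ndarray  # boolean, same frame as parent


@dataclass
class SegmentationBackend:
    """Named segmentation backend with its parameters.

    ``threshold_fallback`` is the self-contained classical pipeline;
    ``cellpose_nuclei`` requires the external cellpose package.
    """

    name: str = "threshold_fallback"
    params: dict = field(default_factory=dict)


def _threshold_label(blue: np.ndarray, params: dict) -> np.ndarray:
    smooth_sigma = params.get("smooth_sigma", 1.0)
    watershed_split = params.get("watershed_split", False)
    mean_diameter_px = params.get("mean_diameter_px", 55)

    img = blue.astype(np.float64)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma)
    if img.max() - img.min() < 1.0:
        return np.zeros(blue.shape, dtype=np.int32)
    thr = filters.threshold_otsu(img)
    fg = img > thr
    # Otsu on a (near-)blank image splits noise; reject degenerate foregrounds.
    frac = fg.mean()
    if frac == 0.0 or frac > 0.5:
        return np.zeros(blue.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=8)
    labels, _ = ndi.label(fg)
    if watershed_split:
        dist = ndi.distance_transform_edt(fg)
        min_dist = max(3, int(mean_diameter_px // 2))
        coords = morphology.local_maxima(
            ndi.gaussian_filter(dist, 1.0), connectivity=2
        )
        markers, _ = ndi.label(coords)
        if markers.max() > 0:
            ws = skseg.watershed(-dist, markers, mask=fg)
            # keep watershed split only where it refines a component
            labels = ws
        _ = min_dist
    return labels.astype(np.int32)


def segment_nuclei(
    blue: np.ndarray, backend: SegmentationBackend | None = None
) -> list[NucleusROI]:
    """Segment nuclei in a grayscale blue-channel image into disjoint ROIs."""
    backend = backend or SegmentationBackend()
    if backend.name == "cellpose_nuclei":
        try:
            import cellpose  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "cellpose backend requested but the cellpose package is not "
                "installed; use SegmentationBackend('threshold_fallback')"
            ) from exc
        raise NotImplementedError("cellpose backend plugin not wired in this build")
    if backend.name != "threshold_fallback":
        raise ValueError(f"unknown segmentation backend: {backend.name!r}")
    labels = _threshold_label(np.asarray(blue), backend.params)
    rois = []
    for rid in range(1, int(labels.max()) + 1):
        mask = labels == rid
        if mask.any():
            rois.append(NucleusROI.from_mask(roi_id=rid, mask=mask))
    return rois


def filter_rois(
    rois: list[NucleusROI], min_area: int = 100, exclude_border: bool = True
) -> list[NucleusROI]:
    """Drop nuclei smaller than ``min_area`` pixels or touching the border."""
    out = []
    for roi in rois:
        if roi.area_px < min_area:
            continue
        if exclude_border and roi.touches_border:
            continue
        out.append(roi)
    return out


def ring_from_nucleus(mask: np.ndarray, parent_roi_id: int = 0) -> RingROI:
    """Perinuclear ring: dilation minus erosion with the 5x5 disk element."""
    mask = np.asarray(mask, dtype=bool)
    dilated = ndi.binary_dilation(mask, structure=DISK_5X5)
    eroded = ndi.binary_erosion(mask, structure=DISK_5X5)
    return RingROI(parent_roi_id=parent_roi_id, mask=dilated & ~eroded)


def project_to_fullres(mask512: np.ndarray, full_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor upscale of a boolean mask to the full-resolution frame."""
    mask512 = np.asarray(mask512, dtype=bool)
    if mask512.shape == tuple(full_shape):
        return mask512.copy()
    out = transform.resize(
        mask512.astype(np.float32),
        full_shape,
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    )
    return out > 0.5


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return int(r0), int(c0), int(r1) + 1, int(c1) + 1


def crop_roi(
    image_full: np.ndarray,
    mask_full: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Crop the masked region: background outside the mask is zeroed.

    ``bbox`` defaults to the tight bounding box of ``mask_full``.
    """
    mask_full = np.asarray(mask_full, dtype=bool)
    if not mask_full.any():
        raise ValueError("cannot crop an empty mask")
    if bbox is None:
        bbox = _bbox_of(mask_full)
    r0, c0, r1, c1 = bbox
    masked = np.where(mask_full, image_full, 0)
    return masked[r0:r1, c0:c1]


def representative_cell(rois: list[NucleusROI]) -> NucleusROI:
    """The median-area ROI (lower median for even counts; ties by lowest id)."""
    if not rois:
        raise ValueError("no ROIs to choose from")
    ordered = sorted(rois, key=lambda r: (r.area_px, r.roi_id))
    return ordered[(len(ordered) - 1) // 2]
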