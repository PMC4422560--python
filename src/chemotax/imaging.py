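"""Frame processing: background estimation, segmentation, area filtering.

The background of each frame is estimated as the 80th-percentile intensity
of 32 × 32-pixel blocks (80 × 80 μm at 2.5 μm/px), bilinearly interpolated
between block centers — a percentile high enough to ride above most of the
pixel noise but robust to the bright nuclei, which occupy a small fraction
of each block. After subtraction (clamped at zero), nuclei are segmented by
a single global intensity threshold followed by a watershed on the inverted
distance transform to split touching cells. Objects with area ≤ 5 px or
> 75 px are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

DEFAULT_BLOCK_PX = 32
DEFAULT_PERCENTILE = 80.0
DEFAULT_MIN_AREA_PX = 5  # exclusive: objects with area <= 5 are dropped
DEFAULT_MAX_AREA_PX = 75  # inclusive: area 75 is kept


@dataclass
class BackgroundField:
    """Blockwise-percentile background.

    ``block_values[i, j]`` is the percentile of block (i, j); ``full`` is the
    bilinear interpolation between block centers at full resolution, with
    pixels beyond the outermost centers clamped to the nearest center value
    (hence every interpolated value lies within the block-value range).
    """

    block_values: np.ndarray
    row_centers: np.ndarray
    col_centers: np.ndarray
    full: np.ndarray
    block_px: int
    percentile: float


@dataclass(frozen=True)
class DetectedObject:
    """One segmented nucleus: sub-pixel centroid (x = column, y = row,
    0-based) and area in pixels."""

    x: float
    y: float
    area: int
    frame: int | None = None
    channel: str | None = None
    well: str | None = None


def _block_slices(size: int, block: int) -> list[slice]:
    edges = list(range(0, size, block))
    return [slice(e, min(e + block, size)) for e in edges]


def estimate_background(
    img: np.ndarray,
    block_px: int = DEFAULT_BLOCK_PX,
    percentile: float = DEFAULT_PERCENTILE,
) -> BackgroundField:
    """Blockwise percentile background with bilinear interpolation.

    The image is tiled into ``block_px``-sized blocks (a trailing partial
    block per axis if the size is not a multiple); each block contributes
    its ``percentile`` value anchored at the block's pixel-center.
    """
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    if rows < block_px or cols < block_px:
        raise ValueError("image dimensions must be >= block_px")
    rslices = _block_slices(rows, block_px)
    cslices = _block_slices(cols, block_px)
    vals = np.empty((len(rslices), len(cslices)))
    for i, rs in enumerate(rslices):
        for j, cs in enumerate(cslices):
            vals[i, j] = np.percentile(img[rs, cs], percentile)
    rc = np.array([(s.start + s.stop - 1) / 2.0 for s in rslices])
    cc = np.array([(s.start + s.stop - 1) / 2.0 for s in cslices])

    # clamped bilinear: clip pixel coordinates into the span of the centers
    rq = np.clip(np.arange(rows, dtype=float), rc[0], rc[-1])
    cq = np.clip(np.arange(cols, dtype=float), cc[0], cc[-1])
    full = _bilinear(rc, cc, vals, rq, cq)
    return BackgroundField(vals, rc, cc, full, block_px, percentile)


def _bilinear(
    rc: np.ndarray, cc: np.ndarray, vals: np.ndarray, rq: np.ndarray, cq: np.ndarray
) -> np.ndarray:
    """Separable linear interpolation of a grid of anchors onto query rows
    and columns (queries assumed within the anchor span)."""
    interp_rows = np.empty((len(rq), vals.shape[1]))
    for j in range(vals.shape[1]):
        interp_rows[:, j] = np.interp(rq, rc, vals[:, j])
    out = np.empty((len(rq), len(cq)))
    for i in range(len(rq)):
        out[i] = np.interp(cq, cc, interp_rows[i])
    return out


def subtract_background(img: np.ndarray, bg: BackgroundField | np.ndarray) -> np.ndarray:
    """Subtract the background, clamping negative values to zero."""
    bg_arr = bg.full if isinstance(bg, BackgroundField) else np.asarray(bg, dtype=float)
    img = np.asarray(img, dtype=float)
    if img.shape != bg_arr.shape:
        raise ValueError("image and background shapes differ")
    return np.clip(img - bg_arr, 0.0, None)


def segment(
    img: np.ndarray,
    threshold: float,
    min_peak_separation_px: int = 2,
    rel_peak_floor: float = 0.5,
    frame: int | None = None,
    channel: str | None = None,
    well: str | None = None,
) -> list[DetectedObject]:
    """Threshold segmentation with watershed splitting of touching nuclei.

    The supra-threshold mask (strictly ``img > threshold``) is split by a
    watershed on the inverted Euclidean distance transform, seeded at local
    distance maxima with a minimum separation; maxima shallower than
    ``rel_peak_floor`` times their connected component's distance maximum
    (e.g. on a thin bridge between two lobes) are not used as seeds, so a
    dumbbell splits into its two lobes rather than fragmenting. Centroids
    are the unweighted means of member pixel coordinates; areas are pixel
    counts. No area filtering is applied here (see :func:`filter_by_area`).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    img = np.asarray(img, dtype=float)
    mask = img > threshold
    if not mask.any():
        return []
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_peak_separation_px, labels=mask, exclude_border=False
    )
    if len(peaks):
        comp, n_comp = ndi.label(mask)
        comp_max = ndi.maximum(distance, comp, index=np.arange(1, n_comp + 1))
        peak_comp = comp[tuple(peaks.T)]
        keep = distance[tuple(peaks.T)] >= rel_peak_floor * comp_max[peak_comp - 1]
        peaks = peaks[keep]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    # mask pixels not claimed by any seed (tiny fragments) get their own labels
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    objs = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid  # row, col
        objs.append(
            DetectedObject(
                x=float(cx), y=float(cy), area=int(prop.area),
                frame=frame, channel=channel, well=well,
            )
        )
    return objs


def filter_by_area(
    objects: list[DetectedObject],
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
) -> list[DetectedObject]:
    """Retain objects with ``min_area_px < area <= max_area_px``."""
    return [o for o in objects if min_area_px < o.area <= max_area_px]


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu threshold helper (convenience for synthetic data; the assay
    itself uses a single manually chosen threshold for all wells)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(img, dtype=float)))


def detect_stack(
    stack: np.ndarray,
    threshold: float,
    block_px: int = DEFAULT_BLOCK_PX,
    percentile: float = DEFAULT_PERCENTILE,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
    channel: str | None = None,
    well: str | None = None,
) -> pd.DataFrame:
    """Run background subtraction, segmentation and area filtering on every
    frame of a stack; return detections as a DataFrame with columns
    ``well, frame, channel, x_px, y_px, area_px``."""
    rows = []
    for f, frame_img in enumerate(stack):
        bg = estimate_background(frame_img, block_px, percentile)
        clean = subtract_background(frame_img, bg)
        objs = filter_by_area(
            segment(clean, threshold, frame=f, channel=channel, well=well),
            min_area_px,
            max_area_px,
        )
        rows.extend(
            {"well": well, "frame": f, "channel": channel,
             "x_px": o.x, "y_px": o.y, "area_px": o.area}
            for o in objs
        )
    return pd.DataFrame(rows, columns=["well", "frame", "channel", "x_px", "y_px", "area_px"])
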