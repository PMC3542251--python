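"""Stain-positive lymphocyte detection in IHC images.

Detection follows a three-step pipeline: (i) color thresholding selects
candidate DAB-brown (positive) pixels against the hematoxylin-blue
counterstain, (ii) a watershed on the distance transform splits touching
cells, and (iii) a size filter removes debris and merged clumps outside the
plausible lymphocyte area range.

The thresholding rule is a plain RGB proxy for brown-vs-blue: a pixel is
candidate-positive when its blue channel is below ``blue_intensity``, its
red channel is above ``red_intensity`` and red exceeds blue.  The three
tunables (object size bounds, blue intensity, red intensity) are exposed in
:class:`DetectionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .geometry import RectangleROI, roi_contains

__all__ = [
    "IHCImage",
    "DetectionParams",
    "CellDetection",
    "stain_mask",
    "split_touching",
    "size_filter",
    "detect_cells",
]

#: minimum separation of watershed markers, um; controls over-splitting of
#: closely packed lymphocytes
MARKER_MIN_SEPARATION_UM = 4.0


@dataclass(frozen=True)
class IHCImage:
    """RGB raster with isotropic physical calibration (microns per pixel)."""

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("IHC image must be an RGB (H, W, 3) raster")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape_um(self) -> tuple[float, float]:
        """(height, width) of the field of view in um."""
        h, w = self.pixels.shape[:2]
        return h * self.mpp, w * self.mpp


@dataclass(frozen=True)
class DetectionParams:
    """The tunable detection parameters: size bounds and color thresholds.

    Size bounds are object areas in um^2 (defaults 15-150 um^2, i.e. a
    lymphocyte-scale equivalent diameter of ~4.4-13.8 um); intensity
    thresholds are 8-bit channel values.
    """

    size_min: float = 15.0
    size_max: float = 150.0
    blue_intensity: int = 160
    red_intensity: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.size_min < self.size_max:
            raise ValueError("require 0 < size_min < size_max")
        for name in ("blue_intensity", "red_intensity"):
            val = getattr(self, name)
            if not 0 <= val <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")


@dataclass(frozen=True)
class CellDetection:
    """One detected stain-positive cell (image-frame um coordinates)."""

    x_um: float
    y_um: float
    area_um2: float
    mean_positive_intensity: float

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um])


def stain_mask(img: IHCImage, params: DetectionParams) -> np.ndarray:
    """Binary mask of candidate positive-stain (DAB brown) pixels."""
    px = img.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("stain_mask requires an RGB image")
    r = px[..., 0].astype(np.int16)
    b = px[..., 2].astype(np.int16)
    return (b < params.blue_intensity) & (r > params.red_intensity) & (r > b)


def split_touching(mask: np.ndarray, mpp: float) -> np.ndarray:
    """Split touching blobs with a watershed on the distance transform.

    Markers are the local maxima of the Euclidean distance transform at a
    minimum mutual separation of 4 um; every connected component keeps at
    least one marker, so no object is lost.  Returns an integer label
    image partitioning the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    components = cc_label(mask, connectivity=2)
    dist = ndi.distance_transform_edt(mask)
    min_dist = max(1, int(round(MARKER_MIN_SEPARATION_UM / mpp)))
    coords = peak_local_max(
        dist, min_distance=min_dist, labels=components, exclude_border=False
    )
    # guarantee a marker in every component (flat tiny blobs can miss out)
    seen = set(components[tuple(coords.T)]) if coords.size else set()
    missing = [i for i in range(1, components.max() + 1) if i not in seen]
    if missing:
        extra = []
        for i in missing:
            masked = np.where(components == i, dist, -1.0)
            extra.append(np.unravel_index(np.argmax(masked), mask.shape))
        coords = np.vstack([coords.reshape(-1, 2), np.array(extra)])
    markers = np.zeros(mask.shape, dtype=np.int32)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    for k, (r, c) in enumerate(coords[order], start=1):
        markers[r, c] = k
    return watershed(-dist, markers=markers, mask=mask).astype(np.int32)


def size_filter(
    labels: np.ndarray,
    mpp: float,
    params: DetectionParams,
    intensity_image: np.ndarray | None = None,
) -> list[CellDetection]:
    """Keep labeled objects with area in [size_min, size_max] um^2.

    Centroids are reported in um (x = column * mpp, y = row * mpp); mean
    positive intensity is the object's mean over ``intensity_image`` (the
    red channel by convention), NaN when no intensity image is given.
    """
    px_area = mpp * mpp
    out: list[CellDetection] = []
    for prop in regionprops(labels, intensity_image=intensity_image):
        area = prop.area * px_area
        if not params.size_min <= area <= params.size_max:
            continue
        cy, cx = prop.centroid
        mean_int = float(prop.intensity_mean) if intensity_image is not None else float("nan")
        out.append(
            CellDetection(
                x_um=float(cx * mpp),
                y_um=float(cy * mpp),
                area_um2=float(area),
                mean_positive_intensity=mean_int,
            )
        )
    out.sort(key=lambda d: (d.y_um, d.x_um))
    return out


def detect_cells(
    img: IHCImage, roi: RectangleROI, params: DetectionParams | None = None
) -> list[CellDetection]:
    """Full detection inside a rectangle: threshold, split, size-filter.

    Objects straddling the ROI edge are kept iff their centroid falls
    inside the rectangle (unbiased counting rule).  Deterministic for
    fixed inputs.
    """
    params = params or DetectionParams()
    h_um, w_um = img.shape_um
    corners = roi.corners()
    if (
        corners[:, 0].min() < -1e-6
        or corners[:, 1].min() < -1e-6
        or corners[:, 0].max() > w_um + 1e-6
        or corners[:, 1].max() > h_um + 1e-6
    ):
        raise ValueError("ROI exceeds image bounds")

    # restrict processing to the ROI's bounding box (plus a margin so
    # watershed splitting of edge-straddling clumps is unaffected)
    pad_px = int(np.ceil(2.0 * np.sqrt(params.size_max / np.pi) / img.mpp)) + 2
    r0 = max(0, int(corners[:, 1].min() / img.mpp) - pad_px)
    r1 = min(img.pixels.shape[0], int(np.ceil(corners[:, 1].max() / img.mpp)) + pad_px)
    c0 = max(0, int(corners[:, 0].min() / img.mpp) - pad_px)
    c1 = min(img.pixels.shape[1], int(np.ceil(corners[:, 0].max() / img.mpp)) + pad_px)
    crop = img.pixels[r0:r1, c0:c1]

    mask = stain_mask(IHCImage(crop, img.mpp), params)
    labels = split_touching(mask, img.mpp)
    dets = size_filter(labels, img.mpp, params, intensity_image=crop[..., 0])

    off_x, off_y = c0 * img.mpp, r0 * img.mpp
    shifted = [
        CellDetection(d.x_um + off_x, d.y_um + off_y, d.area_um2, d.mean_positive_intensity)
        for d in dets
    ]
    return [d for d in shifted if roi_contains(d.centroid, roi)]
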