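"""Larva/background segmentation by contrast-based edge detection.

The stages mirror the classic morphology pipeline for low-contrast
microscope slides of single anesthetized larvae:

1. ``preprocess``      – Gaussian smoothing followed by unsharp masking, so
   short low-contrast gaps in the body outline gain enough contrast to be
   detected as edges.
2. ``detect_edges``    – Sobel gradient magnitude thresholded at a fraction
   of the *maximum* gradient inside the region of interest, making the
   threshold adaptive to overall image contrast.
3. ``close_outline``   – binary dilation (square element) then erosion
   (diamond element) to bridge remaining gaps without inflating the outline.
4. ``extract_regions`` – fill enclosed areas and drop everything connected
   to an image border (water-drop lines, frame edges).
5. ``select_largest``  – the largest 8-connected component is the larva;
   its moment-equivalent ellipse provides the body-axis orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.morphology import diamond

from .errors import NoContrastError, NoLarvaFoundError, ValidationError
from .imaging import GrayImage, RegionOfInterest, roi_mask

#: 8-connectivity structuring element for component labeling.
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation settings.

    ``threshold_fraction`` is the edge threshold as a fraction of the
    maximum gradient magnitude inside the ROI (default 0.55);
    ``dilation_factor`` the radius of the square dilation / diamond erosion
    pair (default 3); ``gaussian_sigma`` the smoothing scale in pixels
    (default 4); ``sharpen_amount`` the unsharp-masking gain;
    ``min_area_fraction`` the smallest acceptable larva area as a fraction
    of the ROI pixel count.
    """

    threshold_fraction: float = 0.55
    dilation_factor: int = 3
    gaussian_sigma: float = 4.0
    sharpen_amount: float = 0.8
    min_area_fraction: float = 0.0005
    roi: RegionOfInterest = field(default_factory=RegionOfInterest.full)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValidationError("threshold_fraction must be in (0, 1]")
        if self.dilation_factor < 0 or int(self.dilation_factor) != self.dilation_factor:
            raise ValidationError("dilation_factor must be a non-negative integer")
        if self.gaussian_sigma < 0:
            raise ValidationError("gaussian_sigma must be >= 0")
        if self.min_area_fraction < 0:
            raise ValidationError("min_area_fraction must be >= 0")


@dataclass(frozen=True)
class LarvaMask:
    """A single-component binary larva segmentation with its ellipse axis.

    ``orientation_deg`` is the major-axis angle of the moment-equivalent
    ellipse in degrees, measured from the +x axis, counterclockwise positive
    in standard (y-up) math orientation, range (-90, 90].
    """

    pixels: np.ndarray
    orientation_deg: float
    centroid: tuple[float, float]
    area: int


def preprocess(image: GrayImage, sigma: float = 4.0, amount: float = 0.8) -> GrayImage:
    """Gaussian blur then unsharp masking at the same scale.

    ``out = blurred + amount * (blurred - reblurred)``, clipped to [0, 1].
    ``sigma == 0`` is the identity.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return image
    blurred = ndi.gaussian_filter(image.pixels, sigma)
    reblurred = ndi.gaussian_filter(blurred, sigma)
    out = blurred + amount * (blurred - reblurred)
    return GrayImage(np.clip(out, 0.0, 1.0))


def detect_edges(
    image: GrayImage,
    threshold_fraction: float = 0.55,
    roi: RegionOfInterest | None = None,
) -> np.ndarray:
    """Threshold the Sobel gradient magnitude at a fraction of its ROI maximum.

    Both the maximum-contrast estimate and the returned edge pixels are
    restricted to the region of interest, so high-contrast artifacts such as
    scale bars outside the ROI cannot inflate the threshold.
    """
    if roi is None:
        roi = RegionOfInterest.full()
    inside = roi_mask(roi, image.height, image.width)
    if not inside.any():
        raise ValidationError("region of interest contains no pixels")
    grad = sobel(image.pixels)
    max_contrast = float(grad[inside].max())
    # intensities are in [0, 1]; anything at double-precision noise level is
    # a numerically flat field, not contrast
    if max_contrast <= 1e-12:
        raise NoContrastError("region of interest is perfectly flat (no contrast)")
    return (grad > threshold_fraction * max_contrast) & inside


def close_outline(edges: np.ndarray, dilation_factor: int = 3) -> np.ndarray:
    """Bridge outline gaps: square dilation then diamond erosion, same radius.

    A dilation factor of 0 is the identity.  The square element of side
    ``2 * factor + 1`` closes gaps up to ~2x the factor; the diamond erosion
    pulls exaggerated edges back in.
    """
    edges = np.asarray(edges).astype(bool)
    f = int(dilation_factor)
    if f < 0:
        raise ValidationError("dilation_factor must be >= 0")
    if f == 0:
        return edges.copy()
    # maximum_filter with a square window == binary dilation by the square;
    # pad dilation with background, erosion with foreground so border-touching
    # structures keep their border contact (and are later rejected as such).
    dilated = ndi.maximum_filter(edges, size=2 * f + 1, mode="constant", cval=0)
    return ndi.binary_erosion(dilated, structure=diamond(f).astype(bool), border_value=1)


def extract_regions(closed: np.ndarray) -> np.ndarray:
    """Fill enclosed areas, then discard components touching any border.

    Hole filling uses 4-connected background (complementary to the
    8-connected foreground used for labeling).  Border rejection removes
    water-drop lines that run from edge to edge and anything partially
    outside the frame.
    """
    closed = np.asarray(closed).astype(bool)
    filled = ndi.binary_fill_holes(closed)
    labels, n = ndi.label(filled, structure=_CONN8)
    if n == 0:
        return filled
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = border_labels[border_labels != 0]
    if border_labels.size:
        filled[np.isin(labels, border_labels)] = False
    return filled


def select_largest(regions: np.ndarray, min_area: float = 0.0) -> LarvaMask:
    """Keep the largest 8-connected component and characterize its ellipse."""
    regions = np.asarray(regions).astype(bool)
    labels, n = ndi.label(regions, structure=_CONN8)
    if n == 0:
        raise NoLarvaFoundError("no candidate region found")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    area = int(sizes[best - 1])
    if area < min_area:
        raise NoLarvaFoundError(
            f"largest region has area {area} px < minimum {min_area:.0f} px"
        )
    mask = labels == best
    centroid, orientation = region_orientation(mask)
    return LarvaMask(pixels=mask, orientation_deg=orientation, centroid=centroid, area=area)


def region_orientation(mask: np.ndarray) -> tuple[tuple[float, float], float]:
    """Centroid and major-axis angle of the moment-equivalent ellipse.

    The angle is computed from second central moments in a y-up frame so
    that positive angles are counterclockwise from +x, range (-90, 90].
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValidationError("empty mask has no orientation")
    cx, cy = float(xs.mean()), float(ys.mean())
    dx = xs - cx
    dy = ys - cy
    mu20 = float((dx * dx).mean())
    mu02 = float((dy * dy).mean())
    mu11 = float((dx * dy).mean())
    # y grows downward in image coordinates; negate mu11 for a y-up angle.
    theta = 0.5 * math.degrees(math.atan2(-2.0 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    return (cx, cy), theta


def segment_larva(image: GrayImage, params: SegmentationParams | None = None) -> LarvaMask:
    """Full segmentation pipeline: preprocess, edges, closure, regions, select.

    Deterministic for fixed inputs.  Raises :class:`NoContrastError` on flat
    ROIs and :class:`NoLarvaFoundError` when nothing of sufficient area
    survives border rejection.
    """
    if params is None:
        params = SegmentationParams()
    params.roi.validate_for(image.height, image.width)
    pre = preprocess(image, params.gaussian_sigma, params.sharpen_amount)
    edges = detect_edges(pre, params.threshold_fraction, params.roi)
    closed = close_outline(edges, params.dilation_factor)
    regions = extract_regions(closed)
    roi_area = int(roi_mask(params.roi, image.height, image.width).sum())
    mask = select_largest(regions, min_area=params.min_area_fraction * roi_area)
    return mask
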