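"""Image loading, grayscale normalization, regions of interest, QC overlays.

The package works on a single in-memory representation, :class:`GrayImage`:
a 2-D float array of intensities in [0, 1] on a pixel grid with 0-based
coordinates, ``x`` = column, ``y`` = row, y increasing downward.  Rectangle
regions of interest are half-open, so areas are plain differences of bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as _draw_line

from .errors import ValidationError

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

MIN_SIDE = 8


@dataclass(frozen=True)
class GrayImage:
    """A grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels:
        2-D float array.  Values outside [0, 1] or images smaller than
        8x8 are rejected.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"image of shape {px.shape} is smaller than {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.isfinite(px).all():
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangle, circle, or full-frame region restricting segmentation.

    Rectangles are half-open pixel bounds ``(x0, y0, x1, y1)``; circles are
    ``(cx, cy, radius)`` with membership decided by pixel-center distance
    <= radius.
    """

    shape: str = "full"
    rect: tuple[float, float, float, float] | None = None
    circle: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("full", "rectangle", "circle"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "rectangle":
            if self.rect is None:
                raise ValidationError("rectangle ROI requires rect bounds")
            x0, y0, x1, y1 = self.rect
            if not (x0 < x1 and y0 < y1):
                raise ValidationError(f"degenerate rectangle bounds {self.rect}")
        if self.shape == "circle":
            if self.circle is None:
                raise ValidationError("circle ROI requires (cx, cy, radius)")
            if self.circle[2] <= 0:
                raise ValidationError("circle radius must be positive")

    @classmethod
    def full(cls) -> "RegionOfInterest":
        return cls("full")

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float) -> "RegionOfInterest":
        return cls("rectangle", rect=(x0, y0, x1, y1))

    @classmethod
    def circle_roi(cls, cx: float, cy: float, radius: float) -> "RegionOfInterest":
        return cls("circle", circle=(cx, cy, radius))

    def validate_for(self, height: int, width: int) -> None:
        """Raise if the region does not fit inside a height x width image."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.rect
            if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
                raise ValidationError(
                    f"rectangle {self.rect} outside image bounds {width}x{height}"
                )
        elif self.shape == "circle":
            cx, cy, _ = self.circle
            if not (0 <= cx < width and 0 <= cy < height):
                raise ValidationError(
                    f"circle center {self.circle[:2]} outside image {width}x{height}"
                )


def load_image(path: str | Path) -> GrayImage:
    """Read a raster file (PNG/TIFF/JPEG/BMP) as a normalized grayscale image.

    Integer images are rescaled by their dtype maximum; RGB(A) images are
    reduced to luminance with BT.601 weights.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"image file does not exist: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises various backend errors
        raise OSError(f"could not read image file {path}: {exc}") from exc
    return to_gray(arr)


def to_gray(arr: np.ndarray) -> GrayImage:
    """Normalize a raw raster array (any supported dtype/layout) to GrayImage."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        data = arr.astype(float) / scale
    else:
        data = np.clip(arr.astype(float), 0.0, 1.0)
    if data.ndim == 3:
        if data.shape[2] == 4:
            data = data[..., :3]
        if data.shape[2] != 3:
            raise ValidationError(f"unsupported channel count {data.shape[2]}")
        data = data @ np.asarray(LUMA_WEIGHTS)
    elif data.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {data.ndim}")
    return GrayImage(np.clip(data, 0.0, 1.0))


def roi_mask(roi: RegionOfInterest, height: int, width: int) -> np.ndarray:
    """Render a region of interest as a boolean mask (True inside)."""
    roi.validate_for(height, width)
    if roi.shape == "full":
        return np.ones((height, width), dtype=bool)
    if roi.shape == "rectangle":
        x0, y0, x1, y1 = roi.rect
        out = np.zeros((height, width), dtype=bool)
        out[int(np.ceil(y0)) : int(np.ceil(y1)), int(np.ceil(x0)) : int(np.ceil(x1))] = True
        return out
    cx, cy, r = roi.circle
    yy, xx = np.mgrid[0:height, 0:width]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def render_overlay(
    image: GrayImage,
    mask: np.ndarray,
    length_path: list[tuple[float, float]] | None = None,
    depth_segment: tuple[tuple[float, float], tuple[float, float]] | None = None,
    *,
    mask_color: tuple[float, float, float] = (0.15, 0.40, 1.0),
    alpha: float = 0.5,
    length_color: tuple[float, float, float] = (1.0, 0.1, 0.1),
    depth_color: tuple[float, float, float] = (0.1, 0.9, 0.2),
) -> np.ndarray:
    """Blend a segmentation mask over the image and draw measurement lines.

    Returns an (H, W, 3) float RGB array in [0, 1].  With an empty mask and
    no lines this is exactly the grayscale image replicated to 3 channels.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.pixels.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image {image.pixels.shape}"
        )
    out = np.repeat(image.pixels[:, :, None], 3, axis=2)
    if mask.any():
        blended = (1.0 - alpha) * image.pixels[mask, None] + alpha * np.asarray(mask_color)
        out[mask] = blended
    if length_path is not None and len(length_path) >= 2:
        _draw_polyline(out, length_path, length_color)
    if depth_segment is not None:
        _draw_polyline(out, list(depth_segment), depth_color)
    return out


def _draw_polyline(out: np.ndarray, points, color) -> None:
    h, w = out.shape[:2]
    pts = [(int(round(x)), int(round(y))) for x, y in points]
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[keep], cc[keep]] = color


def save_overlay(rgb: np.ndarray, path: str | Path) -> None:
    """Write a float RGB overlay as an 8-bit PNG."""
    arr = np.clip(np.asarray(rgb), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit grayscale PNG/TIFF."""
    iio.imwrite(Path(path), (image.pixels * 255.0 + 0.5).astype(np.uint8))
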