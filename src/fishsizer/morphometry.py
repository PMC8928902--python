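"""Length and depth extraction from a larva segmentation.

The mask is first rotated so the body's major axis is horizontal (nearest-
neighbor, as for a binary image).  The head end is the half with more mask
pixels (larval fish are front-heavy).  Body length is the arc length of a
polynomial midline fitted to the mask; the polynomial order follows the
curvature of the *tail* half only, so a large yolk sac cannot force a
curved regression onto a straight larva: an order-2 fit to the tail with
|a2| > 0.1 or |a1| > 0.5 selects order 3 for the whole body, otherwise
order 2.  Body depth is the median vertical extent over a window of +-5% of
the body extent around a configurable position along the body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.integrate import quad

from .errors import MeasurementError, ValidationError
from .segmentation import LarvaMask

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class MorphometryParams:
    """Measurement settings.

    ``depth_offset_percent``: location of the depth measurement as % of
    body length from the head (50 = midpoint).  ``depth_window_percent``:
    half-width of the depth window as % of body extent (the median is taken
    over the window).  ``order_threshold_a2``/``order_threshold_a1``: tail-
    curvature coefficients above which a 3rd-order midline is used; the
    thresholds apply to a fit in raw pixel coordinates with x shifted so
    the tail half starts at 0, and are strict inequalities.
    ``inclusive_depth``: count a column's depth as max-min+1 pixels (a
    1-px-thick band has depth 1); set False for the bare max-min
    difference.  ``midline_fit``: "pixels" fits all mask pixels,
    "column_centroids" fits per-column mean y instead.
    """

    depth_offset_percent: float = 50.0
    depth_window_percent: float = 5.0
    order_threshold_a2: float = 0.1
    order_threshold_a1: float = 0.5
    inclusive_depth: bool = True
    midline_fit: str = "pixels"

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth_offset_percent <= 100.0):
            raise ValidationError("depth_offset_percent must be in [0, 100]")
        if not (0.0 <= self.depth_window_percent <= 50.0):
            raise ValidationError("depth_window_percent must be in [0, 50]")
        if self.midline_fit not in ("pixels", "column_centroids"):
            raise ValidationError("midline_fit must be 'pixels' or 'column_centroids'")


@dataclass(frozen=True)
class MidlinePolynomial:
    """Fitted midline y = p(x) in the rotated frame.

    ``coefficients`` are in descending degree (numpy convention); ``x_min``
    and ``x_max`` give the mask's extent along x, the integration bounds for
    arc length.
    """

    coefficients: tuple[float, ...]
    order: int
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValidationError("midline order must be 2 or 3")
        if not self.x_min < self.x_max:
            raise ValidationError("x_min must be < x_max")

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class MorphometryResult:
    """Automated measurements for one larva."""

    length_px: float
    depth_px: float
    head_side: str
    midline: MidlinePolynomial
    depth_x: float
    rotation_deg: float


def rotate_mask(mask: LarvaMask) -> np.ndarray:
    """Rotate the mask so its major axis is horizontal.

    Nearest-neighbor interpolation on an enlarged canvas; padding is
    background (0).
    """
    rotated = ndi.rotate(
        mask.pixels.astype(np.uint8),
        -mask.orientation_deg,
        order=0,
        reshape=True,
        prefilter=False,
    )
    return rotated.astype(bool)


def find_head_end(rotated: np.ndarray) -> str:
    """Head side of a horizontal mask: the half with more pixels (tie: left)."""
    ys, xs = np.nonzero(rotated)
    if xs.size == 0:
        raise MeasurementError("empty mask")
    center = (xs.min() + xs.max()) / 2.0
    left = int((xs < center).sum())
    right = int((xs > center).sum())
    return LEFT if left >= right else RIGHT


def _tail_pixels(rotated: np.ndarray, head: str) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.nonzero(rotated)
    center = (xs.min() + xs.max()) / 2.0
    keep = xs >= center if head == LEFT else xs <= center
    return xs[keep], ys[keep]


def select_poly_order(
    rotated: np.ndarray, head: str, params: MorphometryParams | None = None
) -> int:
    """Choose midline order 2 or 3 from the curvature of the tail half.

    An order-2 least-squares fit to the tail pixels (x shifted so the tail
    half starts at 0) selects order 3 when |a2| or |a1| strictly exceeds
    its threshold; boundary values keep order 2.
    """
    if params is None:
        params = MorphometryParams()
    txs, tys = _tail_pixels(rotated, head)
    if txs.size < 10:
        raise MeasurementError(f"tail half has only {txs.size} pixels (< 10)")
    t = txs - txs.min()
    a2, a1, _ = np.polyfit(t, tys, 2)
    if abs(a2) > params.order_threshold_a2 or abs(a1) > params.order_threshold_a1:
        return 3
    return 2


def fit_midline(rotated: np.ndarray, order: int, fit: str = "pixels") -> MidlinePolynomial:
    """Least-squares polynomial midline through the rotated mask."""
    if order not in (2, 3):
        raise ValidationError("order must be 2 or 3")
    ys, xs = np.nonzero(rotated)
    if xs.size == 0:
        raise MeasurementError("empty mask")
    if fit == "column_centroids":
        cols = np.unique(xs)
        fit_x = cols.astype(float)
        fit_y = np.array([ys[xs == c].mean() for c in cols])
    else:
        fit_x, fit_y = xs.astype(float), ys.astype(float)
    if np.unique(fit_x).size < order + 1:
        raise MeasurementError(
            f"only {np.unique(fit_x).size} distinct x values for an order-{order} fit"
        )
    coeffs = np.polyfit(fit_x, fit_y, order)
    return MidlinePolynomial(
        coefficients=tuple(float(c) for c in coeffs),
        order=order,
        x_min=float(xs.min()),
        x_max=float(xs.max()),
    )


def arc_length(midline: MidlinePolynomial) -> float:
    """Arc length of the midline over [x_min, x_max] by adaptive quadrature."""
    deriv = np.polyder(np.asarray(midline.coefficients))

    def integrand(x):
        return math.sqrt(1.0 + float(np.polyval(deriv, x)) ** 2)

    value, _ = quad(integrand, midline.x_min, midline.x_max, epsrel=1e-9, limit=200)
    return float(value)


def measure_depth(
    rotated: np.ndarray, head: str, params: MorphometryParams | None = None
) -> tuple[float, float]:
    """Windowed median body depth.

    The target column sits ``depth_offset_percent`` of the x-extent from the
    head end; every integer column within ``+- depth_window_percent`` of the
    extent contributes its vertical extent (max y - min y + 1 by default),
    and the median over non-empty columns is returned together with the
    target x.  Windows at offset 0 or 100 are clipped to the mask extent.
    """
    if params is None:
        params = MorphometryParams()
    ys, xs = np.nonzero(rotated)
    if xs.size == 0:
        raise MeasurementError("empty mask")
    x_min, x_max = int(xs.min()), int(xs.max())
    extent = float(x_max - x_min)
    frac = params.depth_offset_percent / 100.0
    target = x_min + frac * extent if head == LEFT else x_max - frac * extent
    w = params.depth_window_percent / 100.0 * extent
    lo = max(int(math.ceil(target - w)), x_min)
    hi = min(int(math.floor(target + w)), x_max)
    bonus = 1 if params.inclusive_depth else 0
    depths = []
    for col in range(lo, hi + 1):
        col_ys = ys[xs == col]
        if col_ys.size:
            depths.append(float(col_ys.max() - col_ys.min() + bonus))
    if not depths:
        raise MeasurementError("no mask pixels in the depth window")
    return float(np.median(depths)), float(target)


def measure(mask: LarvaMask, params: MorphometryParams | None = None) -> MorphometryResult:
    """Full morphometric extraction from a larva mask (deterministic)."""
    if params is None:
        params = MorphometryParams()
    rotated = rotate_mask(mask)
    head = find_head_end(rotated)
    order = select_poly_order(rotated, head, params)
    midline = fit_midline(rotated, order, params.midline_fit)
    length = arc_length(midline)
    depth, depth_x = measure_depth(rotated, head, params)
    return MorphometryResult(
        length_px=length,
        depth_px=depth,
        head_side=head,
        midline=midline,
        depth_x=depth_x,
        rotation_deg=-mask.orientation_deg,
    )


def polyline_length(points: list[tuple[float, float]]) -> float:
    """Sum of Euclidean segment lengths of an ordered polyline."""
    if points is None or len(points) < 2:
        raise ValidationError("a polyline needs at least 2 points")
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1)).sum())
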