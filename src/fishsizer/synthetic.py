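"""Parametric synthetic larva images with exact ground truth.

Real input images are single anesthetized larvae on a microscope slide: a
mostly uniform, low-contrast background with one elongated, curved, tapered
body, occasionally contaminated by slide scratches, water-drop arcs touching
the frame border, scale bars, and annotation text boxes.  This module
renders that scene from an analytic description so every downstream stage
can be tested against exact ground truth (midline arc length, per-column
depth, head side) without any real data.

The body is the set of pixels within a longitudinal half-depth profile of a
polynomial midline, measured vertically; the half-depth convention makes
the generator's depth ground truth identical in definition to the column
scan used by the measurement stage.  The rendered band is rigidly rotated
(nearest neighbor, fixed canvas), then truncated Gaussian intensity noise is
added.  Ground truth is computed before noise.

Default parameter ranges emulate a stereomicroscope camera frame
(1200 x 1600 px) with a larva 700-950 px long and a maximum half-depth of
60-100 px, i.e. a depth/length ratio of roughly 0.13-0.22 as seen in
yolk-sac and preflexion stages of the species this approach targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import circle_perimeter, line as _draw_line

from .errors import ArtifactPlacementError, ValidationError
from .imaging import GrayImage

PROFILES = ("uniform", "tapered", "yolk_bulge")
ARTIFACT_KINDS = ("scratch", "border_drop", "scale_bar", "text_box")

#: Body must keep at least this margin (px) from every canvas border.
BODY_MARGIN = 5

#: Default parameter ranges for :func:`make_spec` (uniform draws).
DEFAULT_RANGES: dict = {
    "canvas": (1200, 1600),           # height, width in px (fixed, not drawn)
    "span": (700.0, 950.0),           # body x-extent before rotation, px
    "curvature": (-0.6, 0.6),         # a2 * span (dimensionless sag control)
    "slope": (-0.15, 0.15),           # midline slope at body center
    "half_depth_max": (60.0, 100.0),  # maximum half-depth, px
    "taper_exponent": (0.8, 1.5),
    "body_intensity": (0.15, 0.35),
    "background_intensity": (0.70, 0.85),
    "noise_sigma": (0.0, 0.05),
    "rotation_deg": (-25.0, 25.0),
    "profiles": PROFILES,             # candidate depth-profile classes
}


@dataclass(frozen=True)
class SyntheticLarvaSpec:
    """Analytic description of one synthetic larva image.

    ``midline`` holds polynomial coefficients (descending degree, pixel
    units, y = p(x) in image coordinates) of the true generating curve over
    ``x_span``.  The depth profile classes are ``uniform`` (constant
    half-depth), ``tapered`` (head thicker than tail) and ``yolk_bulge``
    (slender body with an anterior bulge).  ``mirrored`` flips the rendered
    scene left-right (head on the right).
    """

    midline: tuple[float, ...]
    x_span: tuple[float, float]
    profile: str = "tapered"
    half_depth_max: float = 80.0
    taper_exponent: float = 1.1
    bulge_center: float = 0.18       # fraction of body length from head
    bulge_width: float = 0.12        # fraction of body length
    body_intensity: float = 0.25
    background_intensity: float = 0.78
    rotation_deg: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    height: int = 1200
    width: int = 1600
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValidationError(f"unknown depth profile {self.profile!r}")
        if not self.x_span[0] < self.x_span[1]:
            raise ValidationError("x_span must be increasing")
        if self.half_depth_max <= 0:
            raise ValidationError("half_depth_max must be positive")
        if abs(self.body_intensity - self.background_intensity) < 0.1:
            raise ValidationError(
                "body/background contrast must be at least 0.1"
            )
        _check_fits(self)

    @property
    def span(self) -> float:
        return self.x_span[1] - self.x_span[0]

    def midline_y(self, x):
        return np.polyval(np.asarray(self.midline), x)

    def half_depth(self, u):
        """Half-depth profile as a function of u in [0, 1] (0 = head)."""
        u = np.asarray(u, dtype=float)
        h = self.half_depth_max
        if self.profile == "uniform":
            return np.full_like(u, h)
        if self.profile == "tapered":
            return h * (0.4 + 0.6 * (1.0 - u) ** self.taper_exponent)
        # yolk_bulge: slender body plus an anterior Gaussian bulge
        base = 0.55 * h
        bulge = 0.45 * h * np.exp(
            -((u - self.bulge_center) ** 2) / (2.0 * self.bulge_width**2)
        )
        return base + bulge

    @property
    def head_side(self) -> str | None:
        """Ground-truth head side in the rendered image, or None (uniform)."""
        if self.profile == "uniform":
            return None
        return "right" if self.mirrored else "left"


class GroundTruth:
    """Exact generator-side truth for one rendered spec."""

    def __init__(
        self,
        length_px: float,
        head_side: str | None,
        body_raster: np.ndarray,
        flat_raster: np.ndarray,
    ):
        self.length_px = length_px
        self.head_side = head_side
        #: rendered (rotated) body pixels, aligned with the image
        self.body_raster = body_raster
        self._flat_raster = flat_raster  # pre-rotation, head at left

    def depth_at(self, offset_percent: float, window_percent: float = 5.0) -> float:
        """True inclusive depth: windowed median column scan, head at left."""
        return _raster_depth(self._flat_raster, offset_percent, window_percent)


def _check_fits(spec: SyntheticLarvaSpec) -> None:
    """Conservative bound: the rotated body must fit with BODY_MARGIN."""
    half_span = spec.span / 2.0
    x_mid = (spec.x_span[0] + spec.x_span[1]) / 2.0
    xs = np.linspace(spec.x_span[0], spec.x_span[1], 64)
    dev = np.abs(spec.midline_y(xs) - spec.midline_y(x_mid))
    half_y = float(dev.max()) + spec.half_depth_max + 2.0
    c, s = abs(math.cos(math.radians(spec.rotation_deg))), abs(
        math.sin(math.radians(spec.rotation_deg))
    )
    rx = half_span * c + half_y * s
    ry = half_span * s + half_y * c
    cx = (spec.width - 1) / 2.0
    cy = (spec.height - 1) / 2.0
    # body is recentered on the canvas before rotation (see render)
    if rx > cx - BODY_MARGIN - 1 or ry > cy - BODY_MARGIN - 1:
        raise ValidationError(
            "body would violate the 5-px canvas margin after rotation"
        )


def make_spec(seed: int, ranges: dict | None = None) -> SyntheticLarvaSpec:
    """Draw a random spec from parameter ranges (deterministic per seed)."""
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)
    height, width = r["canvas"]
    span = rng.uniform(*r["span"])
    curvature = rng.uniform(*r["curvature"])
    slope = rng.uniform(*r["slope"])
    profile = str(rng.choice(list(r["profiles"])))
    h_max = rng.uniform(*r["half_depth_max"])
    taper = rng.uniform(*r["taper_exponent"])
    body_i = rng.uniform(*r["body_intensity"])
    bg_i = rng.uniform(*r["background_intensity"])
    noise = rng.uniform(*r["noise_sigma"])
    rot = rng.uniform(*r["rotation_deg"])

    cx = (width - 1) / 2.0
    cy = (height - 1) / 2.0
    a2 = curvature / span
    # expand cy + slope*(x-cx) + a2*(x-cx)^2 into absolute coefficients
    coeffs = (
        a2,
        slope - 2.0 * a2 * cx,
        cy - slope * cx + a2 * cx * cx,
    )
    return SyntheticLarvaSpec(
        midline=coeffs,
        x_span=(cx - span / 2.0, cx + span / 2.0),
        profile=profile,
        half_depth_max=h_max,
        taper_exponent=taper,
        body_intensity=body_i,
        background_intensity=bg_i,
        rotation_deg=rot,
        noise_sigma=noise,
        seed=int(seed),
        height=height,
        width=width,
    )


def mirror_spec(spec: SyntheticLarvaSpec) -> SyntheticLarvaSpec:
    """Left-right mirror of a spec (head side flips; nothing else changes)."""
    return replace(spec, mirrored=not spec.mirrored)


def true_length(spec: SyntheticLarvaSpec, n: int = 10_000) -> float:
    """Arc length of the generating midline by dense polyline sampling."""
    xs = np.linspace(spec.x_span[0], spec.x_span[1], n + 1)
    ys = spec.midline_y(xs)
    return float(np.sqrt(np.diff(xs) ** 2 + np.diff(ys) ** 2).sum())


def _rasterize_band(spec: SyntheticLarvaSpec) -> np.ndarray:
    """Pre-rotation body raster: pixels within half-depth of the midline."""
    xs = np.arange(spec.width, dtype=float)
    in_span = (xs >= spec.x_span[0]) & (xs <= spec.x_span[1])
    f = spec.midline_y(xs)
    u = np.clip((xs - spec.x_span[0]) / spec.span, 0.0, 1.0)
    h = spec.half_depth(u)
    ygrid = np.arange(spec.height, dtype=float)[:, None]
    return in_span[None, :] & (np.abs(ygrid - f[None, :]) <= h[None, :])


def _raster_depth(raster: np.ndarray, offset_percent: float, window_percent: float) -> float:
    """Windowed median inclusive column depth with the head at the left."""
    ys, xs = np.nonzero(raster)
    x_min, x_max = int(xs.min()), int(xs.max())
    extent = float(x_max - x_min)
    target = x_min + offset_percent / 100.0 * extent
    w = window_percent / 100.0 * extent
    lo = max(int(math.ceil(target - w)), x_min)
    hi = min(int(math.floor(target + w)), x_max)
    depths = []
    for col in range(lo, hi + 1):
        col_ys = ys[xs == col]
        if col_ys.size:
            depths.append(float(col_ys.max() - col_ys.min() + 1))
    return float(np.median(depths))


def render(spec: SyntheticLarvaSpec) -> tuple[GrayImage, GroundTruth]:
    """Rasterize a spec into a noisy grayscale image plus exact ground truth.

    The band is rasterized in the horizontal frame, mirrored if requested,
    rigidly rotated about the canvas center (nearest neighbor, canvas size
    fixed), and intensity noise is added last.  Raises if the rotated body
    violates the 5-px border margin.
    """
    flat = _rasterize_band(spec)
    raster = np.fliplr(flat) if spec.mirrored else flat
    angle = -spec.rotation_deg if spec.mirrored else spec.rotation_deg
    if angle != 0.0:
        raster = ndi.rotate(
            raster.astype(np.uint8), angle, order=0, reshape=False, prefilter=False
        ).astype(bool)
    m = BODY_MARGIN
    if (
        raster[:m, :].any()
        or raster[-m:, :].any()
        or raster[:, :m].any()
        or raster[:, -m:].any()
    ):
        raise ValidationError("rotated body violates the 5-px canvas margin")

    img = np.full(
        (spec.height, spec.width), spec.background_intensity, dtype=float
    )
    img[raster] = spec.body_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        length_px=true_length(spec),
        head_side=spec.head_side,
        body_raster=raster,
        flat_raster=flat,
    )
    return GrayImage(img), truth


# ---------------------------------------------------------------------------
# artifacts


def add_artifacts(
    image: GrayImage,
    kinds,
    seed: int,
    keep_clear: np.ndarray | None = None,
) -> GrayImage:
    """Stamp slide artifacts onto an image (deterministic per seed).

    ``scratch``: thin low-contrast line; ``border_drop``: high-contrast
    water-drop arc intersecting an image border; ``scale_bar``: solid bar
    with tick marks near a corner; ``text_box``: filled rectangle with a
    high-contrast interior pattern.  If ``keep_clear`` (e.g. the body
    raster) is given, placements overlapping its 8-px dilation are retried
    up to 100 times before raising :class:`ArtifactPlacementError`.
    """
    kinds = sorted(set(kinds))
    unknown = [k for k in kinds if k not in ARTIFACT_KINDS]
    if unknown:
        raise ValidationError(f"unknown artifact kinds {unknown}")
    if not kinds:
        return image
    px = image.pixels.copy()
    h, w = px.shape
    forbidden = None
    if keep_clear is not None:
        forbidden = ndi.maximum_filter(keep_clear.astype(bool), size=17)
    rng = np.random.default_rng(seed)
    for kind in kinds:
        for attempt in range(100):
            stamp_mask, stamp_vals = _make_stamp(kind, h, w, rng, px)
            if forbidden is None or not (stamp_mask & forbidden).any():
                px[stamp_mask] = stamp_vals[stamp_mask]
                break
        else:
            raise ArtifactPlacementError(
                f"could not place {kind!r} clear of the body in 100 attempts"
            )
    return GrayImage(np.clip(px, 0.0, 1.0))


def _make_stamp(kind: str, h: int, w: int, rng, base: np.ndarray):
    mask = np.zeros((h, w), dtype=bool)
    vals = base.copy()
    if kind == "scratch":
        # thin, low-contrast line crossing part of the slide
        x0, x1 = rng.integers(0, w, 2)
        y0, y1 = rng.integers(0, h, 2)
        rr, cc = _draw_line(int(y0), int(x0), int(y1), int(x1))
        for dy in (0, 1):
            r2 = np.clip(rr + dy, 0, h - 1)
            mask[r2, cc] = True
        vals[mask] = np.clip(base[mask] + rng.choice((-0.07, 0.07)), 0, 1)
    elif kind == "border_drop":
        # arc of a large circle whose center lies outside the frame
        side = rng.integers(0, 4)
        r = int(rng.uniform(0.25, 0.45) * min(h, w))
        off = int(r * rng.uniform(0.4, 0.8))
        if side == 0:
            c_y, c_x = -off, int(rng.uniform(0.2, 0.8) * w)
        elif side == 1:
            c_y, c_x = h - 1 + off, int(rng.uniform(0.2, 0.8) * w)
        elif side == 2:
            c_y, c_x = int(rng.uniform(0.2, 0.8) * h), -off
        else:
            c_y, c_x = int(rng.uniform(0.2, 0.8) * h), w - 1 + off
        for rad in (r - 1, r, r + 1):
            rr, cc = circle_perimeter(c_y, c_x, rad, shape=None)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[keep], cc[keep]] = True
        vals[mask] = 0.05
    elif kind == "scale_bar":
        bar_len = max(int(0.12 * w), 40)
        bar_th = 10
        x0 = rng.integers(20, max(21, w - bar_len - 20))
        y0 = int(rng.choice((rng.integers(20, 80), h - rng.integers(30, 90))))
        y0 = int(np.clip(y0, 10, h - 30))
        mask[y0 : y0 + bar_th, x0 : x0 + bar_len] = True
        for i in range(6):  # tick marks
            tx = x0 + int(i * (bar_len - 3) / 5)
            mask[max(y0 - 10, 0) : y0, tx : tx + 3] = True
        vals[mask] = 0.05
    else:  # text_box
        bw, bh = 150, 60
        x0 = rng.integers(15, max(16, w - bw - 15))
        y0 = rng.integers(15, max(16, h - bh - 15))
        mask[y0 : y0 + bh, x0 : x0 + bw] = True
        vals[mask] = 0.92
        # glyph-like dark strokes inside the box
        for _ in range(14):
            gx = rng.integers(x0 + 6, x0 + bw - 9)
            gy = rng.integers(y0 + 8, y0 + bh - 20)
            glen = rng.integers(8, 16)
            vals[gy : gy + glen, gx : gx + 3] = 0.30
    return mask, vals


def write_dataset(
    out_dir: str | Path,
    n: int,
    seed: int,
    ranges: dict | None = None,
    artifacts=(),
) -> Path:
    """Render ``n`` seeded specs to PNGs plus a ground-truth CSV.

    Returns the path of the CSV (``ground_truth.csv``) with columns
    file, true_length_px, true_depth50_px, rotation_deg.
    """
    from .imaging import save_image  # local to avoid cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["file,true_length_px,true_depth50_px,rotation_deg"]
    for i in range(n):
        spec = make_spec(seed + i, ranges)
        image, truth = render(spec)
        if artifacts:
            image = add_artifacts(
                image, artifacts, seed=spec.seed + 10_000, keep_clear=truth.body_raster
            )
        name = f"larva_{i:04d}.png"
        save_image(image, out_dir / name)
        rows.append(
            f"{name},{truth.length_px:.4f},{truth.depth_at(50.0):.4f},"
            f"{spec.rotation_deg:.4f}"
        )
    csv_path = out_dir / "ground_truth.csv"
    csv_path.write_text("\n".join(rows) + "\n")
    return csv_path
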