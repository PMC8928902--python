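"""YAML configuration for segmentation and morphometry parameters.

Recognized keys (all optional)::

    threshold: 0.55            # edge threshold, fraction of max contrast
    dilation: 3                # square-dilation / diamond-erosion radius
    sigma: 4.0                 # Gaussian smoothing scale, px
    sharpen_amount: 0.8        # unsharp-masking gain
    min_area_fraction: 0.0005  # smallest larva area / ROI area
    roi: "rect:100,50,1500,1100"   # or "circle:cx,cy,r" or "full"
    depth_offset: 50           # depth location, % of length from head
    depth_window: 5            # depth window half-width, % of extent
    order_threshold_a2: 0.1    # tail-curvature thresholds for order-3 fit
    order_threshold_a1: 0.5
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ValidationError
from .imaging import RegionOfInterest
from .morphometry import MorphometryParams
from .segmentation import SegmentationParams


def parse_roi(text: str | None) -> RegionOfInterest:
    """Parse ``full``, ``rect:x0,y0,x1,y1`` or ``circle:cx,cy,r``."""
    if text is None or text == "full":
        return RegionOfInterest.full()
    kind, _, rest = text.partition(":")
    try:
        nums = [float(v) for v in rest.split(",")] if rest else []
    except ValueError as exc:
        raise ValidationError(f"malformed ROI spec {text!r}") from exc
    if kind == "rect" and len(nums) == 4:
        return RegionOfInterest.rectangle(*nums)
    if kind == "circle" and len(nums) == 3:
        return RegionOfInterest.circle_roi(*nums)
    raise ValidationError(f"malformed ROI spec {text!r}")


def params_from_mapping(cfg: dict) -> tuple[SegmentationParams, MorphometryParams]:
    """Build parameter objects from a flat configuration mapping."""
    cfg = dict(cfg or {})
    known = {
        "threshold", "dilation", "sigma", "sharpen_amount", "min_area_fraction",
        "roi", "depth_offset", "depth_window", "order_threshold_a2",
        "order_threshold_a1",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
    roi = cfg.get("roi")
    seg = SegmentationParams(
        threshold_fraction=float(cfg.get("threshold", 0.55)),
        dilation_factor=int(cfg.get("dilation", 3)),
        gaussian_sigma=float(cfg.get("sigma", 4.0)),
        sharpen_amount=float(cfg.get("sharpen_amount", 0.8)),
        min_area_fraction=float(cfg.get("min_area_fraction", 0.0005)),
        roi=roi if isinstance(roi, RegionOfInterest) else parse_roi(roi),
    )
    morph = MorphometryParams(
        depth_offset_percent=float(cfg.get("depth_offset", 50.0)),
        depth_window_percent=float(cfg.get("depth_window", 5.0)),
        order_threshold_a2=float(cfg.get("order_threshold_a2", 0.1)),
        order_threshold_a1=float(cfg.get("order_threshold_a1", 0.5)),
    )
    return seg, morph


def load_config(path: str | Path) -> tuple[SegmentationParams, MorphometryParams]:
    """Read a YAML config file into parameter objects."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"config file does not exist: {path}")
    try:
        cfg = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return params_from_mapping(cfg)
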