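"""Batch measurement over image directories, calibration, CSV export.

One :class:`MeasurementRecord` is produced per input file.  Automated
values come from segmentation + morphometry; manual polyline measurements
override them without discarding them, exactly as in the exported table:
``Length_px``/``Depth_px`` carry the manual value when one was drawn and the
automated estimate otherwise, while the ``*Automated*`` columns always carry
the automated estimate.  Calibration divides pixel values by a pixels-per-mm
scale obtained from two points spanning a known physical distance.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .errors import FishSizerError, ValidationError
from .imaging import load_image, render_overlay, save_overlay
from .morphometry import MorphometryParams, measure, polyline_length
from .segmentation import SegmentationParams, segment_larva

CSV_COLUMNS_PX = [
    "FileName",
    "Length_px",
    "LengthAutomated_px",
    "Depth_px",
    "DepthAutomated_px",
]
CSV_COLUMNS_MM = [
    "Length_mm",
    "LengthAutomated_mm",
    "Depth_mm",
    "DepthAutomated_mm",
]


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-millimeter conversion factor with provenance."""

    px_per_mm: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.px_per_mm) and self.px_per_mm > 0):
            raise ValidationError(f"px_per_mm must be positive and finite, got {self.px_per_mm}")


@dataclass(frozen=True)
class MeasurementRecord:
    """Per-file measurement state (automated, manual, calibrated)."""

    file_name: str
    length_auto_px: float | None = None
    depth_auto_px: float | None = None
    manual_length_px: float | None = None
    manual_depth_px: float | None = None
    length_mm: float | None = None
    length_auto_mm: float | None = None
    depth_mm: float | None = None
    depth_auto_mm: float | None = None
    excluded: bool = False
    error_note: str = ""

    @property
    def manual_length(self) -> bool:
        return self.manual_length_px is not None

    @property
    def manual_depth(self) -> bool:
        return self.manual_depth_px is not None

    @property
    def length_px(self) -> float | None:
        """Manual value if drawn, else the automated estimate."""
        return self.manual_length_px if self.manual_length else self.length_auto_px

    @property
    def depth_px(self) -> float | None:
        return self.manual_depth_px if self.manual_depth else self.depth_auto_px


def create_calibration(
    p1: tuple[float, float], p2: tuple[float, float], known_mm: float
) -> CalibrationScale:
    """Scale from two points spanning a known physical distance."""
    if known_mm <= 0:
        raise ValidationError("known distance must be positive")
    dist = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if dist == 0:
        raise ValidationError("calibration points must be distinct")
    return CalibrationScale(
        px_per_mm=dist / known_mm,
        source=f"points {tuple(p1)}-{tuple(p2)} over {known_mm} mm",
    )


def save_calibration(scale: CalibrationScale, path: str | Path) -> None:
    """Write a calibration as flat key-value text."""
    created = datetime.now(timezone.utc).isoformat(timespec="seconds")
    Path(path).write_text(
        f"px_per_mm = {scale.px_per_mm!r}\n"
        f"created = {created}\n"
        f"source = {scale.source}\n"
    )


def load_calibration(path: str | Path) -> CalibrationScale:
    """Read a calibration file written by :func:`save_calibration`."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"calibration file does not exist: {path}")
    values: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    if "px_per_mm" not in values:
        raise ValidationError(f"calibration file {path} lacks a px_per_mm entry")
    try:
        px_per_mm = float(values["px_per_mm"])
    except ValueError as exc:
        raise ValidationError(f"malformed px_per_mm in {path}: {values['px_per_mm']!r}") from exc
    return CalibrationScale(px_per_mm=px_per_mm, source=values.get("source", str(path)))


def apply_calibration(record: MeasurementRecord, scale: CalibrationScale) -> MeasurementRecord:
    """Fill the mm fields of a record (px values divided by px_per_mm)."""

    def conv(v: float | None) -> float | None:
        return None if v is None else v / scale.px_per_mm

    return replace(
        record,
        length_mm=conv(record.length_px),
        length_auto_mm=conv(record.length_auto_px),
        depth_mm=conv(record.depth_px),
        depth_auto_mm=conv(record.depth_auto_px),
    )


def measure_file(
    path: str | Path,
    seg: SegmentationParams | None = None,
    morph: MorphometryParams | None = None,
    overlay_path: str | Path | None = None,
) -> MeasurementRecord:
    """Measure a single image file; failures land in ``error_note``."""
    path = Path(path)
    try:
        image = load_image(path)
        mask = segment_larva(image, seg)
        result = measure(mask, morph)
    except (FishSizerError, OSError) as exc:
        return MeasurementRecord(file_name=path.name, error_note=str(exc))
    if overlay_path is not None:
        xs = np.linspace(result.midline.x_min, result.midline.x_max, 200)
        midline_pts = list(zip(xs, result.midline(xs)))
        overlay = render_overlay(image, mask.pixels)
        save_overlay(overlay, overlay_path)
        # companion panel: rotated mask with measurement lines, as the
        # measurements are defined in the rotated frame
        from .imaging import GrayImage
        from .morphometry import rotate_mask

        rotated = rotate_mask(mask)
        depth_col = int(round(result.depth_x))
        col_ys = np.nonzero(rotated[:, depth_col])[0]
        depth_seg = None
        if col_ys.size:
            depth_seg = ((result.depth_x, float(col_ys.min())), (result.depth_x, float(col_ys.max())))
        panel = render_overlay(
            GrayImage(rotated.astype(float)),
            np.zeros_like(rotated),
            length_path=midline_pts,
            depth_segment=depth_seg,
        )
        rp = Path(overlay_path)
        save_overlay(panel, rp.with_name(rp.stem + "_rotated" + rp.suffix))
    return MeasurementRecord(
        file_name=path.name,
        length_auto_px=result.length_px,
        depth_auto_px=result.depth_px,
    )


def process_batch(
    paths,
    seg: SegmentationParams | None = None,
    morph: MorphometryParams | None = None,
    scale: CalibrationScale | None = None,
    overlays_dir: str | Path | None = None,
    log=None,
) -> list[MeasurementRecord]:
    """Measure every file, in input order; per-file failures never abort.

    When ``overlays_dir`` is given, a QC overlay PNG is written per
    successful file.  With a calibration scale, mm fields are filled in.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("process_batch needs at least one path")
    if overlays_dir is not None:
        overlays_dir = Path(overlays_dir)
        overlays_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for path in paths:
        overlay_path = (
            overlays_dir / (path.stem + "_overlay.png") if overlays_dir else None
        )
        record = measure_file(path, seg, morph, overlay_path)
        if record.error_note and log is not None:
            print(f"{path.name}: {record.error_note}", file=log)
        if scale is not None:
            record = apply_calibration(record, scale)
        records.append(record)
    return records


def set_manual(
    record: MeasurementRecord, which: str, points
) -> MeasurementRecord:
    """Attach a manual polyline measurement (length or depth) to a record."""
    value = polyline_length(points)
    if which == "length":
        return replace(record, manual_length_px=value)
    if which == "depth":
        return replace(record, manual_depth_px=value)
    raise ValidationError(f"which must be 'length' or 'depth', got {which!r}")


def clear_manual(record: MeasurementRecord, which: str) -> MeasurementRecord:
    """Drop a manual measurement, reverting to the automated estimate."""
    if which == "length":
        return replace(record, manual_length_px=None)
    if which == "depth":
        return replace(record, manual_depth_px=None)
    raise ValidationError(f"which must be 'length' or 'depth', got {which!r}")


def flag_outliers(
    records, k: float = 3.5
) -> dict[str, list[bool]]:
    """Advisory outlier flags per dimension (median +- k * MAD rule).

    Stands in for visual inspection of the per-batch scatter: records whose
    length (or depth) deviates from the batch median by more than ``k``
    times the median absolute deviation are flagged.  Never modifies values.
    Fewer than 3 records with values yields empty flag lists.
    """
    out: dict[str, list[bool]] = {}
    for dim, getter in (("length", lambda r: r.length_px), ("depth", lambda r: r.depth_px)):
        values = [getter(r) for r in records]
        present = [v for v in values if v is not None]
        if len(present) < 3:
            out[dim] = []
            continue
        med = float(np.median(present))
        mad = float(np.median(np.abs(np.asarray(present) - med)))
        flags = []
        for v in values:
            if v is None:
                flags.append(False)
            elif mad == 0.0:
                flags.append(v != med)
            else:
                flags.append(abs(v - med) > k * mad)
        out[dim] = flags
    return out


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.4f}"


def export_csv(
    records, path: str | Path, scale: CalibrationScale | None = None
) -> Path:
    """Write the measurement table: 5 columns, or 9 when calibrated.

    Excluded records are omitted; failed measurements appear as rows with
    empty numeric cells.  Output is deterministic (byte-identical across
    repeated runs on the same records).
    """
    path = Path(path)
    header = list(CSV_COLUMNS_PX) + (list(CSV_COLUMNS_MM) if scale else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for record in records:
            if record.excluded:
                continue
            if scale is not None:
                record = apply_calibration(record, scale)
            row = [
                record.file_name,
                _fmt(record.length_px),
                _fmt(record.length_auto_px),
                _fmt(record.depth_px),
                _fmt(record.depth_auto_px),
            ]
            if scale is not None:
                row += [
                    _fmt(record.length_mm),
                    _fmt(record.length_auto_mm),
                    _fmt(record.depth_mm),
                    _fmt(record.depth_auto_mm),
                ]
            writer.writerow(row)
    return path
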